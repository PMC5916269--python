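# itvpart

Tools for asking how the match between plant traits and their environment is
maintained along a gradient, at two levels at once:

* **Within a species** — a reciprocal transplant between elevations separates
  *phenotypic plasticity* (trait variation explained by the elevation a plant
  was grown at, EL_T) from *genetic differentiation* (variation explained by
  the elevation it originated from, EL_O), with the origin × transplant
  interaction as the signature of local adaptation.
* **Across species** — community-weighted mean (CWM) traits change along the
  gradient both because species turn over (SPT) and because individuals of
  each species shift their traits (intraspecific trait variation, ITV); the
  two contributions can be separated exactly.

A third layer ties them together: within-site phenotypic selection analysis
tests whether selection on individuals points toward the local CWM — i.e.
whether community-level trait means behave as selective optima.

## The statistics at the core

**Variance partitioning.** Per trait, the transplant model is

```
trait ~ EL_O + EL_T + EL_O:EL_T + R + block(R:EL_T) + init_biomass
```

fit by least squares with sum-to-zero contrasts (R = transect; block is a
fixed factor nested in transect × transplant site; initial biomass is a
covariate). A type III ANOVA — each term's sum of squares is the rise in
residual SS when that term alone is dropped — is appropriate for the
unbalanced design, and the plasticity share is

```
%E = 100 · SS_E / (SS_E + SS_G)
```

with the G×E interaction excluded from the ratio since its variation cannot
be assigned to either source. Survival (binary) uses a logit-link GLM with a
type III analysis of deviance.

**CWM decomposition.** Computing the CWM twice — with site-specific trait
values ("specific") and with gradient-wide species means ("fixed") — and
regressing both series plus their difference on the gradient yields the
exact identity `SS_specific = SS_fixed + SS_intra + SS_cov`; the ITV share
is `100·SS_intra/(SS_intra + SS_fixed)` on the gradient-explained sums of
squares.

**Selection.** Per site, relative fitness is `w = W/mean(W)` (final dry
biomass among survivors) and traits are standardized within site. The
selection differential is `S = cov(w, z)` (significance from the Pearson
correlation test) and the selection gradients β are the partial coefficients
of the multiple regression of `w` on all standardized traits; the two obey
`S = R β̂` with `R` the trait correlation matrix.

A synthetic-data module (`itvpart.synthgen`) generates transplant studies on
the real design grid — 2 transects × 3 elevations (715/870/1,040 m a.s.l.),
4 blocks per site, 7 individuals per origin per block, 504 plants — with
additive effects on the transformed trait scale and lognormal fitness, so
every downstream estimate has a known truth.

## Worked example

```python
from itvpart import partition, synthgen

records = synthgen.simulate_transplant(synthgen.default_params(seed=1))
rt = partition.apply_transform(records, synthgen.TRAIT_TRANSFORMS)
model = partition.fit_trait_model(rt, partition.ModelSpec(response="height_transformed"))
table = partition.type3_anova(model)
print(partition.percent_plasticity(table, "height"))
```

prints

```
PartitionResult(trait='height', ss_e=153.04, ss_g=28.57, ss_gxe=3.15,
                percent_e=84.27, percent_g=15.73)
```

Under the default conditions (plastic elevation steps ~3× the genetic
steps), 84% of the elevational height signal is plastic: SS_E is the
marginal SS of the transplant-elevation term, SS_G of the origin term, and
the interaction (3.15, F ≈ 0.67) shows no G×E, i.e. no local adaptation.
For comparison, the published field-study mean squares give %E = 68.4%
(height), 75.8% (leaf area) and 78.2% (SLA) through the same formula.

The numbered drivers under `analysis/` run the full narrative — simulate
(`01`), partition traits and survival (`02`), decompose CWM turnover (`03`),
selection and the CWM-optimality check (`04`) — writing their tables under
`results/`.

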