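# Methods

## The transplant model and its estimation

Each trait is analyzed on a variance-stabilizing scale — square root for
height (mm), natural log for leaf area (mm²) and SLA (mm² mg⁻¹) — and the
model is linear and additive on that scale:

    trait ~ EL_O + EL_T + EL_O:EL_T + R + block(R:EL_T) + init_biomass

where EL_O and EL_T are three-level factors (elevation of origin and of
transplant; low/mid/high are always treated as factor levels, never as a
numeric covariate), R is the two-level transect factor, and initial biomass
enters centered as a continuous covariate. All factors use sum-to-zero
contrasts, the coding under which type III marginal tests are meaningful.

**Block is a fixed nested factor.** Each of the six transplant sites
(transect × EL_T) carries its own sum-to-zero block contrasts (three columns
per site for four blocks), zero for individuals outside the site. A mixed
model with a random block intercept and Satterthwaite degrees of freedom is
deliberately out of scope: the %E statistic depends only on SS_E and SS_G,
which are well-defined marginal sums of squares in the fixed-effects fit.
The cost is that F ratios for between-site terms are approximations — the
fixed-block fit tests them against the residual mean square, not against
block-level variation. A related consequence, visible in the recovery
benchmarks: site-level block deviates do not average out of the EL_T level
means, so under a null EL_T the expected marginal SS_E is roughly
2(σ² + 21σ_b²) rather than 2σ², while SS_G (origins are crossed with
blocks) stays near 2σ². The null-channel SS is therefore a small positive
bias in %E whose size depends on σ_b, which is why the recovery benchmarks
put equal signal on one channel at a time rather than testing tiny effects
against this floor.

**Type III sums of squares** are computed by refitting: drop the term's
columns from the full design matrix, refit, and take the rise in residual
SS. On balanced factor-only designs this equals the sequential (type I) SS
term by term; the sequential table is also exposed
(`partition.sequential_anova`) and satisfies the conservation identity
Σ SS + SS_resid = SS_total, which the tests use as an independent oracle
alongside `statsmodels.stats.anova.anova_lm`.

**%E.** `percent_plasticity` computes 100·SS_E/(SS_E + SS_G), carries the
G×E SS along without including it (its variation cannot be assigned to
either source), and reports an undefined share (NaN) when both SS are zero
rather than coercing to 0 or 100. The ratio is invariant to rescaling the
response. Applied to an analysis-of-deviance table it yields the
deviance-scale analogue for survival.

**Survival** uses a logit-link binomial GLM on the same design matrix with
likelihood-ratio (deviance-drop) chi-square tests per term. Cells whose
outcomes are all identical are reported as potential separation before
fitting. Individuals dead before the growing season (transplant shock) are
excluded from all analyses by the generator's optional pre-filter; summer
deaths stay in the survival model but drop out of trait and biomass models
simply because their responses are missing.

**Least-squares means** are model predictions on a factor grid with the
other factors averaged equally (their sum-to-zero columns average to zero),
block effects averaged out, and the covariate at its grand mean. Pairwise
contrasts use a Tukey-style studentized-range adjustment by default
(`adjust="none"`/`"bonferroni"` available); binomial-family means are on the
logit scale.

**Stepwise initial biomass.** The initial-biomass covariate is predicted
from morphology by bidirectional stepwise OLS starting from the intercept
model and minimizing AIC (BIC optional). Criterion and direction are
package choices — any information criterion would serve — and the selection
path is returned for audit.

## CWM decomposition

`cwm.decompose` forms three per-site series — specific CWM (site-local
trait values), fixed CWM (gradient-wide species means), and their
difference, the intraspecific series — regresses each on the gradient
(simple linear regression by default; one-way factor coding optional), and
records explained and total sums of squares. The covariation term is defined
as the exact remainder SS_specific − SS_fixed − SS_intra, so additivity is
an identity, not an approximation; SS_cov may be negative. Shares are
reported on the gradient-explained components (the "explanatory power" of
ITV vs turnover) with total-variance shares alongside. Species gradient-wide
means default to abundance-weighted averages of the site-specific values
(unweighted optional). Degenerate inputs: fewer than 2 sites is an error
(with exactly 2 the linear model is saturated and explained = total SS); a
zero-variance specific series leaves the shares undefined. Missing
site-specific values for a present species are a strict error by default,
with an opt-in policy substituting the species mean under a warning.

## Selection analysis

Relative fitness and trait standardization are computed **within site**
(global options exist but are off by default): w = W/mean(W) using final dry
biomass among survivors as the fitness proxy, z = (x − mean)/sd with the
sample (n−1) sd — the covariance denominator is likewise n−1 throughout.
S = cov(w, z) with significance from the two-sided Pearson correlation test;
β from OLS of w on all standardized traits jointly (statsmodels, with an
explicit normal-equations solver as the test oracle). Traits enter the
gradient model on the raw scale by default (standardization makes the scale
choice a near-affine one; a transformed-scale switch exists). No
multiplicity adjustment is applied across the site × trait grid. The
CWM-optimality check scores sign(S) against sign(CWM − population mean) per
site × trait; exact zeros on either side are indeterminate and excluded
from the consistency fraction, and declared scale mismatches between the
CWM table and the population means are rejected.

## The synthetic study

The generator reproduces the experimental design exactly: 2 transects × 3
elevations × 4 blocks × 3 origins × 7 individuals = 504 plants, origins
transplanted only within their own transect. Traits are generated additively
on the transformed scale and back-transformed, so the analysis model is the
generating model and parameter recovery is well-posed. Default magnitudes
are modeled on the published field ANOVA's mean squares: residual sd 1.05
(sqrt-mm height), 0.52 and 0.19 (log leaf area, log SLA); plastic elevation
steps ≈ 0.7 residual sd, genetic steps ≈ 0.25, both decreasing from low to
high elevation; block sd ≈ 0.25 residual sd; transect offset large for
height only. Initial biomass is N(0.25 g, 0.08 g) truncated positive;
survival is Bernoulli with logit intercept 1.4 (~80%) plus optional per-cell
offsets. Fitness is lognormal in within-site standardized traits with true
gradients (0.10, 0.45, −0.15) for (height, leaf area, SLA), normalized so
each site's mean biomass is exactly 0.35 g — under this construction the
standardized linear gradients of relative fitness equal the generating β.
One global integer seed drives independent sub-streams
(`numpy.random.SeedSequence.spawn`), so runs are byte-identical per seed.

Two benchmark generators exist besides the transplant study. The
selection-recovery benchmark uses an *additive* linear fitness surface
(w = 1 + Σβz + ε) where OLS is exactly unbiased, isolating estimator
behavior from surface curvature. The CWM-optimality benchmark offsets each
site's population mean from a CWM target by a known signed amount, makes
fitness a Gaussian peak at the CWM, and adds mean-centered noise that is
*scaled* common random draws — each site × trait selection differential is
then exactly linear in the noise scale, so consistency with the CWM
direction degrades monotonically in noise by construction (at high noise a
few simulated fitness values may go non-positive; this is harmless for the
covariance-based S but is why the benchmark is not a demographic model).

**What the simulations do not emulate:** spatial autocorrelation and
microsite heterogeneity beyond the block deviate, non-additive
trait–environment interactions on the raw scale, correlated trait residuals
within individuals, informative missingness (the optional trait mask is
MCAR), overwinter mortality that depends on traits, and multi-year
demography. Passing recovery tests therefore shows the estimators are
correct under the stated model, not that field data meet the model.

## Problem sizes and numerical choices

The stochastic checks use 20 seeds of the full 504-plant design for %E
recovery, 100 replicates of n = 300 for selection-gradient recovery, and
3 × 18 site × trait cells per noise level for the optimality curve — sizes
at which the Monte-Carlo error is far smaller than the margins being
tested. Least-squares fits use `numpy.linalg.lstsq`; rank deficiency is
detected before fitting and reported with the aliased terms named. Marginal
SS that come out slightly negative by floating-point cancellation are
clipped at zero after a tolerance check (1e-8). Abundance rows off 1 by
≤ 1e-6 are renormalized silently, larger deviations with a warning, and
all-zero rows are errors.
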