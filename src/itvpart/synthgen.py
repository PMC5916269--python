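"""Synthetic reciprocal-transplant and community data with known ground truth.

The transplant generator reproduces the structure of a reciprocal transplant
of a perennial understory herb between two transects and three elevations
(low ~715 m, mid ~870 m, high ~1,040 m a.s.l.): plants from each origin
elevation are grown at every elevation of their own transect, split over
four blocks per transplant site with seven individuals per origin per block.
Traits are generated additively on the analysis (transformed) scale —
grand mean + plastic effect of the transplant elevation + genetic effect of
the origin elevation + G×E + transect + block deviate + an initial-biomass
covariate term + residual noise — then back-transformed, so the downstream
linear model is exactly the generating model and every variance component
has a known truth.  Survival is Bernoulli on a logistic scale; final dry
biomass (the fitness proxy) is lognormal in within-site standardized traits
so the true standardized selection gradients are known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cwm import CommunityDataset

__all__ = [
    "DesignSpec",
    "SimulationParams",
    "default_params",
    "plastic_only",
    "genetic_only",
    "simulate_transplant",
    "simulate_community",
    "simulate_selection_dataset",
    "simulate_optimality_study",
    "TRAIT_TRANSFORMS",
]

#: analysis-scale transform per default trait (see partition.apply_transform)
TRAIT_TRANSFORMS = {"height": "sqrt", "leaf_area": "log", "sla": "log"}

_FORWARD = {"sqrt": np.sqrt, "log": np.log, "identity": lambda x: x}
_INVERSE = {"sqrt": np.square, "log": np.exp, "identity": lambda x: x}


@dataclass(frozen=True)
class DesignSpec:
    """The transplant design grid.

    Every (transect, transplant-elevation) site holds ``blocks_per_site``
    blocks, each with ``individuals_per_origin_per_block`` plants from every
    origin elevation of the same transect; origins never cross transects.
    """

    transects: tuple[str, ...] = ("south", "north")
    elevations: tuple[str, ...] = ("low", "mid", "high")
    elevation_meters: dict[str, float] = field(
        default_factory=lambda: {"low": 715.0, "mid": 870.0, "high": 1040.0}
    )
    blocks_per_site: int = 4
    individuals_per_origin_per_block: int = 7

    def __post_init__(self) -> None:
        if self.blocks_per_site < 1 or self.individuals_per_origin_per_block < 1:
            raise ValueError("block and individual counts must be positive")
        if len(set(self.elevations)) < 2:
            raise ValueError("need at least two elevation levels")

    @property
    def n_sites(self) -> int:
        return len(self.transects) * len(self.elevations)

    @property
    def n_total(self) -> int:
        # transect × EL_T × block × EL_O × individuals
        return (
            self.n_sites
            * self.blocks_per_site
            * len(self.elevations)
            * self.individuals_per_origin_per_block
        )


@dataclass
class SimulationParams:
    """All generative effect sizes and noise scales for the transplant study.

    Effects live on the transformed trait scale (sqrt mm for height, log
    mm² / log mm²·mg⁻¹ for leaf area and SLA).  ``fitness_beta`` holds the
    true standardized selection gradients wired into the lognormal fitness
    surface.  A single integer ``seed`` determines every sub-stream.
    """

    design: DesignSpec
    trait_names: tuple[str, ...]
    grand_mean: dict[str, float]
    plastic_effect: dict[str, dict[str, float]]
    genetic_effect: dict[str, dict[str, float]]
    gxe_effect: dict[str, dict[tuple[str, str], float]]
    transect_effect: dict[str, float]
    block_sd: dict[str, float]
    residual_sd: dict[str, float]
    init_biomass_mean: float
    init_biomass_sd: float
    covariate_slope: dict[str, float]
    survival_logit_intercept: float
    survival_logit_offsets: dict[tuple[str, str, str], float]
    fitness_beta: dict[str, float]
    fitness_noise_sd: float
    final_biomass_mean: float
    winter_shock_fraction: float = 0.0
    missing_rate: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        d = self.design
        for trait in self.trait_names:
            for table, keyset in (
                (self.plastic_effect, d.elevations),
                (self.genetic_effect, d.elevations),
            ):
                if trait not in table:
                    raise ValueError(f"effect table missing trait {trait!r}")
                missing = set(keyset) - set(table[trait])
                if missing:
                    raise ValueError(
                        f"effect table for {trait!r} missing levels {sorted(missing)}"
                    )
                for v in table[trait].values():
                    if not math.isfinite(v):
                        raise ValueError(f"non-finite effect for {trait!r}")
            if self.block_sd.get(trait, 0.0) < 0:
                raise ValueError(f"negative block_sd for {trait!r}")
            sd = self.residual_sd.get(trait, 0.0)
            if not math.isfinite(sd) or sd < 0:
                raise ValueError(f"residual_sd for {trait!r} must be finite and >= 0")
        if self.init_biomass_sd < 0 or self.fitness_noise_sd < 0:
            raise ValueError("sd parameters must be non-negative")
        if not (0.0 <= self.winter_shock_fraction < 1.0):
            raise ValueError("winter_shock_fraction must be in [0, 1)")
        for trait, rate in self.missing_rate.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing_rate for {trait!r} must be in [0, 1)")


def default_params(seed: int = 0, **overrides) -> SimulationParams:
    """Defaults sized like the field study they emulate.

    Residual standard deviations on the transformed scale follow the
    magnitudes observed in the published transplant ANOVA (height ≈ 1.05 on
    the sqrt-mm scale, leaf area ≈ 0.52 and SLA ≈ 0.19 on the log scale);
    plastic elevation steps are ~0.7 residual sd, genetic steps ~0.25, so
    plasticity dominates the elevational signal as observed in the field.
    Traits decrease from low to high elevation.  Survival is ~80%; final dry
    biomass averages 0.35 g with leaf area under the strongest selection.
    """
    design = DesignSpec()
    p = SimulationParams(
        design=design,
        trait_names=("height", "leaf_area", "sla"),
        grand_mean={"height": 7.7, "leaf_area": 6.1, "sla": 3.4},
        plastic_effect={
            "height": {"low": 0.75, "mid": 0.0, "high": -0.75},
            "leaf_area": {"low": 0.36, "mid": 0.0, "high": -0.36},
            "sla": {"low": 0.13, "mid": 0.0, "high": -0.13},
        },
        genetic_effect={
            "height": {"low": 0.26, "mid": 0.0, "high": -0.26},
            "leaf_area": {"low": 0.13, "mid": 0.0, "high": -0.13},
            "sla": {"low": 0.047, "mid": 0.0, "high": -0.047},
        },
        gxe_effect={t: {} for t in ("height", "leaf_area", "sla")},
        transect_effect={"height": 0.4, "leaf_area": 0.05, "sla": 0.05},
        block_sd={"height": 0.3, "leaf_area": 0.13, "sla": 0.05},
        residual_sd={"height": 1.05, "leaf_area": 0.52, "sla": 0.19},
        init_biomass_mean=0.25,
        init_biomass_sd=0.08,
        covariate_slope={"height": 1.5, "leaf_area": 0.8, "sla": 0.3},
        survival_logit_intercept=1.4,
        survival_logit_offsets={},
        fitness_beta={"height": 0.10, "leaf_area": 0.45, "sla": -0.15},
        fitness_noise_sd=0.5,
        final_biomass_mean=0.35,
        seed=seed,
    )
    if overrides:
        p = replace(p, **overrides)
    return p


def _zero_effects(params: SimulationParams, which: str) -> SimulationParams:
    table = {t: {lv: 0.0 for lv in params.design.elevations} for t in params.trait_names}
    return replace(params, **{which: table})


def plastic_only(seed: int = 0) -> SimulationParams:
    """Default conditions with the genetic (origin) effects switched off.

    The elevational signal sits entirely on the transplant channel, at the
    default plastic magnitudes.
    """
    return _zero_effects(default_params(seed), "genetic_effect")


def genetic_only(seed: int = 0) -> SimulationParams:
    """Default conditions with the elevational signal moved to the origin channel.

    The mirror image of :func:`plastic_only`: plastic effects are zeroed and
    the genetic effects take the default *plastic* magnitudes, so the two
    recovery benchmarks carry equal signal on opposite channels.
    """
    p = default_params(seed)
    p = replace(p, genetic_effect={t: dict(v) for t, v in p.plastic_effect.items()})
    return _zero_effects(p, "plastic_effect")


def simulate_transplant(params: SimulationParams) -> pd.DataFrame:
    """Generate one realization of the transplant study.

    Returns one row per individual with design factors (``transect``,
    ``elevation_origin``, ``elevation_transplant``, ``block``), the
    initial-biomass covariate, survival, final biomass (NaN for
    non-survivors) and raw-scale trait values.  Identical seeds give
    byte-identical frames.
    """
    params.validate()
    d = params.design
    ss = np.random.SeedSequence(params.seed)
    rng_init, rng_block, rng_resid, rng_surv, rng_fit, rng_miss, rng_shock = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )

    rows = []
    uid = 0
    for transect in d.transects:
        for el_t in d.elevations:
            for block in range(1, d.blocks_per_site + 1):
                for el_o in d.elevations:
                    for _ in range(d.individuals_per_origin_per_block):
                        uid += 1
                        rows.append((f"ind{uid:04d}", transect, el_o, el_t, block))
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "transect", "elevation_origin",
                 "elevation_transplant", "block"],
    )
    n = len(df)
    assert n == d.n_total

    init = rng_init.normal(params.init_biomass_mean, params.init_biomass_sd, n)
    init = np.clip(init, 1e-3, None)  # biomass is strictly positive
    df["init_biomass"] = init

    # one block deviate per (trait, transect, EL_T, block)
    block_dev = {
        trait: {
            (tr, et, b): rng_block.normal(0.0, params.block_sd.get(trait, 0.0))
            for tr in d.transects
            for et in d.elevations
            for b in range(1, d.blocks_per_site + 1)
        }
        for trait in params.trait_names
    }
    tsign = {tr: (1.0 if i == 0 else -1.0) for i, tr in enumerate(d.transects)}

    for trait in params.trait_names:
        eff = (
            np.array([params.plastic_effect[trait][e] for e in df["elevation_transplant"]])
            + np.array([params.genetic_effect[trait][e] for e in df["elevation_origin"]])
            + np.array(
                [
                    params.gxe_effect.get(trait, {}).get((o, t), 0.0)
                    for o, t in zip(df["elevation_origin"], df["elevation_transplant"])
                ]
            )
            + np.array([tsign[tr] * params.transect_effect.get(trait, 0.0) for tr in df["transect"]])
            + np.array(
                [
                    block_dev[trait][(tr, et, b)]
                    for tr, et, b in zip(df["transect"], df["elevation_transplant"], df["block"])
                ]
            )
        )
        transformed = (
            params.grand_mean[trait]
            + eff
            + params.covariate_slope.get(trait, 0.0) * (init - params.init_biomass_mean)
            + rng_resid.normal(0.0, params.residual_sd[trait], n)
        )
        transform = TRAIT_TRANSFORMS.get(trait, "identity")
        df[trait] = _INVERSE[transform](transformed)

    logit = params.survival_logit_intercept + np.array(
        [
            params.survival_logit_offsets.get((tr, o, t), 0.0)
            for tr, o, t in zip(df["transect"], df["elevation_origin"], df["elevation_transplant"])
        ]
    )
    p_surv = 1.0 / (1.0 + np.exp(-logit))
    df["survived"] = rng_surv.random(n) < p_surv

    # lognormal fitness in within-site standardized traits, rescaled so each
    # site's mean final biomass equals final_biomass_mean exactly
    df["final_biomass"] = np.nan
    for (_, _), idx in df.groupby(["transect", "elevation_transplant"]).groups.items():
        alive = df.loc[idx].index[df.loc[idx, "survived"]]
        if len(alive) < 2:
            continue
        lin = np.zeros(len(alive))
        for trait in params.trait_names:
            x = df.loc[alive, trait].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                continue
            lin += params.fitness_beta.get(trait, 0.0) * (x - x.mean()) / sd
        lin = lin + rng_fit.normal(0.0, params.fitness_noise_sd, len(alive))
        w = np.exp(lin)
        df.loc[alive, "final_biomass"] = params.final_biomass_mean * w / w.mean()

    for trait, rate in params.missing_rate.items():
        if rate > 0:
            mask = rng_miss.random(n) < rate
            df.loc[mask, trait] = np.nan

    if params.winter_shock_fraction > 0:
        keep = rng_shock.random(n) >= params.winter_shock_fraction
        df = df.loc[keep].reset_index(drop=True)

    return df


def simulate_community(
    n_sites: int,
    species_pool: list[str],
    gradient: np.ndarray | None = None,
    itv_slopes: dict[str, float] | None = None,
    abundance_model: str | np.ndarray = "gaussian",
    noise_sd: float = 0.0,
    seed: int = 0,
    species_means: dict[str, float] | None = None,
    niche_width: float | None = None,
) -> CommunityDataset:
    """Generate a community dataset along a gradient.

    Species follow Gaussian niche responses to the gradient (optima evenly
    spaced over its span), renormalized to relative abundances per site.
    Site-specific trait values are ``x̄_i + itv_slope_i·g_j + noise``, so a
    zero slope and zero noise give a community with no intraspecific trait
    variation.  ``abundance_model`` may also be a precomputed site × species
    weight matrix.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be at least 2")
    if not species_pool:
        raise ValueError("species_pool must be non-empty")
    k = len(species_pool)
    rng = np.random.default_rng(seed)
    g = np.linspace(0.0, 1.0, n_sites) if gradient is None else np.asarray(gradient, float)
    if len(g) != n_sites:
        raise ValueError("gradient length must equal n_sites")

    if isinstance(abundance_model, str):
        if abundance_model != "gaussian":
            raise ValueError(f"unknown abundance model {abundance_model!r}")
        span = g.max() - g.min()
        width = niche_width if niche_width is not None else (span / 2 if span > 0 else 1.0)
        optima = (
            np.linspace(g.min(), g.max(), k) if k > 1 else np.array([(g.min() + g.max()) / 2])
        )
        weights = np.exp(-0.5 * ((g[:, None] - optima[None, :]) / width) ** 2)
    else:
        weights = np.asarray(abundance_model, dtype=float)
        if weights.shape != (n_sites, k):
            raise ValueError("abundance weight matrix must be n_sites × n_species")
        if (weights < 0).any():
            raise ValueError("abundance weights must be non-negative")
    rowsum = weights.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError("all-zero abundance row: cannot renormalize")
    p = weights / rowsum[:, None]

    if species_means is None:
        species_means = {sp: v for sp, v in zip(species_pool, np.linspace(10.0, 20.0, k))}
    slopes = {sp: 0.0 for sp in species_pool}
    if itv_slopes:
        slopes.update(itv_slopes)
    x = np.empty((n_sites, k))
    for j, sp in enumerate(species_pool):
        x[:, j] = species_means[sp] + slopes[sp] * g + rng.normal(0.0, noise_sd, n_sites)

    site_ids = [f"s{j+1:02d}" for j in range(n_sites)]
    sites = pd.DataFrame({"site": site_ids, "gradient": g})
    abundance = pd.DataFrame(p, index=site_ids, columns=species_pool)
    traits = {"trait": pd.DataFrame(x, index=site_ids, columns=species_pool)}
    return CommunityDataset(sites=sites, abundance=abundance, traits=traits)


def simulate_selection_dataset(
    beta: np.ndarray,
    n: int = 300,
    noise_sd: float = 0.1,
    trait_corr: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Benchmark dataset with an additive linear fitness surface.

    Traits are multivariate normal (optionally correlated); relative fitness
    is ``w = 1 + Σ β_j z_j + ε`` with ``ε ~ N(0, noise_sd)``, so the true
    standardized linear selection gradients are exactly ``beta``.  Returns a
    frame with columns ``trait_1..k`` and ``fitness`` plus the true beta.
    """
    beta = np.asarray(beta, dtype=float)
    k = len(beta)
    rng = np.random.default_rng(seed)
    if trait_corr is None:
        z = rng.normal(size=(n, k))
    else:
        L = np.linalg.cholesky(np.asarray(trait_corr, float))
        z = rng.normal(size=(n, k)) @ L.T
    zs = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    w = 1.0 + zs @ beta + rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame(z, columns=[f"trait_{j+1}" for j in range(k)])
    df["fitness"] = w
    return df, beta


def simulate_optimality_study(
    noise_scale: float,
    n_sites: int = 6,
    n_traits: int = 3,
    n_per_site: int = 80,
    peak_width: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fitness peaked at the community-weighted mean, with scalable noise.

    Each site's population trait mean is offset from the site CWM by a known
    signed amount; fitness is a Gaussian function of the standardized
    distance to the CWM plus mean-centered additive noise scaled by
    ``noise_scale``.  Because the same noise draws are reused at every
    scale (common random numbers) and the noise enters fitness additively
    with a fixed site mean, each site × trait selection differential is an
    exactly linear function of ``noise_scale`` — so the consistency of
    selection with the CWM direction degrades monotonically as noise grows.

    Returns ``(records, cwm_table)`` where records hold per-individual
    traits and fitness and cwm_table holds the site × trait CWM targets.
    """
    rng = np.random.default_rng(seed)
    sites = [f"site{j+1}" for j in range(n_sites)]
    traits = [f"trait_{t+1}" for t in range(n_traits)]
    records = []
    cwm_rows = []
    for j, site in enumerate(sites):
        x = rng.normal(0.0, 1.0, size=(n_per_site, n_traits))
        # signed offsets of the CWM from the population mean, fixed per cell
        offsets = rng.choice([-1.0, 1.0], size=n_traits) * rng.uniform(0.4, 1.0, n_traits)
        cwm = x.mean(axis=0) + offsets
        dist2 = ((x - cwm) ** 2 / peak_width**2).sum(axis=1)
        base = np.exp(-0.5 * dist2)
        eps = rng.normal(0.0, 1.0, n_per_site)
        eps -= eps.mean()  # keeps site mean fitness independent of the scale
        fitness = base + noise_scale * eps
        for i in range(n_per_site):
            rec = {"site": site, "fitness": fitness[i]}
            rec.update({tr: x[i, t] for t, tr in enumerate(traits)})
            records.append(rec)
        for t, tr in enumerate(traits):
            cwm_rows.append({"site": site, "trait": tr, "cwm": cwm[t]})
    return pd.DataFrame(records), pd.DataFrame(cwm_rows)
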