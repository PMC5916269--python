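"""Phenotypic selection analysis within transplant sites.

Selection on each trait is measured two ways, following the classical
regression approach to selection on correlated characters.  The standardized
selection differential

    S = cov(w, z)

is the covariance between relative fitness ``w`` (individual fitness over
the site mean — here final dry biomass among survivors) and the
within-site standardized trait ``z``; it captures total selection, direct
plus indirect through correlated traits.  The standardized selection
gradients ``β`` are the partial coefficients of the multiple regression of
``w`` on all traits jointly, isolating direct selection on each.  The two
are linked by the exact identity ``S = R β̂`` where ``R`` is the sample
trait correlation matrix.

A site's population can then be asked whether selection points toward the
local community-weighted mean (CWM): if CWM values are adaptive optima,
``sign(S)`` should match ``sign(CWM − population mean)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_fitness",
    "standardize_traits",
    "selection_differential",
    "selection_gradients",
    "cwm_optimality",
    "full_lande_arnold",
]


def relative_fitness(W: np.ndarray | pd.Series) -> np.ndarray:
    """Relative fitness w = W / mean(W); mean(w) = 1 exactly."""
    W = np.asarray(W, dtype=float)
    if len(W) < 2:
        raise ValueError("need at least 2 individuals with a fitness measure")
    m = W.mean()
    if m <= 0:
        raise ValueError("non-positive mean fitness; cannot relativize")
    return W / m


def standardize_traits(x: np.ndarray | pd.Series) -> np.ndarray:
    """z = (x − mean)/sd with the sample sd (n−1 denominator)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("zero trait variance; cannot standardize")
    return (x - x.mean()) / sd


def selection_differential(w: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Standardized selection differential and its significance.

    S is the sample covariance (n−1) between relative fitness and the
    standardized trait; the p-value is the two-sided Pearson correlation
    test on the same pair.  With constant fitness the correlation (hence p)
    is undefined and returned as NaN.
    """
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(w) != len(z):
        raise ValueError("w and z must be paired")
    ok = np.isfinite(w) & np.isfinite(z)
    w, z = w[ok], z[ok]
    if len(w) < 3:
        raise ValueError("need at least 3 complete pairs")
    S = float(np.cov(w, z, ddof=1)[0, 1])
    if w.std(ddof=1) == 0 or z.std(ddof=1) == 0:
        return S, float("nan")
    r = stats.pearsonr(w, z)
    return S, float(r.pvalue)


def selection_gradients(
    w: np.ndarray, Z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Standardized linear selection gradients by multiple regression.

    OLS of relative fitness on all standardized traits jointly; returns
    (β, se, two-sided p, adjusted R²).  Rank deficiency is an error naming
    the collinear trait pairs.
    """
    import statsmodels.api as sm

    w = np.asarray(w, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    if np.linalg.matrix_rank(Z) < k:
        corr = np.corrcoef(Z, rowvar=False)
        pairs = [
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"collinear traits (column pairs): {pairs}")
    X = sm.add_constant(Z)
    res = sm.OLS(w, X).fit()
    return (
        np.asarray(res.params[1:]),
        np.asarray(res.bse[1:]),
        np.asarray(res.pvalues[1:]),
        float(res.rsquared_adj),
    )


def full_lande_arnold(
    records: pd.DataFrame,
    traits: list[str],
    site_cols: tuple[str, ...] = ("transect", "elevation_transplant"),
    fitness: str = "final_biomass",
) -> pd.DataFrame:
    """Per-site selection differentials and gradients.

    Filters to individuals with a fitness measure (survivors), relativizes
    fitness and standardizes traits within each site, computes S with its
    Pearson p per trait, and fits the joint gradient model.  Returns one row
    per site × trait with the per-site model's adjusted R² and sample size
    attached.
    """
    site_cols = [c for c in site_cols if c in records.columns]
    if not site_cols:
        raise ValueError("no site columns present")
    rows = []
    for site, grp in records.groupby(site_cols, sort=True):
        site_id = ":".join(map(str, site)) if isinstance(site, tuple) else str(site)
        sub = grp.dropna(subset=[fitness] + list(traits))
        if len(sub) < len(traits) + 2:
            raise ValueError(
                f"site {site_id}: n={len(sub)} too small for {len(traits)} traits"
            )
        try:
            w = relative_fitness(sub[fitness])
            Z = np.column_stack([standardize_traits(sub[t]) for t in traits])
        except ValueError as err:
            raise ValueError(f"site {site_id}: {err}") from err
        beta, se, pb, adj_r2 = selection_gradients(w, Z)
        for j, trait in enumerate(traits):
            S, pS = selection_differential(w, Z[:, j])
            rows.append(
                {
                    "site": site_id,
                    **{c: v for c, v in zip(site_cols, site if isinstance(site, tuple) else (site,))},
                    "trait": trait,
                    "S": S,
                    "p_S": pS,
                    "beta": beta[j],
                    "se_beta": se[j],
                    "p_beta": pb[j],
                    "adj_r2": adj_r2,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OptimalityCheck:
    """Per site × trait agreement between selection and the CWM direction."""

    table: pd.DataFrame
    consistency_fraction: float  # over determinate cells
    n_indeterminate: int


def cwm_optimality(
    selection_results: pd.DataFrame,
    cwm_table: pd.DataFrame,
    population_means: pd.DataFrame,
) -> OptimalityCheck:
    """Does selection point toward the community-weighted mean?

    For each site × trait, compares ``sign(S)`` with ``sign(CWM − local
    population mean)``; the two must be supplied on the same trait scale.
    Exact zeros on either side are scored indeterminate and excluded from
    the summary fraction.

    ``cwm_table`` and ``population_means`` are long tables with columns
    (site, trait, cwm) and (site, trait, pop_mean).
    """
    for df, col in ((cwm_table, "cwm"), (population_means, "pop_mean")):
        missing = {"site", "trait", col} - set(df.columns)
        if missing:
            raise ValueError(f"table missing columns {sorted(missing)}")
    if "scale" in cwm_table.columns and "scale" in population_means.columns:
        merged_scales = cwm_table.merge(population_means, on=["site", "trait"])
        if (merged_scales["scale_x"] != merged_scales["scale_y"]).any():
            raise ValueError("CWM and population means declare different trait scales")
    tab = (
        selection_results[["site", "trait", "S"]]
        .merge(cwm_table[["site", "trait", "cwm"]], on=["site", "trait"])
        .merge(population_means[["site", "trait", "pop_mean"]], on=["site", "trait"])
    )
    tab["delta"] = tab["cwm"] - tab["pop_mean"]
    sign_s = np.sign(tab["S"])
    sign_d = np.sign(tab["delta"])
    indeterminate = (sign_s == 0) | (sign_d == 0)
    tab["consistent"] = np.where(indeterminate, np.nan, sign_s == sign_d)
    determinate = tab.loc[~indeterminate, "consistent"]
    frac = float(determinate.mean()) if len(determinate) else float("nan")
    return OptimalityCheck(
        table=tab, consistency_fraction=frac, n_indeterminate=int(indeterminate.sum())
    )
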