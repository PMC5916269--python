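"""Community-weighted mean (CWM) trait turnover and its decomposition.

A community's mean trait value along a gradient can change for two reasons:
the species present (and their abundances) change — species turnover, SPT —
or the individuals of each species change their trait values from site to
site — intraspecific trait variation, ITV.  Computing the CWM twice, once
with site-specific ("specific") trait values and once with gradient-wide
species means ("fixed"), and decomposing the variance of the two series plus
their difference, separates the two contributions and their covariation.

The decomposition is an exact sum-of-squares identity:

    SS_specific = SS_fixed + SS_intra + SS_cov

where ``SS_cov`` (which may be negative) absorbs the covariation between the
turnover and intraspecific components.  Shares are reported on the
gradient-explained sums of squares, i.e. the part of each series a linear
(or one-way factor) model of the gradient accounts for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityDataset",
    "CwmDecomposition",
    "compute_cwm",
    "decompose",
]


@dataclass
class CommunityDataset:
    """Site-by-species abundances plus site-specific trait values.

    Parameters
    ----------
    sites : pd.DataFrame
        One row per site with columns ``site`` and ``gradient`` (numeric
        position along the gradient, e.g. elevation in m) and optionally
        ``transect``.
    abundance : pd.DataFrame
        Site × species relative abundances (rows indexed by site id,
        columns by species).  Each row must sum to 1.
    traits : dict[str, pd.DataFrame]
        Per trait, a site × species table of site-specific trait values
        (same shape as ``abundance``; NaN where unmeasured).
    species_means : dict[str, pd.Series]
        Per trait, gradient-wide species mean trait values indexed by
        species.  If omitted they are computed abundance-weighted across
        sites (``mean_weighting='abundance'``) or unweighted.
    """

    sites: pd.DataFrame
    abundance: pd.DataFrame
    traits: dict[str, pd.DataFrame]
    species_means: dict[str, pd.Series] = field(default_factory=dict)
    mean_weighting: str = "abundance"

    def __post_init__(self) -> None:
        if "site" not in self.sites.columns or "gradient" not in self.sites.columns:
            raise ValueError("sites table requires 'site' and 'gradient' columns")
        self.sites = self.sites.reset_index(drop=True)
        order = list(self.sites["site"])
        self.abundance = self.abundance.loc[order]
        if (self.abundance.values < 0).any():
            raise ValueError("negative abundance")
        rowsum = self.abundance.sum(axis=1)
        if (rowsum == 0).any():
            bad = list(rowsum.index[rowsum == 0])
            raise ValueError(f"all-zero abundance row at site(s) {bad}: cannot renormalize")
        if not np.allclose(rowsum, 1.0, rtol=0, atol=1e-9):
            if not np.allclose(rowsum, 1.0, rtol=0, atol=1e-6):
                warnings.warn(
                    "site abundances do not sum to 1; renormalizing", stacklevel=2
                )
            self.abundance = self.abundance.div(rowsum, axis=0)
        self.traits = {t: x.loc[order] for t, x in self.traits.items()}
        for trait in self.traits:
            if trait not in self.species_means:
                self.species_means[trait] = self._gradient_means(trait)

    def _gradient_means(self, trait: str) -> pd.Series:
        """Species mean trait values across the gradient.

        Defaults to abundance-weighting the site-specific values; the
        unweighted per-species average is available via
        ``mean_weighting='unweighted'``.
        """
        x = self.traits[trait]
        if self.mean_weighting == "unweighted":
            return x.mean(axis=0)
        w = self.abundance.where(x.notna(), 0.0)
        num = (w * x.fillna(0.0)).sum(axis=0)
        den = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            means = num / den
        return means

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def gradient(self) -> np.ndarray:
        return self.sites["gradient"].to_numpy(dtype=float)


@dataclass
class CwmDecomposition:
    """Sum-of-squares decomposition of CWM turnover for one trait."""

    trait: str
    ss_specific: float
    ss_fixed: float
    ss_intra: float
    ss_cov: float
    ss_specific_total: float
    ss_fixed_total: float
    ss_intra_total: float
    ss_cov_total: float
    itv_share: float  # percent, on gradient-explained SS
    spt_share: float
    itv_share_total: float
    spt_share_total: float
    cwm_specific: pd.Series = field(repr=False, default=None)
    cwm_fixed: pd.Series = field(repr=False, default=None)
    cwm_intra: pd.Series = field(repr=False, default=None)

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "ss_specific": self.ss_specific,
            "ss_fixed": self.ss_fixed,
            "ss_intra": self.ss_intra,
            "ss_cov": self.ss_cov,
            "ss_specific_total": self.ss_specific_total,
            "ss_fixed_total": self.ss_fixed_total,
            "ss_intra_total": self.ss_intra_total,
            "ss_cov_total": self.ss_cov_total,
            "itv_share": self.itv_share,
            "spt_share": self.spt_share,
            "itv_share_total": self.itv_share_total,
            "spt_share_total": self.spt_share_total,
        }


def compute_cwm(
    dataset: CommunityDataset,
    mode: str = "specific",
    trait: str | None = None,
    missing_policy: str = "strict",
) -> pd.Series:
    """Per-site community-weighted mean of one trait.

    ``CWM_j = Σ_i p_ij x_ij`` in ``specific`` mode (site-local trait
    values) or ``Σ_i p_ij x̄_i`` in ``fixed`` mode (gradient-wide species
    means).  Under the default strict policy a species that is present at a
    site but has no usable trait value is an error; ``missing_policy=
    'substitute'`` falls back to the species gradient-wide mean with a
    warning.
    """
    if mode not in ("specific", "fixed"):
        raise ValueError(f"mode must be 'specific' or 'fixed', got {mode!r}")
    if trait is None:
        if len(dataset.traits) != 1:
            raise ValueError("trait must be named when the dataset holds several")
        trait = next(iter(dataset.traits))
    p = dataset.abundance
    xbar = dataset.species_means[trait]
    if mode == "fixed":
        x = pd.DataFrame(
            np.broadcast_to(xbar.to_numpy(dtype=float), p.shape),
            index=p.index,
            columns=p.columns,
        )
    else:
        x = dataset.traits[trait].astype(float)
        missing = x.isna() & (p > 0)
        if missing.values.any():
            rows, cols = np.nonzero(missing.values)
            cells = [(missing.index[r], missing.columns[c]) for r, c in zip(rows, cols)]
            if missing_policy == "strict":
                raise ValueError(
                    f"missing trait value(s) for present species ({trait}): {cells}"
                )
            warnings.warn(
                f"substituting gradient-wide means for {len(cells)} missing "
                f"site-specific value(s) of {trait}",
                stacklevel=2,
            )
            x = x.where(~missing, np.broadcast_to(xbar.to_numpy(dtype=float), x.shape))
    contrib = (p * x.fillna(0.0)).sum(axis=1)
    contrib.name = f"cwm_{mode}_{trait}"
    return contrib


def _explained_ss(y: np.ndarray, g: np.ndarray, model: str) -> tuple[float, float]:
    """Total SS about the mean and the part a gradient model explains.

    ``model='linear'`` fits simple linear regression on the numeric
    gradient; ``model='factor'`` treats each distinct gradient value as a
    level of a one-way classification (its explained SS is the classical
    between-group SS).
    """
    ybar = y.mean()
    ss_total = float(((y - ybar) ** 2).sum())
    if model == "factor":
        fitted = np.empty_like(y, dtype=float)
        for val in np.unique(g):
            m = g == val
            fitted[m] = y[m].mean()
    elif model == "linear":
        X = np.column_stack([np.ones_like(g, dtype=float), g.astype(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
    else:
        raise ValueError(f"unknown gradient model {model!r}")
    ss_resid = float(((y - fitted) ** 2).sum())
    return ss_total, ss_total - ss_resid


def decompose(
    dataset: CommunityDataset,
    trait: str | None = None,
    model: str = "linear",
    missing_policy: str = "strict",
) -> CwmDecomposition:
    """Decompose CWM turnover along the gradient into SPT, ITV and covariation.

    The intraspecific series is ``CWM_specific − CWM_fixed`` per site.  Each
    of the three series is regressed on the gradient; explained and total
    sums of squares are recorded and the covariation term is the exact
    remainder ``SS_specific − SS_fixed − SS_intra`` (same identity on the
    explained and total scales).  The ITV share is
    ``100·SS_intra/(SS_intra + SS_fixed)`` on the explained components —
    the relative explanatory power of intraspecific shifts versus species
    turnover — with total-variance shares also reported.
    """
    if trait is None:
        if len(dataset.traits) != 1:
            raise ValueError("trait must be named when the dataset holds several")
        trait = next(iter(dataset.traits))
    n_sites = len(dataset.sites)
    if n_sites < 2:
        raise ValueError(f"decomposition needs at least 2 sites, got {n_sites}")
    g = dataset.gradient
    cwm_s = compute_cwm(dataset, "specific", trait, missing_policy)
    cwm_f = compute_cwm(dataset, "fixed", trait)
    cwm_i = cwm_s - cwm_f
    cwm_i.name = f"cwm_intra_{trait}"

    tot_s, exp_s = _explained_ss(cwm_s.to_numpy(), g, model)
    tot_f, exp_f = _explained_ss(cwm_f.to_numpy(), g, model)
    tot_i, exp_i = _explained_ss(cwm_i.to_numpy(), g, model)
    cov_exp = exp_s - exp_f - exp_i
    cov_tot = tot_s - tot_f - tot_i

    def shares(intra: float, fixed: float) -> tuple[float, float]:
        den = intra + fixed
        if den <= 0:
            return float("nan"), float("nan")
        itv = 100.0 * intra / den
        return itv, 100.0 - itv

    itv_e, spt_e = shares(exp_i, exp_f)
    itv_t, spt_t = shares(tot_i, tot_f)
    return CwmDecomposition(
        trait=trait,
        ss_specific=exp_s,
        ss_fixed=exp_f,
        ss_intra=exp_i,
        ss_cov=cov_exp,
        ss_specific_total=tot_s,
        ss_fixed_total=tot_f,
        ss_intra_total=tot_i,
        ss_cov_total=cov_tot,
        itv_share=itv_e,
        spt_share=spt_e,
        itv_share_total=itv_t,
        spt_share_total=spt_t,
        cwm_specific=cwm_s,
        cwm_fixed=cwm_f,
        cwm_intra=cwm_i,
    )
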