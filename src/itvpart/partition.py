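"""Partitioning plastic (E) and genetic (G) sources of intraspecific variation.

A reciprocal transplant separates the two intraspecific drivers of a trait:
variation explained by the elevation where a plant was *grown* (EL_T) is
plasticity, variation explained by the elevation it *came from* (EL_O) is
genetic differentiation, and their interaction — higher fitness of locals at
home — is the signature of local adaptation.  The per-trait linear model is

    trait ~ EL_O + EL_T + EL_O:EL_T + transect + block(transect:EL_T) + init_biomass

fit with sum-to-zero factor coding so that type III (marginal) sums of
squares are meaningful on the unbalanced design.  Block is a fixed factor
nested in transect × transplant elevation.  The headline statistic is the
plasticity share

    %E = 100 · SS_E / (SS_E + SS_G)

with the G×E sum of squares reported but excluded from the ratio, since its
variation cannot be attributed to either source alone.

Survival (binary) is analyzed with a logit-link GLM and a type III analysis
of deviance; a deviance-scale %E analogue is available through the same
ratio on the deviance column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitTransform",
    "ModelSpec",
    "FittedModel",
    "PartitionResult",
    "LsmeansResult",
    "apply_transform",
    "fit_trait_model",
    "type3_anova",
    "sequential_anova",
    "percent_plasticity",
    "fit_survival_model",
    "lsmeans_pairwise",
    "fit_initial_biomass",
]

ELEVATION_ORDER = ("low", "mid", "high")

_TRANSFORMS = {
    "sqrt": (np.sqrt, lambda x: x < 0, "negative value under sqrt"),
    "log": (np.log, lambda x: x <= 0, "non-positive value under log"),
    "identity": (lambda x: x, lambda x: np.zeros(len(x), dtype=bool), ""),
}


@dataclass(frozen=True)
class TraitTransform:
    trait: str
    transform: str  # sqrt | log | identity

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class ModelSpec:
    """Term set of the per-trait model; defaults to the full transplant model."""

    response: str
    covariate: str | None = "init_biomass"
    include_interaction: bool = True
    include_transect: bool = True
    include_block: bool = True
    family: str = "gaussian"  # gaussian | binomial

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")


def apply_transform(
    records: pd.DataFrame, transform_map: dict[str, str], suffix: str = "_transformed"
) -> pd.DataFrame:
    """Add transformed trait columns; the originals are untouched.

    Domain violations (negative under sqrt, non-positive under log) raise
    with the offending ``individual_id`` rows named.
    """
    out = records.copy()
    for trait, name in transform_map.items():
        if isinstance(name, TraitTransform):
            name = name.transform
        fn, bad_fn, msg = _TRANSFORMS[name]
        x = out[trait].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = bad_fn(x) & ~np.isnan(x)
        if bad.any():
            ids = (
                list(out.loc[bad, "individual_id"])
                if "individual_id" in out.columns
                else list(out.index[bad])
            )
            raise ValueError(f"{msg} for trait {trait!r} in records {ids}")
        with np.errstate(divide="ignore", invalid="ignore"):
            out[trait + suffix] = fn(x)
    return out


# ---------------------------------------------------------------------------
# design matrix with sum-to-zero contrasts and a nested fixed block factor


def _sum_to_zero(levels: list, values: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) contrast columns for a factor."""
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    idx = {lv: i for i, lv in enumerate(levels)}
    code = values.map(idx).to_numpy()
    for j in range(k - 1):
        cols[code == j, j] = 1.0
        cols[code == k - 1, j] = -1.0
    return cols


def _ordered_levels(values: pd.Series) -> list:
    present = list(pd.unique(values))
    if set(present) <= set(ELEVATION_ORDER):
        return [lv for lv in ELEVATION_ORDER if lv in present]
    return sorted(present, key=str)


@dataclass
class FittedModel:
    """A least-squares or GLM fit carrying enough state for marginal tests."""

    spec: ModelSpec
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    term_slices: dict[str, list[int]]
    term_order: list[str]
    params: np.ndarray
    rss: float  # residual SS (gaussian) or deviance (binomial)
    df_resid: float
    n_obs: int
    scale: float  # residual mean square (gaussian) / 1.0 (binomial)
    cov_params: np.ndarray = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    covariate_mean: float | None = None
    factor_levels: dict[str, list] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def fitted_values(self) -> np.ndarray:
        eta = self.X @ self.params
        if self.spec.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    @property
    def total_ss(self) -> float:
        return float(((self.y - self.y.mean()) ** 2).sum())


def _build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, dict[str, list[int]], list[str], dict, float | None, list[str]]:
    warns: list[str] = []
    n = len(data)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    term_slices: dict[str, list[int]] = {"Intercept": [0]}
    term_order = ["Intercept"]
    pos = 1
    levels: dict[str, list] = {}

    def add_term(name: str, block: np.ndarray) -> None:
        nonlocal pos
        cols.append(block)
        term_slices[name] = list(range(pos, pos + block.shape[1]))
        term_order.append(name)
        pos += block.shape[1]

    lev_o = _ordered_levels(data["elevation_origin"])
    lev_t = _ordered_levels(data["elevation_transplant"])
    levels["EL_O"], levels["EL_T"] = lev_o, lev_t
    if len(lev_o) < 2 or len(lev_t) < 2:
        raise ValueError("elevation factors need at least 2 levels present in the data")
    C_o = _sum_to_zero(lev_o, data["elevation_origin"])
    C_t = _sum_to_zero(lev_t, data["elevation_transplant"])
    add_term("EL_O", C_o)
    add_term("EL_T", C_t)
    if spec.include_interaction:
        inter = np.einsum("ni,nj->nij", C_o, C_t).reshape(n, -1)
        add_term("EL_O:EL_T", inter)

    include_transect = spec.include_transect
    lev_r = _ordered_levels(data["transect"]) if "transect" in data.columns else []
    if include_transect and len(lev_r) < 2:
        warns.append("transect has fewer than 2 levels; dropping term R")
        warnings.warn(warns[-1], stacklevel=3)
        include_transect = False
    if include_transect:
        levels["R"] = lev_r
        add_term("R", _sum_to_zero(lev_r, data["transect"]))

    if spec.include_block and "block" in data.columns:
        # fixed block effects nested in transect × EL_T: sum-to-zero contrasts
        # among the blocks of each site, zero outside that site
        site_cols = ["transect", "elevation_transplant"] if "transect" in data.columns else ["elevation_transplant"]
        blocks = []
        for _, grp in data.groupby(site_cols, sort=True):
            blevels = sorted(pd.unique(grp["block"]), key=str)
            if len(blevels) < 2:
                continue
            sub = np.zeros((n, len(blevels) - 1))
            sub[data.index.get_indexer(grp.index), :] = _sum_to_zero(blevels, grp["block"])
            blocks.append(sub)
        if blocks:
            add_term("Block(R:EL_T)", np.hstack(blocks))
        else:
            warns.append("no site has 2+ blocks; dropping block term")
            warnings.warn(warns[-1], stacklevel=3)

    cov_mean = None
    if spec.covariate is not None and spec.covariate in data.columns:
        cov = data[spec.covariate].to_numpy(dtype=float)
        cov_mean = float(cov.mean())
        add_term("Init.biom", (cov - cov_mean)[:, None])

    X = np.hstack(cols)
    return X, term_slices, term_order, levels, cov_mean, warns


def _check_rank(X: np.ndarray, term_slices: dict[str, list[int]]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    aliased = []
    for term, idx in term_slices.items():
        if term == "Intercept":
            continue
        others = [j for j in range(X.shape[1]) if j not in idx]
        if np.linalg.matrix_rank(X) < np.linalg.matrix_rank(X[:, others]) + len(idx):
            aliased.append(term)
    raise ValueError(f"rank-deficient design; aliased terms: {aliased or 'unknown'}")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_trait_model(records: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Least-squares fit of the transplant model on the transformed response.

    Rows with a missing response or covariate are dropped (the design is
    analyzed as unbalanced).  Sum-to-zero factor coding throughout; block is
    a fixed factor nested in transect × EL_T.  Rank deficiency is an error
    naming the aliased terms.
    """
    needed = [spec.response, "elevation_origin", "elevation_transplant"]
    if spec.covariate:
        needed.append(spec.covariate)
    data = records.dropna(subset=[c for c in needed if c in records.columns])
    data = data.reset_index(drop=True)
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} not found")
    y = data[spec.response].to_numpy(dtype=float)
    X, term_slices, term_order, levels, cov_mean, warns = _build_design(data, spec)
    _check_rank(X, term_slices)
    beta, rss = _ols(X, y)
    df_resid = len(y) - X.shape[1]
    scale = rss / df_resid if df_resid > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    return FittedModel(
        spec=spec,
        X=X,
        y=y,
        term_slices=term_slices,
        term_order=term_order,
        params=beta,
        rss=rss,
        df_resid=df_resid,
        n_obs=len(y),
        scale=scale,
        cov_params=XtX_inv * (scale if np.isfinite(scale) else 0.0),
        data=data,
        covariate_mean=cov_mean,
        factor_levels=levels,
        warnings_=warns,
    )


def type3_anova(model: FittedModel) -> pd.DataFrame:
    """Type III (marginal) ANOVA table.

    Each term's SS is the increase in residual SS when that term alone is
    dropped from the full model — the partial SS appropriate for unbalanced
    designs under sum-to-zero coding.  F tests use the full-model residual
    mean square.
    """
    rows = []
    for term in model.term_order:
        if term == "Intercept":
            continue
        idx = model.term_slices[term]
        keep = [j for j in range(model.X.shape[1]) if j not in idx]
        _, rss_red = _ols(model.X[:, keep], model.y)
        ss = rss_red - model.rss
        df = len(idx)
        if ss < -1e-8:
            warnings.warn(f"non-estimable marginal test for term {term}", stacklevel=2)
        ss = max(ss, 0.0)
        ms = ss / df
        F = ms / model.scale if model.scale > 0 else np.inf
        p = float(stats.f.sf(F, df, model.df_resid)) if model.df_resid > 0 else np.nan
        rows.append((term, df, ss, ms, F, p))
    rows.append(
        ("Residuals", model.df_resid, model.rss, model.scale, np.nan, np.nan)
    )
    return pd.DataFrame(rows, columns=["term", "df", "ss", "ms", "F", "p"])


def sequential_anova(model: FittedModel) -> pd.DataFrame:
    """Sequential (type I) ANOVA: terms added in model order.

    Satisfies the conservation identity Σ term SS + residual SS = total SS,
    and coincides with the type III table on balanced designs.
    """
    rows = []
    current: list[int] = list(model.term_slices["Intercept"])
    _, rss_prev = _ols(model.X[:, current], model.y)
    for term in model.term_order:
        if term == "Intercept":
            continue
        current = current + model.term_slices[term]
        _, rss_cur = _ols(model.X[:, current], model.y)
        ss = max(rss_prev - rss_cur, 0.0)
        df = len(model.term_slices[term])
        ms = ss / df
        F = ms / model.scale if model.scale > 0 else np.inf
        p = float(stats.f.sf(F, df, model.df_resid)) if model.df_resid > 0 else np.nan
        rows.append((term, df, ss, ms, F, p))
        rss_prev = rss_cur
    rows.append(("Residuals", model.df_resid, model.rss, model.scale, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["term", "df", "ss", "ms", "F", "p"])


@dataclass
class PartitionResult:
    """The %E plasticity share of a trait's elevational variance."""

    trait: str
    ss_e: float
    ss_g: float
    ss_gxe: float | None
    percent_e: float  # NaN when SS_E + SS_G = 0 (undefined, never coerced)
    percent_g: float

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "ss_e": self.ss_e,
            "ss_g": self.ss_g,
            "ss_gxe": self.ss_gxe,
            "percent_e": self.percent_e,
            "percent_g": self.percent_g,
        }


def percent_plasticity(
    anova: pd.DataFrame,
    trait: str = "",
    env_term: str = "EL_T",
    gen_term: str = "EL_O",
) -> PartitionResult:
    """%E = 100·SS_E/(SS_E + SS_G) from a type III table.

    The G×E interaction is excluded from the ratio (its variation cannot be
    assigned to either source) but its SS is carried along.  Works equally
    on an analysis-of-deviance table, giving the deviance-scale analogue.
    A zero denominator leaves the shares undefined (NaN).
    """
    tab = anova.set_index("term")
    for t in (env_term, gen_term):
        if t not in tab.index:
            raise ValueError(f"ANOVA table has no {t!r} row")
    ss_col = "ss" if "ss" in tab.columns else "deviance"
    ss_e = float(tab.loc[env_term, ss_col])
    ss_g = float(tab.loc[gen_term, ss_col])
    inter = f"{gen_term}:{env_term}"
    ss_gxe = float(tab.loc[inter, ss_col]) if inter in tab.index else None
    den = ss_e + ss_g
    if den == 0:
        pe = pg = float("nan")
    else:
        pe = 100.0 * ss_e / den
        pg = 100.0 - pe
    return PartitionResult(trait=trait, ss_e=ss_e, ss_g=ss_g, ss_gxe=ss_gxe,
                           percent_e=pe, percent_g=pg)


def fit_survival_model(
    records: pd.DataFrame, spec: ModelSpec | None = None
) -> tuple[FittedModel, pd.DataFrame]:
    """Logit-link binomial GLM for survival plus a type III deviance table.

    Per-term chi-square statistics come from the deviance increase when the
    term is dropped (likelihood-ratio tests).  Design cells in which every
    individual has the same outcome are reported as potential separation.
    """
    import statsmodels.api as sm

    if spec is None:
        spec = ModelSpec(response="survived", family="binomial")
    if spec.family != "binomial":
        raise ValueError("fit_survival_model requires a binomial ModelSpec")
    needed = [spec.response, "elevation_origin", "elevation_transplant"]
    if spec.covariate:
        needed.append(spec.covariate)
    data = records.dropna(subset=[c for c in needed if c in records.columns])
    data = data.reset_index(drop=True)
    y = data[spec.response].astype(float).to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("survival response must be binary")
    if y.min() == y.max():
        raise ValueError("survival response is constant (all died or all survived)")

    warns: list[str] = []
    cell_cols = [c for c in ("transect", "elevation_origin", "elevation_transplant") if c in data.columns]
    for cell, grp in data.groupby(cell_cols, sort=True):
        vals = grp[spec.response].astype(float)
        if len(vals) > 1 and vals.min() == vals.max():
            outcome = "survivors" if vals.iloc[0] == 1 else "deaths"
            msg = f"cell {cell} contains only {outcome}: possible separation"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)

    X, term_slices, term_order, levels, cov_mean, build_warns = _build_design(data, spec)
    _check_rank(X, term_slices)

    def deviance(Xm: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        res = sm.GLM(y, Xm, family=sm.families.Binomial()).fit()
        return res.params, float(res.deviance), np.asarray(res.cov_params())

    beta, dev_full, covp = deviance(X)
    df_resid = len(y) - X.shape[1]
    model = FittedModel(
        spec=spec,
        X=X,
        y=y,
        term_slices=term_slices,
        term_order=term_order,
        params=beta,
        rss=dev_full,
        df_resid=df_resid,
        n_obs=len(y),
        scale=1.0,
        cov_params=covp,
        data=data,
        covariate_mean=cov_mean,
        factor_levels=levels,
        warnings_=warns + build_warns,
    )
    rows = []
    for term in term_order:
        if term == "Intercept":
            continue
        idx = term_slices[term]
        keep = [j for j in range(X.shape[1]) if j not in idx]
        _, dev_red, _ = deviance(X[:, keep])
        chisq = max(dev_red - dev_full, 0.0)
        df = len(idx)
        p = float(stats.chi2.sf(chisq, df))
        rows.append((term, df, chisq, p))
    table = pd.DataFrame(rows, columns=["term", "df", "deviance", "p"])
    return model, table


@dataclass
class LsmeansResult:
    """Model-adjusted cell means and their pairwise contrasts."""

    means: pd.DataFrame  # columns: factor levels..., estimate, se
    contrasts: pd.DataFrame  # columns: a, b, estimate, se, statistic, p_adj
    factors: tuple[str, ...]
    adjust: str


_FACTOR_COLUMN = {"EL_O": "elevation_origin", "EL_T": "elevation_transplant", "R": "transect"}


def _grid_row(model: FittedModel, assignment: dict[str, object]) -> np.ndarray:
    """Design row for a cell of the reference grid.

    Factors not in the assignment are averaged with equal weight over their
    levels (their sum-to-zero contrast columns average to 0), blocks average
    out within sites, and the centered covariate sits at its grand mean.
    """
    x = np.zeros(model.X.shape[1])
    x[model.term_slices["Intercept"][0]] = 1.0

    def contrast_values(term: str, level) -> np.ndarray:
        levels = model.factor_levels[term]
        k = len(levels)
        v = np.zeros(k - 1)
        i = levels.index(level)
        if i < k - 1:
            v[i] = 1.0
        else:
            v[:] = -1.0
        return v

    per_term: dict[str, np.ndarray] = {}
    for term in ("EL_O", "EL_T", "R"):
        if term not in model.term_slices:
            continue
        if term in assignment:
            per_term[term] = contrast_values(term, assignment[term])
        else:
            per_term[term] = np.zeros(len(model.term_slices[term]))
        x[model.term_slices[term]] = per_term[term]
    if "EL_O:EL_T" in model.term_slices:
        x[model.term_slices["EL_O:EL_T"]] = np.outer(
            per_term["EL_O"], per_term["EL_T"]
        ).ravel()
    return x


def lsmeans_pairwise(
    model: FittedModel,
    factors: tuple[str, ...] = ("EL_O", "EL_T"),
    adjust: str = "tukey",
) -> LsmeansResult:
    """Least-squares means over a factor grid with pairwise contrasts.

    Cell means are model predictions at each combination of the requested
    factors, with remaining factors averaged equally, block effects averaged
    out and the covariate held at its grand mean.  Contrasts are tested with
    a Tukey-style studentized-range adjustment by default (``adjust`` may be
    ``'none'`` or ``'bonferroni'``); for the binomial family the means are on
    the linear-predictor (logit) scale.
    """
    for f in factors:
        if f not in model.term_slices:
            raise ValueError(f"factor {f!r} not in the fitted model")
    import itertools

    level_sets = [model.factor_levels[f] for f in factors]
    cells = list(itertools.product(*level_sets))
    rows = []
    xs = []
    for cell in cells:
        assignment = dict(zip(factors, cell))
        x = _grid_row(model, assignment)
        est = float(x @ model.params)
        se = float(np.sqrt(x @ model.cov_params @ x))
        xs.append(x)
        rows.append({**{f: lv for f, lv in zip(factors, cell)}, "estimate": est, "se": se})
    means = pd.DataFrame(rows)

    k = len(cells)
    df = model.df_resid if model.spec.family == "gaussian" else 1e6
    crows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = xs[i] - xs[j]
            est = float(d @ model.params)
            se = float(np.sqrt(d @ model.cov_params @ d))
            tstat = est / se if se > 0 else np.nan
            if adjust == "tukey":
                p = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, df))
            elif adjust == "bonferroni":
                raw = 2 * float(stats.t.sf(abs(tstat), df))
                p = min(1.0, raw * k * (k - 1) / 2)
            elif adjust == "none":
                p = 2 * float(stats.t.sf(abs(tstat), df))
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            crows.append(
                {
                    "a": ":".join(map(str, cells[i])),
                    "b": ":".join(map(str, cells[j])),
                    "estimate": est,
                    "se": se,
                    "statistic": tstat,
                    "p_adj": p,
                }
            )
    return LsmeansResult(
        means=means, contrasts=pd.DataFrame(crows), factors=tuple(factors), adjust=adjust
    )


def fit_initial_biomass(
    records: pd.DataFrame,
    response: str = "final_biomass",
    candidates: tuple[str, ...] = ("height", "rhizome_length", "rhizome_thickness", "n_leaves"),
    criterion: str = "aic",
) -> dict:
    """Bidirectional stepwise OLS predicting dry biomass from morphology.

    Starts from the intercept-only model and adds/removes candidate
    predictors to minimize AIC (BIC via ``criterion='bic'``).  The fitted
    model's predictions serve as the initial-biomass covariate for plants
    whose biomass could not be measured directly.  Returns the selected
    terms, the statsmodels results object, R², per-row predictions and the
    selection path.
    """
    import statsmodels.api as sm

    candidates = [c for c in candidates if c in records.columns]
    if not candidates:
        raise ValueError("no candidate predictor columns present")
    data = records.dropna(subset=[response] + list(candidates)).reset_index(drop=True)
    if len(data) <= len(candidates) + 2:
        raise ValueError("too few rows for stepwise selection")
    y = data[response].to_numpy(dtype=float)

    def score(terms: list[str]) -> float:
        X = sm.add_constant(data[terms].to_numpy(dtype=float)) if terms else np.ones((len(y), 1))
        if terms and np.linalg.matrix_rank(X) < X.shape[1]:
            return np.inf
        res = sm.OLS(y, X).fit()
        return res.aic if criterion == "aic" else res.bic

    selected: list[str] = []
    best = score(selected)
    path = [("start", tuple(selected), best)]
    improved = True
    while improved:
        improved = False
        moves = [("add", c) for c in candidates if c not in selected] + [
            ("drop", c) for c in selected
        ]
        best_move, best_score = None, best
        for action, term in moves:
            trial = selected + [term] if action == "add" else [t for t in selected if t != term]
            s = score(trial)
            if s < best_score - 1e-9:
                best_move, best_score = (action, term), s
        if best_move is not None:
            action, term = best_move
            selected = selected + [term] if action == "add" else [t for t in selected if t != term]
            best = best_score
            path.append((f"{action} {term}", tuple(selected), best))
            improved = True

    X = sm.add_constant(data[selected].to_numpy(dtype=float)) if selected else np.ones((len(y), 1))
    res = sm.OLS(y, X).fit()
    full_rank = np.linalg.matrix_rank(data[candidates].to_numpy(dtype=float))
    collinear = full_rank < len(candidates)
    return {
        "selected": selected,
        "model": res,
        "r_squared": float(res.rsquared) if selected else 0.0,
        "predictions": pd.Series(res.predict(X), index=data.index, name="init_biomass_pred"),
        "path": path,
        "collinear_candidates": collinear,
    }
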