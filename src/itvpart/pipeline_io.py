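"""File schemas, run configuration and the end-to-end pipeline.

CSV is the single interchange format.  The transplant table is one row per
individual (snake_case columns, elevations as the labels low/mid/high); the
community data is a long table (site, species, abundance, trait columns)
plus a site table (site, gradient).  ``run_pipeline`` ties the stages
together: simulate (or read) → per-trait variance partitioning → survival →
least-squares means → CWM decomposition → selection → CWM-optimality check,
writing tidy CSV outputs and a provenance stamp (config hash, seed,
versions) sufficient to reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cwm as cwm_mod
from . import partition, selection, synthgen

__all__ = [
    "TRANSPLANT_COLUMNS",
    "RunConfig",
    "ReportBundle",
    "read_transplant_csv",
    "write_transplant_csv",
    "read_community_csv",
    "write_community_csv",
    "run_pipeline",
]

log = logging.getLogger("itvpart")

TRANSPLANT_COLUMNS = (
    "individual_id",
    "transect",
    "elevation_origin",
    "elevation_transplant",
    "block",
    "init_biomass",
    "survived",
    "final_biomass",
)
ELEVATION_LEVELS = {"low", "mid", "high"}


def read_transplant_csv(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a transplant table.

    ``column_map`` renames user columns to the canonical schema before
    validation (an adapter for externally produced tables).  Unknown
    elevation labels, duplicate individual ids and missing required columns
    are errors naming the offender; missing values stay missing.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRANSPLANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transplant file {path} missing required column(s): {missing}")
    for col in ("elevation_origin", "elevation_transplant"):
        bad = set(df[col].dropna().unique()) - ELEVATION_LEVELS
        if bad:
            raise ValueError(f"unknown elevation label(s) in {col}: {sorted(bad)}")
    dup = df["individual_id"][df["individual_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate individual_id(s): {sorted(set(dup))[:5]}")
    df["survived"] = df["survived"].astype(bool)
    if (df["final_biomass"].notna() & ~df["survived"]).any():
        raise ValueError("final_biomass present for non-survivors")
    if (df["init_biomass"] <= 0).any():
        raise ValueError("init_biomass must be positive")
    return df


def write_transplant_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_community_csv(site_path: str | Path, long_path: str | Path) -> cwm_mod.CommunityDataset:
    """Assemble a CommunityDataset from a site table and a long table.

    Abundance rows off 1 by more than 1e-6 are renormalized with a warning
    (smaller discrepancies silently); a site in the long file absent from
    the site table, or a negative abundance, is an error.
    """
    sites = pd.read_csv(site_path)
    long = pd.read_csv(long_path)
    for needed, name, df in (
        (("site", "gradient"), "site table", sites),
        (("site", "species", "abundance"), "long table", long),
    ):
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"{name} missing column(s): {missing}")
    unknown = set(long["site"]) - set(sites["site"])
    if unknown:
        raise ValueError(f"site(s) in long table not in site table: {sorted(unknown)}")
    if (long["abundance"] < 0).any():
        raise ValueError("negative abundance")
    abundance = long.pivot_table(index="site", columns="species", values="abundance",
                                 fill_value=0.0, aggfunc="sum")
    abundance = abundance.loc[sites["site"]]
    rowsum = abundance.sum(axis=1)
    if not np.allclose(rowsum, 1.0, rtol=0, atol=1e-6):
        warnings.warn("abundances off by > 1e-6; renormalizing", stacklevel=2)
    trait_cols = [c for c in long.columns if c not in ("site", "species", "abundance")]
    traits = {
        t: long.pivot_table(index="site", columns="species", values=t).reindex(
            index=sites["site"], columns=abundance.columns
        )
        for t in trait_cols
    }
    return cwm_mod.CommunityDataset(sites=sites, abundance=abundance, traits=traits)


def write_community_csv(
    dataset: cwm_mod.CommunityDataset, site_path: str | Path, long_path: str | Path
) -> None:
    dataset.sites.to_csv(site_path, index=False)
    frames = []
    for site in dataset.abundance.index:
        row = {"site": site}
        sub = pd.DataFrame(
            {
                "site": site,
                "species": dataset.abundance.columns,
                "abundance": dataset.abundance.loc[site].to_numpy(),
            }
        )
        for t, x in dataset.traits.items():
            sub[t] = x.loc[site].to_numpy()
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(long_path, index=False)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    out_dir: str
    seed: int = 0
    transplant_path: str | None = None
    simulate_transplant: bool = True
    community_site_path: str | None = None
    community_long_path: str | None = None
    simulate_community: bool = False
    run_cwm: bool = False
    traits: tuple[str, ...] = ("height", "leaf_area", "sla")
    transform_map: dict = field(default_factory=lambda: dict(synthgen.TRAIT_TRANSFORMS))
    lsmeans_adjust: str = "tukey"
    cwm_gradient_model: str = "linear"
    selection_on_transformed: bool = False
    simulation_overrides: dict = field(default_factory=dict)
    community_options: dict = field(default_factory=dict)
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def validate(self) -> None:
        if self.transplant_path and self.simulate_transplant:
            raise ValueError("give either transplant_path or simulate_transplant, not both")
        if not self.transplant_path and not self.simulate_transplant:
            raise ValueError("no transplant data source configured")
        has_community_files = bool(self.community_site_path and self.community_long_path)
        if self.run_cwm and not (has_community_files or self.simulate_community):
            raise ValueError("run_cwm requested but no community data configured")
        if has_community_files and self.simulate_community:
            raise ValueError("give either community files or simulate_community, not both")

    def hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        payload["transform_map"] = dict(self.transform_map)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables of one run plus the provenance needed to reproduce them."""

    anova_tables: dict[str, pd.DataFrame]
    partition_summary: pd.DataFrame
    survival_table: pd.DataFrame | None
    lsmeans: dict[str, partition.LsmeansResult]
    cwm_decomposition: pd.DataFrame | None
    selection_table: pd.DataFrame
    optimality: selection.OptimalityCheck | None
    provenance: dict


def _population_means(records: pd.DataFrame, traits: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for site, grp in records.groupby(["transect", "elevation_transplant"], sort=True):
        for t in traits:
            rows.append(
                {
                    "site": ":".join(map(str, site)),
                    "trait": t,
                    "pop_mean": float(grp[t].mean()),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write its outputs under ``out_dir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        log.info("stage: %s", name)

    stage("data")
    if config.simulate_transplant:
        params = synthgen.default_params(seed=config.seed, **config.simulation_overrides)
        records = synthgen.simulate_transplant(params)
    else:
        records = read_transplant_csv(config.transplant_path)
    write_transplant_csv(records, out / "transplant_records.csv")

    stage("partition")
    records_t = partition.apply_transform(records, {t: config.transform_map[t] for t in config.traits})
    anova_tables: dict[str, pd.DataFrame] = {}
    part_rows = []
    lsmeans: dict[str, partition.LsmeansResult] = {}
    for trait in config.traits:
        spec = partition.ModelSpec(response=f"{trait}_transformed")
        model = partition.fit_trait_model(records_t, spec)
        tab = partition.type3_anova(model)
        anova_tables[trait] = tab
        tab.assign(trait=trait).to_csv(out / f"anova_{trait}.csv", index=False)
        part_rows.append(partition.percent_plasticity(tab, trait=trait).as_row())
        lsmeans[trait] = partition.lsmeans_pairwise(model, adjust=config.lsmeans_adjust)
        lsmeans[trait].means.to_csv(out / f"lsmeans_{trait}.csv", index=False)
    partition_summary = pd.DataFrame(part_rows)
    partition_summary.to_csv(out / "percent_plasticity.csv", index=False)

    stage("survival")
    survival_table = None
    if records["survived"].nunique() > 1:
        _, survival_table = partition.fit_survival_model(records)
        survival_table.to_csv(out / "survival_deviance.csv", index=False)
    else:
        log.warning("survival constant; skipping survival model")

    stage("cwm")
    cwm_table = None
    dataset = None
    if config.simulate_community:
        opts = {"n_sites": 10, "species_pool": [f"sp{j}" for j in range(1, 6)],
                "seed": config.seed, **config.community_options}
        dataset = synthgen.simulate_community(**opts)
    elif config.community_site_path:
        dataset = read_community_csv(config.community_site_path, config.community_long_path)
    if dataset is not None and config.run_cwm:
        rows = [
            cwm_mod.decompose(dataset, trait=t, model=config.cwm_gradient_model).as_row()
            for t in dataset.traits
        ]
        cwm_table = pd.DataFrame(rows)
        cwm_table.to_csv(out / "cwm_decomposition.csv", index=False)

    stage("selection")
    sel_traits = [f"{t}_transformed" for t in config.traits] if config.selection_on_transformed else list(config.traits)
    sel_source = records_t if config.selection_on_transformed else records
    selection_table = selection.full_lande_arnold(sel_source, sel_traits)
    selection_table.to_csv(out / "selection.csv", index=False)

    stage("optimality")
    optimality = None
    pop_means = _population_means(sel_source, tuple(sel_traits))
    # without observed community data at the transplant sites, the CWM table
    # must be supplied externally; the pipeline checks selection against it
    # only when present
    cwm_targets_path = out / "cwm_targets.csv"
    if cwm_targets_path.exists():
        cwm_targets = pd.read_csv(cwm_targets_path)
        optimality = selection.cwm_optimality(selection_table, cwm_targets, pop_means)
        optimality.table.to_csv(out / "optimality.csv", index=False)

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    summary = [
        "Transplant variance partitioning (%E = plasticity share):",
        partition_summary.to_string(index=False),
    ]
    if cwm_table is not None:
        summary += ["", "CWM decomposition:", cwm_table.to_string(index=False)]
    summary += ["", "Selection (per site x trait):", selection_table.to_string(index=False)]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    return ReportBundle(
        anova_tables=anova_tables,
        partition_summary=partition_summary,
        survival_table=survival_table,
        lsmeans=lsmeans,
        cwm_decomposition=cwm_table,
        selection_table=selection_table,
        optimality=optimality,
        provenance=provenance,
    )
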