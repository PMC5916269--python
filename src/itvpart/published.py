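"""Published field-study statistics used as worked-example inputs.

The original *Oxalis montana* reciprocal-transplant study printed, per
trait, the degrees of freedom and mean squares of its elevation terms.
Since SS = df × MS, those printed values suffice to evaluate the %E
plasticity share, making the table a self-contained worked example for
:func:`itvpart.partition.percent_plasticity` without access to the raw
deposit.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PUBLISHED_TRAIT_ANOVA", "published_anova_table", "published_percent_e"]

#: per trait: term -> (df, mean square) as printed in the field study's
#: trait ANOVA (height on the sqrt scale, leaf area and SLA on the log scale)
PUBLISHED_TRAIT_ANOVA: dict[str, dict[str, tuple[int, float]]] = {
    "height": {
        "EL_O": (2, 4.75),
        "EL_T": (2, 10.26),
        "EL_O:EL_T": (4, 1.12),
        "R": (1, 13.50),
        "Init.biom": (1, 0.15),
        "Residuals": (315, 1.10),
    },
    "leaf_area": {
        "EL_O": (2, 0.711),
        "EL_T": (2, 2.224),
        "EL_O:EL_T": (4, 0.265),
        "R": (1, 0.038),
        "Init.biom": (1, 0.043),
        "Residuals": (271, 0.267),
    },
    "sla": {
        "EL_O": (2, 0.099),
        "EL_T": (2, 0.355),
        "EL_O:EL_T": (4, 0.028),
        "R": (1, 0.044),
        "Init.biom": (1, 0.189),
        "Residuals": (271, 0.035),
    },
}


def published_anova_table(trait: str) -> pd.DataFrame:
    """Reconstruct an ANOVA table (term, df, ss, ms) from printed df and MS."""
    if trait not in PUBLISHED_TRAIT_ANOVA:
        raise KeyError(f"no published table for trait {trait!r}")
    rows = [
        {"term": term, "df": df, "ss": df * ms, "ms": ms}
        for term, (df, ms) in PUBLISHED_TRAIT_ANOVA[trait].items()
    ]
    return pd.DataFrame(rows)


def published_percent_e(trait: str) -> float:
    """%E computed from the published mean squares of one trait."""
    from .partition import percent_plasticity

    return percent_plasticity(published_anova_table(trait), trait=trait).percent_e
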