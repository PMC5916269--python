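"""Decompose community-weighted-mean trait turnover along the gradient.

Splits the variance of the specific-CWM series into species-turnover,
intraspecific and covariation components and reports the ITV share, then
shows how that share grows with the strength of intraspecific trait shifts.
"""

from pathlib import Path

import pandas as pd

from itvpart import cwm, pipeline_io, synthgen

OUT = Path(__file__).resolve().parents[1] / "results"

dataset = pipeline_io.read_community_csv(
    OUT / "community_sites.csv", OUT / "community_long.csv"
)
d = cwm.decompose(dataset)
pd.DataFrame([d.as_row()]).to_csv(OUT / "cwm_decomposition.csv", index=False)
print(f"gradient-explained SS: specific={d.ss_specific:.3f} "
      f"fixed={d.ss_fixed:.3f} intra={d.ss_intra:.3f} cov={d.ss_cov:.3f}")
print(f"ITV share {d.itv_share:.1f}% vs species turnover {d.spt_share:.1f}%")

rows = []
for slope in (0.0, 0.5, 1.0, 2.0, 4.0):
    ds = synthgen.simulate_community(
        10, [f"sp{i}" for i in range(1, 6)],
        itv_slopes={f"sp{i}": slope for i in range(1, 6)},
        noise_sd=0.0, seed=1,
    )
    rows.append({"itv_slope": slope, "itv_share": cwm.decompose(ds).itv_share})
grid = pd.DataFrame(rows)
grid.to_csv(OUT / "itv_share_vs_slope.csv", index=False)
print("\nITV share rises monotonically with the intraspecific slope:")
print(grid.to_string(index=False))
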