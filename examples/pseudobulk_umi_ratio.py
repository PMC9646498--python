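"""Tumor:non-tumor total-UMI ratio from labeled single cells, with a CI.

In single-cell data the per-cell total UMI count proxies total mRNA content.
Pooling cells into a pseudo-bulk, the ratio of mean totals between tumor and
non-tumor cells is the single-cell analogue of TmS (ploidy aside). The 95% CI
comes from a stratified percentile bootstrap (1,000 replicates, tumor and
non-tumor cells resampled separately at their original class sizes).
"""

import pandas as pd

from tms import bootstrap_ratio_ci, normalize_cells, simulate_single_cell

# two samples with different sequencing depth, true ratio 1.6 in both
cells_a = simulate_single_cell(400, 600, 1.6, seed=1, base_total=2000,
                               sample_id="patient_a")
cells_b = simulate_single_cell(300, 700, 1.6, seed=2, base_total=5000,
                               sample_id="patient_b")
cells = normalize_cells(pd.concat([cells_a, cells_b], ignore_index=True))

for sid, grp in cells.groupby("sample_id"):
    res = bootstrap_ratio_ci(grp, n_boot=1000, seed=3, sample_id=str(sid))
    print(f"{sid}: ratio {res.ratio:.3f}  95% CI [{res.ci_lower:.3f}, "
          f"{res.ci_upper:.3f}]  ({res.n_tumor} tumor / {res.n_nontumor} "
          f"non-tumor cells)")
print("\nthe true mean ratio is 1.6; both intervals should cover it, and "
      "depth differences are removed by the median normalization")
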