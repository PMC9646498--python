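"""TmS from transcript proportion + purity/ploidy; two-caller consensus.

TmS = [pi (1 - rho) Psi_N] / [rho (1 - pi) Psi_T] compares total mRNA per
haploid genome between tumor and non-tumor cells. When two DNA callers
provide (purity, ploidy) pairs, a log-log regression with Cook's-distance
screening (threshold 4/n) drops discordant samples before taking the
geometric-mean consensus; a planted 100x-discordant sample is rejected.
"""

import numpy as np
import pandas as pd

from tms import compute_tms, consensus_tms, filter_extreme_pi, multiregion_summary

print("single sample: pi=0.6, purity=0.5, tumor ploidy=3, normal ploidy=2")
print(f"  TmS = {compute_tms(0.6, 0.5, 3.0, 2.0):.3f}")

rng = np.random.default_rng(0)
t = rng.uniform(0.5, 2.0, 30)
tms_a = np.append(t * 2.0 ** rng.normal(0, 0.05, 30), 100.0)
tms_b = np.append(t * 2.0 ** rng.normal(0, 0.05, 30), 1.0)
ids = [f"s{i:02d}" for i in range(30)] + ["discordant"]
table = pd.DataFrame({"sample_id": np.repeat(ids, 2),
                      "caller": ["ascat", "absolute"] * 31,
                      "tms": np.column_stack([tms_a, tms_b]).ravel()})
out = consensus_tms(table).set_index("sample_id")
print(f"\nconsensus over {len(out)} samples, Cook's threshold {4 / len(out):.4f}:")
print(f"  kept {int(out['kept'].sum())}, dropped: "
      f"{out.index[~out['kept']].tolist()}")

pi = pd.Series(rng.uniform(0.1, 0.95, 200))
keep = filter_extreme_pi(pi)
print(f"\nextreme-pi filter on 200 samples: dropped {int((~keep).sum())} "
      f"(pi > 0.85 or above the 97.5th percentile)")

regions = pd.DataFrame({"patient_id": ["p1"] * 3 + ["p2"] * 2 + ["p3"],
                        "tms": [0.8, 1.3, 2.1, 0.9, 1.1, 1.5]})
print("\nmulti-region summaries (TmS_max, TmS_med, log2 range):")
print(multiregion_summary(regions).to_string(index=False))
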