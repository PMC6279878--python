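"""Compare network edges between trauma strata by label permutation.

Two strata whose generating dynamics differ in exactly one cross-lag
(anxious -> down, +0.3 in the high-trauma group).  Stratum labels are shuffled
across participants and both networks refitted per permutation; the cell-wise
coefficient difference yields a two-sided p-value per edge.
"""

import numpy as np
import pandas as pd

from esmnet import SimConfig, generate_cohort, stratum_difference_test
from esmnet.simulate import DEFAULT_ITEMS

k = len(DEFAULT_ITEMS)
idx = {n: i for i, n in enumerate(DEFAULT_ITEMS)}
a = np.eye(k) * 0.3
b = a.copy()
b[idx["anxious"], idx["down"]] = 0.3

cfg = SimConfig(
    n_pairs=150, n_sisters=0, likert_clip=False, p_invalid=0.0, seed=3,
    transition_matrices={"a": a, "b": b},
    trauma_effect={"low": "a", "medium": "a", "high": "b"},
)
panel, meta = generate_cohort(cfg)
labels = meta[["subject_id", "true_trauma_stratum"]].rename(
    columns={"true_trauma_stratum": "stratum"}
)
comp = stratum_difference_test(panel, labels, "stratum", ("high", "low"), n_perm=99, seed=9)

print("observed edge differences (high - low):")
print(pd.DataFrame(comp.observed_diff, index=DEFAULT_ITEMS, columns=DEFAULT_ITEMS).round(3).to_string())
cell = (idx["anxious"], idx["down"])
print(f"\ntarget cell anxious->down: diff {comp.observed_diff[cell]:+.3f} "
      f"(truth +0.30), p = {comp.pvalues[cell]:.3f}")
print(f"smallest p among all 36 cells: {np.nanmin(comp.pvalues):.3f} "
      f"(the differing edge should attain it)")
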