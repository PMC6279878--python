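"""Recover a known lagged affect network from synthetic continuous data.

Each affect item at beep t is regressed on all six person-mean-centered items
at beep t-1 (three-level mixed model: pair and subject intercepts, subject
time slope).  The 6x6 coefficient matrix is the directed network; because the
generator's transition matrix is known, estimation error is visible directly.
"""

import numpy as np

from esmnet import SimConfig, generate_cohort, estimate_network
from esmnet.simulate import DEFAULT_ITEMS

k = len(DEFAULT_ITEMS)
idx = {n: i for i, n in enumerate(DEFAULT_ITEMS)}
truth = np.eye(k) * 0.3
truth[idx["relaxed"], idx["cheerful"]] = 0.2   # relaxed(t-1) -> cheerful(t)

cfg = SimConfig(
    n_pairs=100, n_sisters=0, likert_clip=False, p_invalid=0.0, seed=7,
    transition_matrices={"a": truth},
    trauma_effect={"low": "a", "medium": "a", "high": "a"},
)
panel, _ = generate_cohort(cfg)
net = estimate_network(panel)

print("fitted edge matrix (rows: item at t-1, columns: item at t):")
print(net.to_frame().round(3).to_string())
err = np.abs(net.w - truth)
print(f"\nrecovery vs ground truth: mean |error| {err.mean():.4f}, max {err.max():.4f}")
print("(autoregressive diagonal entries sit ~0.03 below truth: the finite-length "
      "person-mean-centering bias of about -(1+rho)/T at T = 45 lag pairs/subject)")
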