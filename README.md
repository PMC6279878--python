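# esmnet

Directed time-lagged networks of momentary affective states from
experience-sampling (ESM) data, with permutation inference and twin-design
stratification.

Repeated momentary self-reports (beeps) let affect dynamics be modelled as a
network: each of six momentary states — cheerful, insecure, relaxed, anxious,
irritated, down — rated 1–7 at every beep, is regressed on all six states at
the previous beep. The lagged coefficients **B** are directed weighted edges
(`B[p, o]`: item *p* at *t−1* → item *o* at *t*; the diagonal holds the
self-loops, i.e. emotional inertia). Networks are estimated separately within
strata of childhood-trauma severity (tertiles of the trauma-questionnaire mean
score) and of genetic liability (whether a subject's MZ or DZ co-twin scores
in the top quartile of psychopathology), and compared edge by edge.

For each outcome item the model is a three-level mixed regression —
assessments within subjects within twin pairs —

    y_ijk = (B0 + e_ijk) + Σ_p B_p·lag_p,ijk + (B7 + u7_jk)·time_ijk + a_k + b_jk

with person-mean-centered lagged predictors, a fixed + random slope for beep
number (1..50), and random intercepts for pair and subject. Edge p-values
come from refitting under within-subject outcome shuffling; between-stratum
differences from refitting under stratum-label shuffling; both are doubled
exceedance proportions, thresholded by the Simes step-up rule (corrected
α = k·α/m over the family of m tests). Node strength, closeness and
betweenness (edge length 1/|B|, self-loops counted twice in strength,
magnitudes only in distances) profile each network. A synthetic twin-cohort
generator with known VAR(1) dynamics, MZ>DZ resemblance, Likert floor effects
and report-delay missingness makes the whole chain testable by parameter
recovery. See `docs/methods.md` for the full model account.

## Worked example

Recover a known network from a simulated continuous-scale cohort
(`examples/02_fit_affect_network.py`):

```python
import numpy as np
from esmnet import SimConfig, generate_cohort, estimate_network
from esmnet.simulate import DEFAULT_ITEMS

k = len(DEFAULT_ITEMS)
idx = {n: i for i, n in enumerate(DEFAULT_ITEMS)}
truth = np.eye(k) * 0.3
truth[idx["relaxed"], idx["cheerful"]] = 0.2      # relaxed(t-1) -> cheerful(t)

cfg = SimConfig(n_pairs=100, n_sisters=0, likert_clip=False, p_invalid=0.0,
                seed=7, transition_matrices={"a": truth},
                trauma_effect={"low": "a", "medium": "a", "high": "a"})
panel, _ = generate_cohort(cfg)
net = estimate_network(panel)
print(net.to_frame().round(3))
```

prints (rows: predictor at *t−1*, columns: outcome at *t*)

```
               cheerful_t  insecure_t  relaxed_t  anxious_t  irritated_t  down_t
cheerful_t-1        0.269      -0.008     -0.001     -0.004        0.011   0.001
insecure_t-1        0.022       0.264      0.015     -0.011        0.001  -0.001
relaxed_t-1         0.201      -0.002      0.259     -0.003       -0.006   0.008
anxious_t-1         0.023      -0.001     -0.006      0.276       -0.001   0.009
irritated_t-1      -0.003       0.004      0.011     -0.003        0.258   0.003
down_t-1            0.014       0.001      0.027     -0.004       -0.000   0.283
```

The planted cross-lag relaxed→cheerful is recovered at 0.201 (truth 0.20) and
all other cross-lags stay near zero (mean |error| 0.011). The autoregressive
diagonal sits ~0.03 below the generating 0.3 — the finite-length
person-mean-centering bias of ≈ −(1+ρ)/T at T = 45 lag pairs per subject,
discussed in `docs/methods.md`.

The other example scripts walk through cohort simulation and filtering (`01`),
edge significance with Simes correction (`03` — the seven truly nonzero edges
are exactly the ones that survive), between-stratum comparison of a planted
0.3 cross-lag difference (`04`), and centrality profiles with GraphML export
(`05`). A full pipeline — simulate or load CSVs, preprocess, fit all strata,
permute, correct, export — runs from a YAML config:

```sh
esmnet simulate --n-pairs 60 --seed 1 --out-prefix cohort
esmnet validate cohort_panel.csv cohort_meta.csv
esmnet run-all --config run.yaml --seed 1 --n-perm 199
```

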