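# Methods

`esmnet` estimates directed, weighted, time-lagged networks among momentary
affective states measured by experience sampling (ESM), compares those
networks between subject strata (childhood-trauma tertiles; co-twin-based
genetic-liability classes), and profiles node centrality. Because suitable
twin ESM data are rarely shareable, the package ships a synthetic twin-cohort
generator with known dynamics, so every stage of the pipeline can be validated
end to end by parameter recovery.

## The lagged network model

The observational unit is a beep report: subject *j* in twin pair *k* rates
six affect items (cheerful, insecure, relaxed, anxious, irritated, down) on a
1–7 Likert scale at beep *i* of a 5-day × 10-beep schedule. For each item as
outcome, a three-level linear mixed model regresses the rating at beep *t* on
all six ratings at beep *t−1*:

```
y_ijk = (B0 + e_ijk) + Σ_p B_p · lag_p,ijk + (B7 + u7_jk) · time_ijk + a_k + b_jk
```

* `lag_p,ijk` — item *p* at the immediately preceding beep of the same day,
  **person-mean centered** (each subject's own mean over their design rows is
  subtracted), isolating within-person dynamics from between-person level
  differences;
* `time_ijk` — the beep number 1..50, entered both as a fixed effect and with
  a subject-level random slope `u7_jk`, so person-specific trends do not
  masquerade as autocorrelation;
* `a_k`, `b_jk` — random intercepts for twin pair and subject (independent
  variance components), absorbing familial and individual affect levels;
* `e_ijk` — residual.

Lag pairs must be contiguous within a day and both reports valid; the last
beep of a day is never the lag of the next morning's first beep, and a missing
mid-day beep removes both adjacent pairs. The k×k matrix **B** with
`B[p, o]` = coefficient of lagged item *p* in the model for outcome *o* is the
network: diagonal entries are autoregressive self-loops (emotional inertia),
off-diagonal entries cross-lagged influences.

Richer models (random slopes for all six lagged predictors, unstructured
random-effect covariance) do not converge on data of this shape, which is why
the random part is restricted to the three independent components above and
why edge inference is permutation-based rather than Wald-based.

## Estimation

The fit is restricted maximum likelihood on the profiled scale. With
`V = I + Σ_c γ_c Z_c Z_c'` (γ = variance ratios for pair intercept, subject
intercept, subject time slope), the random-effect design is block diagonal by
twin pair and each block is tiny — one pair column plus an intercept and a
time column per member. The Woodbury identity reduces every likelihood and
score evaluation to batched Cholesky factorizations of (2m+1)×(2m+1)
matrices (m = pair members), with all outcome-independent cross products
(`Z'Z`, `Z'X`, `X'X`) cached at construction. The three log-variance ratios
are optimised by L-BFGS-B with the analytic REML/ML gradient; if a line search
aborts the point is polished by Nelder-Mead before the fit is flagged
non-converged. A non-converged REML fit is retried under ML; a fit that still
fails is returned flagged, never dropped silently, and flagged cells are
excluded from permutation inference.

This makes one fit a few milliseconds and a permutation refit (same design,
new outcome vector) cheaper still — the property the 1,000-refit permutation
schemes depend on. The test suite pins the fitter against statsmodels
`MixedLM` on the identical structure (coefficients and variance components to
1e−3, plus a criterion-dominance check that is robust to `MixedLM`'s own
convergence failures) and against pooled OLS in the zero-variance limit.

Boundary variance estimates are reported as zero. Coefficients are invariant
to design row order (1e−10) and to constant shifts of raw predictors.

## Permutation inference

Model-based standard errors are not trusted (single random slope only), so
p-values come from two permutation schemes:

* **Edge significance** — the outcome column of each model is shuffled
  uniformly at random *within subject*, predictors and clustering untouched,
  and all six models are refitted; 1,000 repetitions (default) give each
  coefficient's null distribution.
* **Between-stratum differences** — stratum labels are permuted across
  participants and both strata's networks refitted; the statistic is the
  cell-wise coefficient difference. All 36 cells are tested regardless of
  marginal significance. Label permutation defaults to the individual
  participant; a pair-level unit is available for designs where individual
  shuffling breaks pair exchangeability.

The two-sided p-value doubles the one-tailed exceedance count on the side of
the observed sign, with add-one smoothing: `p = min(1, 2(c+1)/(N+1))`, where
`c` counts null values at least as extreme as the observed coefficient. The
smoothing keeps p in (0, 1] and recovers the plain proportion as N grows; an
absolute-value variant (`tail="absolute"`) is available. Per-permutation
seeds derive deterministically from the master seed and permutation index, so
runs are reproducible and mergeable across workers.

Families for multiplicity control follow the 2 × 3 × 36 accounting: one
family per scheme spanning all three strata's 36 edge tests, and separate
families for the between-stratum comparisons. The **Simes step-up rule**
sorts the family's m p-values, finds `k = max{ i : p(i) ≤ i·α/m }`, and
rejects everything at or below the single corrected threshold `k·α/m`
(for example, k = 70 of m = 216 at α = 0.05 gives 0.0162).

## Centrality

Three indices per node, on the signed weighted digraph:

* **Strength** — Σ|in-weights| + Σ|out-weights|; the self-loop belongs to both
  sums and is counted twice (inertia is a connectivity feature).
* **Closeness** — 1 / Σ directed shortest-path distances to all other nodes,
  with edge length 1/|B| (strong edges are short). A node that cannot reach
  every other node has closeness 0; a harmonic variant degrades gracefully.
* **Betweenness** — number of shortest paths between ordered pairs of other
  nodes passing through the node, ties split fractionally.

Only coefficient magnitudes enter distances — the only convention that yields
valid path lengths for negative coefficients — and self-loops never enter
path computations. All three indices are verified against exhaustive
path-enumeration oracles on random digraphs. Centralities are computed on the
full matrix by default; a significance-masked mode mirrors networks displayed
after correction.

## Preprocessing conventions

* Reports completed more than 15 minutes after the beep are invalid (exactly
  15 is kept); subjects with fewer than 17 of 50 valid reports are dropped
  entirely.
* Trauma score = mean of the administered questionnaire items after reversing
  positively worded items (x → 6−x); the divisor is the number of administered
  items (21 by default — four explicit items of the 25-item short form are
  omitted in the emulated protocol), both divisor and reversal key set
  configurable. Tertile cut points are the empirical 1/3 and 2/3 quantiles;
  boundary ties go to the lower tertile by subject id until its quota
  (⌈n/3⌉) fills — deterministic and seed-free.
* Genetic liability: the co-twin's averaged symptom-checklist score is
  dichotomised at the sample 75th percentile (linear interpolation, computed
  over retained twins; sisters are excluded from this scheme). Classes:
  co-twin low (reference), DZ co-twin high (intermediate), MZ co-twin high
  (high).
* Person means are computed over the rows entering each outcome's design, so
  centered columns sum to exactly zero per subject within each fitted model.
* The floor-effect screen fits per-subject lag-1 slopes; a slope is
  "horizontal" when the predictor variance is zero or |slope| ≤ `slope_eps`
  (default 0.05, a package construct — no standard numerical definition
  exists).

## The synthetic cohort

The generator emulates: three-level clustering (beeps ⊂ subjects ⊂ pairs,
plus non-twin sisters attached to pairs at sibling-level resemblance), VAR(1)
latent affect `x_t = c_j + A'x_{t−1} + ε_t` with stationary mean pinned at
`item_intercepts + b_j`, within-pair correlation of subject levels (MZ >
DZ), stratum-specific transition matrices selected by a latent trauma draw
cut at its theoretical tertiles, per-subject linear drift, 7-point Likert
discretization (round, clip) with floor effects when intercepts sit near 1,
and missing-completely-at-random invalidity via report-delay inflation.
Default sizes mirror the emulated design: 270 pairs + 45 sisters, 5 × 10
schedule; twin correlations 0.4/0.2, trauma item mean 1.6 (sd 0.45) on the
1–5 scale, symptom scores 120 ± 30 — plausible population values for a
female general-population cohort.

Not emulated: momentary context items, circadian beep timing in minutes
(only indices matter downstream), informative missingness, item reliability
differences, and any gene–environment correlation. Passing recovery tests
therefore show the *pipeline* is correct under the stated generative model,
not that real affect dynamics are VAR(1).

The latent recursion runs across overnight gaps; dropping overnight lag pairs
is purely a preprocessing rule. Drift is added to recorded values rather than
recursed, so the ground-truth transition matrix stays the estimand of the
lagged fit.

## Known limitations

* **Finite-length centering bias.** Person-mean centering with T design rows
  per subject biases autoregressive coefficients by ≈ −(1+ρ)/T (cross-lags
  are essentially unaffected). At the full 45-rows-per-subject schedule this
  is ≈ −0.03 for ρ = 0.3 — visible in parameter-recovery output as diagonal
  entries sitting just below truth. Two consequences worth knowing:
  recovery of strong self-loops is bias-limited, not noise-limited, at
  realistic cohort sizes; and under a global null the observed self-lag
  estimate (biased ≈ −1/T) is compared to an outcome-shuffle null centered at
  zero, so self-loop p-values are anticonservative on short series (at 20
  beeps/subject the bias is −1/18 ≈ −0.056, about 1.3 standard errors for 30
  subjects, inflating self-loop rejection at α = 0.05 to ~25%).
  Cross-lagged edges — the substantive between-stratum quantities — are
  exactly calibrated, which the test suite verifies. The bias is a property
  of the estimator itself, shared with any implementation of this model.
* Monte-Carlo p-values are discrete with grid 2/(N+1); uniformity checks in
  the test suite jitter within the grid cell before applying a continuous
  Kolmogorov–Smirnov test.
* The between-stratum test shuffles labels at the participant level by
  default, which treats co-twins as exchangeable across pairs; the pair-level
  unit is the conservative alternative.
* Likert discretization attenuates latent twin correlations only mildly at
  mid-scale intercepts but strongly under severe floor effects.

## Problem sizes in the test suite

Exact combinatorial checks (lag construction, centering, Simes-vs-brute-force,
centrality-vs-enumeration) run at full precision in seconds. Stochastic
checks use scaled-down designs chosen to keep a routine run short while
leaving clear statistical margins: parameter recovery at ~100 pairs per
stratum; null calibration on 50 datasets of 30 subjects × 20 beeps with 99
permutations; between-stratum power at 100 pairs per stratum over 20
replicates; twin-structure fidelity at 2,000 pairs.
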