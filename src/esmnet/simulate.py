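"""Synthetic twin-cohort generator for experience-sampling (ESM) affect panels.

The generator emulates the data layout of a prospective female-twin ESM study:
twin pairs (plus a few non-twin sisters attached to pairs), five diary days with
ten beeps per day, six momentary affect items rated on a 1-7 Likert scale, a
report delay that decides validity, and subject-level questionnaires (childhood
trauma items, two symptom-checklist assessments).

Latent affect follows a stationary first-order vector autoregression

    x_t = c_j + A' x_{t-1} + eps_t,      eps_t ~ N(0, diag(residual_sd^2))

where the subject constant ``c_j = (I - A') (mu + b_j)`` fixes the stationary
mean at ``mu + b_j``; ``b_j`` are per-item subject deviations correlated within
a pair (MZ > DZ), and ``A`` is the ground-truth transition matrix recovered by
the downstream lagged network fit.  A subject's childhood-trauma stratum can
select a different transition matrix, which provides known between-stratum edge
differences.  A per-subject linear drift ``s_j * t`` is added to the recorded
(not recursed) values so that the model's fixed + random time slope has a
matching generative counterpart.

The recursion runs across the whole beep sequence including overnight gaps;
excluding the last-beep -> first-beep-next-day lag is a preprocessing rule, not
a generative break.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ITEMS",
    "SimConfig",
    "default_transition_matrices",
    "discretize_likert",
    "generate_cohort",
    "pair_correlation_check",
]

DEFAULT_ITEMS: tuple[str, ...] = (
    "cheerful",
    "insecure",
    "relaxed",
    "anxious",
    "irritated",
    "down",
)

#: columns of an EsmPanel that are not affect items
PANEL_META_COLUMNS: tuple[str, ...] = (
    "pair_id",
    "subject_id",
    "zygosity",
    "day",
    "beep_in_day",
    "beep_number",
    "response_delay_min",
)

# 0-based positions (within the administered item list) of positively worded,
# reverse-keyed trauma-questionnaire items.
DEFAULT_CTQ_REVERSE_KEYS: tuple[int, ...] = (1, 4, 6, 12, 18)


def default_transition_matrices(k: int = 6) -> dict[str, np.ndarray]:
    """Plausible affect transition matrices, ``A[p, o]`` = effect of item ``p``
    at t-1 on item ``o`` at t.

    ``base`` has moderate inertia (0.25 autoregression), mutual reinforcement
    of the positive pair (cheerful, relaxed) and of the negative triplet
    (insecure, anxious, down), and mild cross-valence damping.  ``high`` adds
    stronger negative-affect inertia and coupling, the kind of "risky" network
    hypothesised for trauma-exposed subjects.  Both are comfortably stationary
    (spectral radius < 0.5).
    """
    if k != len(DEFAULT_ITEMS):
        raise ValueError("default matrices are defined for the six standard items")
    idx = {name: i for i, name in enumerate(DEFAULT_ITEMS)}
    base = np.eye(k) * 0.25
    base[idx["cheerful"], idx["relaxed"]] = 0.10
    base[idx["relaxed"], idx["cheerful"]] = 0.10
    base[idx["insecure"], idx["anxious"]] = 0.08
    base[idx["anxious"], idx["down"]] = 0.08
    base[idx["down"], idx["insecure"]] = 0.05
    base[idx["relaxed"], idx["anxious"]] = -0.06
    base[idx["cheerful"], idx["down"]] = -0.06
    high = base.copy()
    for a in ("insecure", "anxious", "down"):
        high[idx[a], idx[a]] += 0.10
    high[idx["anxious"], idx["insecure"]] = 0.08
    high[idx["down"], idx["anxious"]] = 0.08
    return {"base": base, "high": high}


@dataclass
class SimConfig:
    """Study-design and ground-truth parameters of the synthetic cohort.

    Defaults mirror the emulated study: 270 twin pairs plus 45 sisters
    (585 subjects), 5 days x 10 beeps, six affect items, tertile-dependent
    dynamics, and modest twin resemblance (MZ 0.4, DZ 0.2) of the latent
    affect levels and symptom scores.
    """

    n_pairs: int = 270
    prop_mz: float = 0.5
    n_sisters: int = 45
    n_days: int = 5
    beeps_per_day: int = 10
    items: tuple[str, ...] = DEFAULT_ITEMS
    transition_matrices: Mapping[str, np.ndarray] = field(
        default_factory=default_transition_matrices
    )
    item_intercepts: Sequence[float] = (4.5, 1.6, 4.4, 1.5, 1.8, 1.6)
    residual_sd: Sequence[float] = (0.8, 0.6, 0.8, 0.6, 0.7, 0.6)
    pair_intercept_sd: Sequence[float] = (0.6, 0.5, 0.6, 0.5, 0.5, 0.5)
    mz_corr: float = 0.4
    dz_corr: float = 0.2
    time_slope_sd: float = 0.003
    likert_clip: bool = True
    p_invalid: float = 0.10
    trauma_dist: tuple[float, float] = (1.6, 0.45)
    scl_dist: tuple[float, float] = (120.0, 30.0)
    trauma_effect: Mapping[str, str] = field(
        default_factory=lambda: {"low": "base", "medium": "base", "high": "high"}
    )
    n_ctq_items: int = 21
    ctq_reverse_keys: tuple[int, ...] = DEFAULT_CTQ_REVERSE_KEYS
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.items)

    def validate(self) -> None:
        k = self.k
        if not 0.0 <= self.prop_mz <= 1.0:
            raise ValueError("prop_mz must lie in [0, 1]")
        if not 0.0 <= self.p_invalid <= 1.0:
            raise ValueError("p_invalid must lie in [0, 1]")
        if not 0.0 <= self.dz_corr <= self.mz_corr <= 1.0:
            raise ValueError("need 0 <= dz_corr <= mz_corr <= 1")
        for name, vec in (
            ("item_intercepts", self.item_intercepts),
            ("residual_sd", self.residual_sd),
            ("pair_intercept_sd", self.pair_intercept_sd),
        ):
            if len(vec) != k:
                raise ValueError(f"{name} must have length k={k}")
        for key, a in self.transition_matrices.items():
            a = np.asarray(a, dtype=float)
            if a.shape != (k, k):
                raise ValueError(f"transition matrix {key!r} must be {k}x{k}")
            rho = max(abs(np.linalg.eigvals(a)))
            if rho >= 1.0:
                raise ValueError(
                    f"transition matrix {key!r} is non-stationary (spectral radius {rho:.3f} >= 1)"
                )
        missing = set(self.trauma_effect.values()) - set(self.transition_matrices)
        if missing:
            raise ValueError(f"trauma_effect refers to unknown matrices: {sorted(missing)}")
        for label in ("low", "medium", "high"):
            if label not in self.trauma_effect:
                raise ValueError(f"trauma_effect must map stratum {label!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transition_matrices"] = {
            key: np.asarray(a).tolist() for key, a in self.transition_matrices.items()
        }
        d["trauma_effect"] = dict(self.trauma_effect)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "transition_matrices" in d:
            d["transition_matrices"] = {
                key: np.asarray(a, dtype=float) for key, a in d["transition_matrices"].items()
            }
        for key in ("items", "ctq_reverse_keys"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("item_intercepts", "residual_sd", "pair_intercept_sd"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        for key in ("trauma_dist", "scl_dist"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


def discretize_likert(latent):
    """Map latent affect to a 1..7 Likert rating: round to nearest, clip to [1, 7].

    Accepts scalars or arrays; monotone in the latent value.
    """
    arr = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("latent values must be finite")
    out = np.clip(np.rint(arr), 1, 7).astype(int)
    if np.isscalar(latent) or np.ndim(latent) == 0:
        return int(out)
    return out


def _correlated_pair_effects(rng, sizes, zyg_per_pair, sd, mz_corr, dz_corr):
    """Per-item subject deviations with within-pair correlation.

    Twin-twin correlation is mz_corr or dz_corr by zygosity; any attached
    sister correlates at dz_corr with both twins (sibling-level resemblance).
    Returns an (n_subjects,) array for one item.
    """
    out = []
    for m, zyg in zip(sizes, zyg_per_pair):
        rho = mz_corr if zyg == "MZ" else dz_corr
        c = np.full((m, m), dz_corr)
        c[0, 1] = c[1, 0] = rho
        np.fill_diagonal(c, 1.0)
        chol = np.linalg.cholesky(c)
        out.append(chol @ rng.standard_normal(m))
    return np.concatenate(out) * sd


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an ESM panel and its subject-level table.

    Returns ``(panel, meta)``: one panel row per subject per scheduled beep
    (ratings integer 1..7 when ``likert_clip`` else continuous), and one meta
    row per subject with trauma items/mean, two symptom-checklist scores, and
    the ground-truth trauma stratum used to pick that subject's dynamics.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.k
    items = list(config.items)

    n_mz = int(round(config.prop_mz * config.n_pairs))
    zyg_per_pair = ["MZ"] * n_mz + ["DZ"] * (config.n_pairs - n_mz)
    if config.n_sisters > config.n_pairs:
        raise ValueError("n_sisters cannot exceed n_pairs (one sister per pair)")
    sizes = [3 if i < config.n_sisters else 2 for i in range(config.n_pairs)]

    pair_ids, subject_ids, zygosity = [], [], []
    for i, (m, zyg) in enumerate(zip(sizes, zyg_per_pair), start=1):
        for member in range(1, m + 1):
            pair_ids.append(i)
            subject_ids.append(i * 10 + member)
            zygosity.append(zyg if member <= 2 else "SIB")
    pair_ids = np.asarray(pair_ids)
    subject_ids = np.asarray(subject_ids)
    zygosity = np.asarray(zygosity)
    n_sub = len(subject_ids)

    # --- subject-level questionnaires -------------------------------------
    mu_t, sd_t = config.trauma_dist
    ctq_latent = rng.normal(mu_t, sd_t, size=n_sub)
    # keyed item scores scatter around the subject's latent trauma level
    keyed = np.clip(
        np.rint(ctq_latent[:, None] + rng.normal(0.0, 0.7, size=(n_sub, config.n_ctq_items))),
        1,
        5,
    ).astype(int)
    raw = keyed.copy()
    rev = list(config.ctq_reverse_keys)
    raw[:, rev] = 6 - raw[:, rev]
    ctq_mean = keyed.mean(axis=1)

    # theoretical tertiles of the generating normal, applied to the latent
    # trauma draw (not the discretized item mean), define the ground-truth
    # stratum that drives each subject's dynamics; groups are balanced ~n/3
    z3 = 0.4307272992954576  # Phi^{-1}(2/3)
    cut_lo, cut_hi = mu_t - z3 * sd_t, mu_t + z3 * sd_t
    stratum = np.where(
        ctq_latent <= cut_lo, "low", np.where(ctq_latent <= cut_hi, "medium", "high")
    )

    mu_s, sd_s = config.scl_dist
    scl_latent = mu_s + sd_s * 0.8 * _correlated_pair_effects(
        rng, sizes, zyg_per_pair, 1.0, config.mz_corr, config.dz_corr
    )
    scl_t1 = scl_latent + rng.normal(0.0, sd_s * 0.6, size=n_sub)
    scl_t2 = scl_latent + rng.normal(0.0, sd_s * 0.6, size=n_sub)

    # --- latent dynamics ---------------------------------------------------
    mu = np.asarray(config.item_intercepts, dtype=float)
    res_sd = np.asarray(config.residual_sd, dtype=float)
    b = np.column_stack(
        [
            _correlated_pair_effects(
                rng, sizes, zyg_per_pair, config.pair_intercept_sd[i], config.mz_corr, config.dz_corr
            )
            for i in range(k)
        ]
    )
    subj_mean = mu[None, :] + b  # (n_sub, k)
    drift = rng.normal(0.0, config.time_slope_sd, size=(n_sub, k))

    a_by_key = {key: np.asarray(a, dtype=float) for key, a in config.transition_matrices.items()}
    a_key = np.array([config.trauma_effect[s] for s in stratum])

    n_beeps = config.n_days * config.beeps_per_day
    burn_in = 10
    x = subj_mean + rng.standard_normal((n_sub, k)) * res_sd
    recorded = np.empty((n_beeps, n_sub, k))
    for t in range(burn_in + n_beeps):
        dev = x - subj_mean
        nxt = np.empty_like(dev)
        for key, a in a_by_key.items():
            sel = a_key == key
            if sel.any():
                nxt[sel] = dev[sel] @ a  # (x' A)_o = sum_p A[p,o] x_p
        x = subj_mean + nxt + rng.standard_normal((n_sub, k)) * res_sd
        if t >= burn_in:
            recorded[t - burn_in] = x + drift * (t - burn_in + 1)

    # --- assemble panel ----------------------------------------------------
    beep_number = np.arange(1, n_beeps + 1)
    day = (beep_number - 1) // config.beeps_per_day + 1
    beep_in_day = (beep_number - 1) % config.beeps_per_day + 1

    invalid = rng.random((n_beeps, n_sub)) < config.p_invalid
    delay = rng.uniform(0.0, 15.0, size=(n_beeps, n_sub))
    delay[invalid] = 15.0 + rng.exponential(10.0, size=int(invalid.sum()))

    panel = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_ids, n_beeps),
            "subject_id": np.repeat(subject_ids, n_beeps),
            "zygosity": np.repeat(zygosity, n_beeps),
            "day": np.tile(day, n_sub),
            "beep_in_day": np.tile(beep_in_day, n_sub),
            "beep_number": np.tile(beep_number, n_sub),
            "response_delay_min": np.round(delay.T.reshape(-1), 2),
        }
    )
    ratings = recorded.transpose(1, 0, 2).reshape(-1, k)  # subject-major
    if config.likert_clip:
        ratings = discretize_likert(ratings)
    for i, name in enumerate(items):
        panel[name] = ratings[:, i]

    meta = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "pair_id": pair_ids,
            "zygosity": zygosity,
            "ctq_mean": ctq_mean,
            "scl90_t1": np.round(scl_t1, 2),
            "scl90_t2": np.round(scl_t2, 2),
            "true_trauma_stratum": stratum,
        }
    )
    meta["scl90_mean"] = (meta["scl90_t1"] + meta["scl90_t2"]) / 2.0
    for j in range(config.n_ctq_items):
        meta[f"ctq_item_{j + 1}"] = raw[:, j]
    return panel, meta


def pair_correlation_check(meta: pd.DataFrame, panel: pd.DataFrame) -> dict[str, float]:
    """Realized within-pair correlation of subject mean ratings, per zygosity.

    Subject mean = mean over all item columns and beeps.  Pairs are
    double-entered (both orderings), making the estimate symmetric in twin
    labelling.  Requires at least two complete pairs per zygosity.
    """
    item_cols = [c for c in panel.columns if c not in PANEL_META_COLUMNS]
    subj_mean = panel.groupby("subject_id")[item_cols].mean().mean(axis=1)
    twins = meta[meta["zygosity"].isin(["MZ", "DZ"])]
    out = {}
    for zyg, key in (("MZ", "mz_r"), ("DZ", "dz_r")):
        rows = twins[twins["zygosity"] == zyg]
        pairs = []
        for _, grp in rows.groupby("pair_id"):
            ids = grp["subject_id"].tolist()
            if len(ids) == 2 and all(s in subj_mean.index for s in ids):
                a, b = subj_mean[ids[0]], subj_mean[ids[1]]
                pairs.append((a, b))
                pairs.append((b, a))
        if len(pairs) < 4:
            raise ValueError(f"need at least 2 complete {zyg} pairs")
        arr = np.asarray(pairs)
        out[key] = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    return out
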