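"""Permutation inference for lagged network edges and stratum contrasts.

Two permutation schemes give distribution-free p-values for the mixed-model
coefficients (whose model-based standard errors are not trusted, because the
model carries only a single random slope):

* **outcome shuffle** — for each outcome model, the outcome values are
  re-ordered uniformly at random *within each subject*, predictors and the
  clustering untouched; refitting yields coefficients under the null of no
  lagged association while preserving the multilevel structure.
* **label shuffle** — stratum labels (trauma tertile or liability class) are
  permuted across participants; refitting both strata yields the distribution
  of the between-stratum coefficient difference under the null of no stratum
  effect.

Two-sided p-values use the one-tailed exceedance count on the side of the
observed sign, doubled and capped at one, with add-one smoothing:
``p = min(1, 2 (c + 1) / (N + 1))``.  Families of p-values are thresholded by
the Simes step-up rule, whose effective corrected alpha is ``k_rejected *
alpha / m``.

Per-permutation seeds derive deterministically from the master seed and the
permutation index, so runs are reproducible and mergeable across workers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import EdgeMatrix, LaggedMixedModel, _design_arrays
from .preprocess import build_lagged_design, item_columns

__all__ = [
    "PermutationDistribution",
    "StratumComparison",
    "SimesResult",
    "permute_outcome_within_subject",
    "permute_group_labels",
    "null_distribution_edges",
    "edge_pvalue",
    "pvalue_matrix",
    "stratum_difference_test",
    "simes_correct",
]

log = logging.getLogger(__name__)

_SCHEME_COLS = {"trauma": "trauma_tertile", "liability": "liability_class"}


def _label_column(scheme: str) -> str:
    return _SCHEME_COLS.get(scheme, scheme)


def _perm_seed(master_seed: int, index: int, tag: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(tag), int(index))))


# ---------------------------------------------------------------------------
# permutation primitives
# ---------------------------------------------------------------------------

def permute_outcome_within_subject(design: pd.DataFrame, seed) -> pd.DataFrame:
    """Shuffle ``outcome_value`` uniformly at random within each subject.

    Predictors, time and clustering columns are untouched, so the multilevel
    structure of the data is preserved exactly; each subject's multiset of
    outcome values is conserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = design.copy()
    y = out["outcome_value"].to_numpy(dtype=float).copy()
    for idx in out.groupby("subject_id").indices.values():
        y[idx] = y[rng.permutation(idx)]
    out["outcome_value"] = y
    return out


def permute_group_labels(labels: pd.DataFrame, scheme: str, seed, unit: str = "subject") -> pd.DataFrame:
    """Permute stratum labels across participants; group sizes are conserved.

    Subjects labelled ``excluded`` keep their label (they are outside the
    analysis).  ``unit="pair"`` permutes pair-wise instead, assigning both
    members of a pair the labels of another pair's members — an option for
    designs where individual-level shuffling breaks pair exchangeability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    col = _label_column(scheme)
    out = labels.copy()
    mask = (out[col] != "excluded").to_numpy()
    vals = out.loc[mask, col].to_numpy()
    if unit == "subject":
        out.loc[mask, col] = vals[rng.permutation(len(vals))]
    elif unit == "pair":
        sub = out.loc[mask]
        if "pair_id" not in sub.columns:
            raise ValueError("pair-unit permutation needs a pair_id column in labels")
        pairs = sub["pair_id"]
        uniq = pairs.unique()
        perm = uniq[rng.permutation(len(uniq))]
        mapping = dict(zip(uniq, perm))
        # give each pair the label multiset of its image pair, member-by-member
        by_pair = {p: sub.loc[pairs == p, col].to_numpy() for p in uniq}
        new = np.empty(len(sub), dtype=object)
        for i, p in enumerate(uniq):
            src = by_pair[mapping[p]]
            tgt_idx = np.flatnonzero((pairs == p).to_numpy())
            m = min(len(src), len(tgt_idx))
            new[tgt_idx[:m]] = src[:m]
            if len(tgt_idx) > m:  # uneven pair sizes: recycle the image's labels
                new[tgt_idx[m:]] = src[np.arange(len(tgt_idx) - m) % len(src)]
        out.loc[mask, col] = new
    else:
        raise ValueError("unit must be 'subject' or 'pair'")
    return out


# ---------------------------------------------------------------------------
# fast refitting engine
# ---------------------------------------------------------------------------

class _OutcomeCache:
    """Design + fitter cache for one outcome on one subject set."""

    def __init__(self, design: pd.DataFrame, items: Sequence[str], reml: bool):
        X, names = _design_arrays(design, items)
        self.model = LaggedMixedModel(
            design["pair_id"].to_numpy(),
            design["subject_id"].to_numpy(),
            design["beep_number"].to_numpy(dtype=float),
            X,
            y=design["outcome_value"].to_numpy(dtype=float),
            column_names=names,
        )
        self.reml = reml
        # subject codes of the internally sorted rows (contiguous blocks)
        self.subj_codes = self.model.subj_codes
        self.y_sorted = self.model.y
        self.k = len(items)
        beta, vc, conv, f, u = self.model.fit(reml=reml)
        self.observed_beta = beta
        self.observed_vc = vc
        self.observed_converged = conv
        self.warm = u

    def observed_coefs(self) -> np.ndarray:
        return self.observed_beta[1 : 1 + self.k]

    def refit_shuffled(self, rng: np.random.Generator):
        keys = rng.random(self.model.n)
        perm = np.lexsort((keys, self.subj_codes))
        y_perm = self.y_sorted[perm]
        beta, _, conv, _, _ = self.model.fit(y=y_perm, reml=self.reml, start=self.warm, presorted=True)
        return beta[1 : 1 + self.k], conv


class NetworkEngine:
    """Per-outcome caches for one subject set; supports fast permutation refits."""

    def __init__(self, panel: pd.DataFrame, items: Sequence[str] | None = None, reml: bool = True):
        self.items = tuple(items) if items is not None else tuple(item_columns(panel))
        self.caches = [
            _OutcomeCache(build_lagged_design(panel, it), self.items, reml) for it in self.items
        ]

    def observed_w(self) -> np.ndarray:
        return np.column_stack([c.observed_coefs() for c in self.caches])

    def observed_edge_matrix(self, stratum: str = "all") -> EdgeMatrix:
        conv = np.array([c.observed_converged for c in self.caches])
        return EdgeMatrix(stratum=stratum, items=self.items, w=self.observed_w(), converged=conv)

    def permuted_w(self, rng: np.random.Generator) -> np.ndarray:
        k = len(self.items)
        w = np.full((k, k), np.nan)
        for j, cache in enumerate(self.caches):
            coefs, conv = cache.refit_shuffled(rng)
            if conv:
                w[:, j] = coefs
        return w


# ---------------------------------------------------------------------------
# null distributions and p-values
# ---------------------------------------------------------------------------

@dataclass
class PermutationDistribution:
    """Per-edge null coefficients (or coefficient differences) from refits."""

    scheme: str
    stratum: str
    items: tuple[str, ...]
    values: np.ndarray  # (n_perm, k, k); NaN where a refit failed
    n_permutations: int
    seed: int

    @property
    def n_effective(self) -> np.ndarray:
        return np.isfinite(self.values).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.values.shape[0]):
            for i, p in enumerate(self.items):
                for j, o in enumerate(self.items):
                    rows.append((self.stratum, p, o, r, self.values[r, i, j]))
        return pd.DataFrame(
            rows, columns=["stratum", "predictor", "outcome", "permutation", "value"]
        )


def null_distribution_edges(
    panel: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    scheme: str | None = None,
    stratum: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    items: Sequence[str] | None = None,
    reml: bool = True,
    engine: NetworkEngine | None = None,
) -> tuple[EdgeMatrix, PermutationDistribution]:
    """Observed edge matrix plus its outcome-shuffle null distribution.

    For every permutation the outcome of each of the k models is shuffled
    within subject and all k models are refitted; all k^2 coefficients are
    recorded.  Returns ``(observed, null)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if engine is None:
        if labels is not None:
            col = _label_column(scheme)
            ids = labels.loc[labels[col] == stratum, "subject_id"]
            panel = panel[panel["subject_id"].isin(ids)]
        engine = NetworkEngine(panel, items=items, reml=reml)
    k = len(engine.items)
    values = np.full((n_perm, k, k), np.nan)
    for r in range(n_perm):
        values[r] = engine.permuted_w(_perm_seed(seed, r, tag=1))
    n_failed = int(np.isnan(values).any(axis=(1, 2)).sum())
    if n_failed:
        log.info("null_distribution_edges: %d/%d permutations had failed refits", n_failed, n_perm)
    observed = engine.observed_edge_matrix(stratum=str(stratum or "all"))
    dist = PermutationDistribution(
        scheme="outcome_shuffle",
        stratum=str(stratum or "all"),
        items=engine.items,
        values=values,
        n_permutations=n_perm,
        seed=seed,
    )
    return observed, dist


def edge_pvalue(observed: float, null_values: np.ndarray, tail: str = "signed") -> float:
    """Two-sided Monte-Carlo p-value of one observed coefficient.

    ``signed`` (default): count null values at least as extreme on the side of
    the observed sign, double, cap at one:  ``p = min(1, 2 (c+1) / (N+1))``;
    an observed value of exactly zero hits the cap and returns 1.
    ``absolute``: count ``|v| >= |observed|`` without doubling.
    Add-one smoothing keeps p in (0, 1] and recovers the plain proportion as
    the number of permutations grows.
    """
    if not np.isfinite(observed):
        return float("nan")  # non-converged observed fit: excluded from inference
    vals = np.asarray(null_values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n == 0:
        raise ValueError("empty null distribution (no successful refits)")
    if tail == "signed":
        s = np.sign(observed)
        c = int(np.sum(vals * s >= abs(observed)))
        return min(1.0, 2.0 * (c + 1) / (n + 1))
    if tail == "absolute":
        c = int(np.sum(np.abs(vals) >= abs(observed)))
        return (c + 1) / (n + 1)
    raise ValueError("tail must be 'signed' or 'absolute'")


def pvalue_matrix(observed: np.ndarray, dist: PermutationDistribution, tail: str = "signed") -> np.ndarray:
    """Two-sided p-value for every cell of an edge (or difference) matrix."""
    observed = np.asarray(observed, dtype=float)
    k = observed.shape[0]
    P = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            P[i, j] = edge_pvalue(observed[i, j], dist.values[:, i, j], tail=tail)
    return P


# ---------------------------------------------------------------------------
# between-stratum comparison
# ---------------------------------------------------------------------------

@dataclass
class StratumComparison:
    scheme: str
    strata: tuple[str, str]
    items: tuple[str, ...]
    observed_diff: np.ndarray  # W_a - W_b
    null: PermutationDistribution
    pvalues: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.items):
            for j, o in enumerate(self.items):
                rows.append(
                    {
                        "scheme": self.scheme,
                        "stratum_a": self.strata[0],
                        "stratum_b": self.strata[1],
                        "predictor": p,
                        "outcome": o,
                        "diff": self.observed_diff[i, j],
                        "p": self.pvalues[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _pooled_designs(panel: pd.DataFrame, items: Sequence[str]) -> list[pd.DataFrame]:
    return [build_lagged_design(panel, it) for it in items]


def _fit_w_from_designs(designs, items, subject_ids, reml, warm=None):
    """Fit all outcome models on the subjects in ``subject_ids`` using row
    subsets of pooled designs (person-mean centering is subset-stable)."""
    k = len(items)
    w = np.full((k, k), np.nan)
    conv = np.zeros(k, dtype=bool)
    warms = []
    for j, design in enumerate(designs):
        sub = design[design["subject_id"].isin(subject_ids)]
        X, names = _design_arrays(sub, items)
        model = LaggedMixedModel(
            sub["pair_id"].to_numpy(),
            sub["subject_id"].to_numpy(),
            sub["beep_number"].to_numpy(dtype=float),
            X,
            y=sub["outcome_value"].to_numpy(dtype=float),
            column_names=names,
        )
        start = warm[j] if warm is not None else None
        beta, _, cj, _, u = model.fit(reml=reml, start=start)
        warms.append(u)
        w[:, j] = beta[1 : 1 + k]
        conv[j] = cj
    return w, conv, warms


def stratum_difference_test(
    panel: pd.DataFrame,
    labels: pd.DataFrame,
    scheme: str,
    strata: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    items: Sequence[str] | None = None,
    reml: bool = True,
    tail: str = "signed",
) -> StratumComparison:
    """Permutation test of edge-wise coefficient differences between two strata.

    The statistic per cell is ``B_a - B_b``.  The null shuffles stratum labels
    across the participants of the two strata and refits both networks per
    permutation; all 36 cells are tested regardless of their marginal
    significance.  p-values follow the same two-sided doubled-count rule as
    the single-edge test.
    """
    col = _label_column(scheme)
    a, b = strata
    lab = labels[labels[col].isin([a, b])]
    if (lab[col] == a).sum() == 0 or (lab[col] == b).sum() == 0:
        raise ValueError(f"both strata must be nonempty: {strata}")
    subjects = lab["subject_id"].to_numpy()
    is_a = (lab[col] == a).to_numpy()
    pool = panel[panel["subject_id"].isin(subjects)]
    if items is None:
        items = tuple(item_columns(pool))
    designs = _pooled_designs(pool, items)

    ids_a = set(subjects[is_a])
    ids_b = set(subjects[~is_a])
    w_a, conv_a, warm_a = _fit_w_from_designs(designs, items, ids_a, reml)
    w_b, conv_b, warm_b = _fit_w_from_designs(designs, items, ids_b, reml)
    observed = w_a - w_b
    cell_ok = np.outer(np.ones(len(items), dtype=bool), conv_a & conv_b)

    k = len(items)
    values = np.full((n_perm, k, k), np.nan)
    for r in range(n_perm):
        rng = _perm_seed(seed, r, tag=2)
        shuffled = is_a[rng.permutation(len(is_a))]
        pa = set(subjects[shuffled])
        pb = set(subjects[~shuffled])
        wa, ca, warm_a = _fit_w_from_designs(designs, items, pa, reml, warm=warm_a)
        wb, cb, warm_b = _fit_w_from_designs(designs, items, pb, reml, warm=warm_b)
        diff = wa - wb
        bad = ~(ca & cb)
        if bad.any():
            diff[:, bad] = np.nan
        values[r] = diff

    dist = PermutationDistribution(
        scheme="label_shuffle",
        stratum=f"{a}-vs-{b}",
        items=tuple(items),
        values=values,
        n_permutations=n_perm,
        seed=seed,
    )
    P = pvalue_matrix(observed, dist, tail=tail)
    # cells whose observed fits did not converge are excluded from inference
    P[~cell_ok] = np.nan
    return StratumComparison(
        scheme=scheme,
        strata=(str(a), str(b)),
        items=tuple(items),
        observed_diff=observed,
        null=dist,
        pvalues=P,
    )


# ---------------------------------------------------------------------------
# Simes step-up correction
# ---------------------------------------------------------------------------

@dataclass
class SimesResult:
    family: str
    m: int
    alpha_nominal: float
    k_rejected: int
    corrected_alpha: float
    mask: np.ndarray  # same shape as the input p-values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [self.family],
                "m": [self.m],
                "alpha_nominal": [self.alpha_nominal],
                "k_rejected": [self.k_rejected],
                "corrected_alpha": [self.corrected_alpha],
            }
        )


def simes_correct(pvalues, alpha: float = 0.05, family: str = "") -> SimesResult:
    """Simes step-up multiple-testing threshold over a family of m p-values.

    Sort ascending; ``k = max{ i : p_(i) <= i * alpha / m }`` (0 if none);
    the single corrected threshold is ``corrected_alpha = k * alpha / m`` and
    every p at or below it is rejected.  NaN entries (cells excluded from
    inference) are ignored for ``m`` and never rejected.
    """
    arr = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if vals.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((vals <= 0) | (vals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = vals.size
    order = np.sort(vals)
    thresh = np.arange(1, m + 1) * alpha / m
    hits = np.flatnonzero(order <= thresh)
    k = int(hits[-1] + 1) if hits.size else 0
    corrected = k * alpha / m
    mask = np.zeros(arr.shape, dtype=bool)
    mask[finite] = vals <= corrected if k > 0 else False
    return SimesResult(
        family=family,
        m=m,
        alpha_nominal=alpha,
        k_rejected=k,
        corrected_alpha=float(corrected),
        mask=mask,
    )
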