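"""Three-level time-lagged mixed model and stratum edge matrices.

For each affect item as outcome, the model regresses the rating at beep t on
all person-mean-centered item ratings at beep t-1 plus a linear time trend
(beep number 1..T), with random intercepts for twin pair and for subject and a
random subject-level slope of time:

    y_ijk = (B0 + e_ijk) + sum_p B_p * lag_p,ijk + (B7 + u7_jk) * time_ijk
            + a_k + b_jk

with independent variance components  a_k ~ N(0, s2_pair),  b_jk ~ N(0,
s2_subj),  u7_jk ~ N(0, s2_time),  e ~ N(0, s2_resid).  The k x k matrix of
lagged coefficients across the k outcome models is the directed network: entry
(p, o) is the weight of the edge item_p(t-1) -> item_o(t), the diagonal the
autoregressive self-loops.

Estimation is profiled restricted maximum likelihood specialised to this
random-effects structure.  Random-effect design blocks are per twin pair and
tiny (one pair column plus an intercept and a time column per member), so the
likelihood reduces, via the Woodbury identity, to batched small-matrix algebra
over pairs; only three variance ratios are optimised numerically.  This makes
a single fit a few milliseconds and permutation refits (same fixed design, new
outcome vector) cheaper still — the property the permutation machinery relies
on.  Agreement with statsmodels' MixedLM and with pooled OLS in the
zero-variance limit is enforced in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .preprocess import build_lagged_design, item_columns

__all__ = [
    "ModelSpec",
    "FitResult",
    "EdgeMatrix",
    "LaggedMixedModel",
    "fit_lagged_model",
    "estimate_network",
]

_LOG_GAMMA_BOUNDS = [(-24.0, 6.0), (-24.0, 6.0), (-30.0, 3.0)]
_DEFAULT_START = np.log([0.2, 0.2, 1e-4])


@dataclass
class ModelSpec:
    """Specification of one outcome model: which item is the outcome, the
    (ordered) lagged predictors, and the estimation criterion."""

    outcome_item: str
    predictor_items: Sequence[str]
    reml: bool = True
    max_iter: int = 200
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.outcome_item not in self.predictor_items:
            raise ValueError("predictors must include the outcome's own lag")


@dataclass
class FitResult:
    outcome_item: str
    intercept: float
    b_lag: dict[str, float]
    b_time: float
    var_pair_intercept: float
    var_subject_intercept: float
    var_subject_time_slope: float
    var_residual: float
    n_obs: int
    n_subjects: int
    n_pairs: int
    converged: bool
    method: str = "reml"
    neg2ll: float = float("nan")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(list(self.b_lag.values()))


@dataclass
class EdgeMatrix:
    """Directed lagged-coefficient matrix for one stratum.

    ``w[p, o]`` is the coefficient of ``items[p]`` at t-1 in the model for
    ``items[o]`` at t; the diagonal holds the autoregressive self-loops.
    """

    stratum: str
    items: tuple[str, ...]
    w: np.ndarray
    converged: np.ndarray = field(default=None)  # per-outcome flag
    fits: dict[str, FitResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        k = len(self.items)
        if self.w.shape != (k, k):
            raise ValueError("edge matrix must be k x k")
        if self.converged is None:
            self.converged = np.ones(k, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{it}_t-1" for it in self.items]
        cols = [f"{it}_t" for it in self.items]
        return pd.DataFrame(self.w, index=idx, columns=cols)

    def to_edgelist(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.items):
            for j, o in enumerate(self.items):
                rows.append(
                    {
                        "stratum": self.stratum,
                        "predictor": p,
                        "outcome": o,
                        "B": self.w[i, j],
                        "converged": bool(self.converged[j]),
                    }
                )
        return pd.DataFrame(rows)


class LaggedMixedModel:
    """Profiled-REML fitter for the pair/subject/time-slope model.

    Construction precomputes every cross-product that does not involve the
    outcome (random-design Gram blocks per pair, fixed-design Gram matrix), so
    repeated fits with new outcome vectors — the permutation loop — reuse the
    cache.  Rows are regrouped subject-contiguously; coefficient estimates are
    invariant to the input row order.
    """

    def __init__(
        self,
        pair_ids: np.ndarray,
        subject_ids: np.ndarray,
        time: np.ndarray,
        X: np.ndarray,
        y: np.ndarray | None = None,
        column_names: Sequence[str] | None = None,
    ):
        pair_ids = np.asarray(pair_ids)
        subject_ids = np.asarray(subject_ids)
        time = np.asarray(time, dtype=float)
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        self.column_names = list(column_names) if column_names is not None else [
            f"x{i}" for i in range(p)
        ]

        # order rows subject-contiguously (stable), remember subject blocks
        order = np.lexsort((np.arange(n), subject_ids, pair_ids))
        self._order = order
        pair_ids, subject_ids = pair_ids[order], subject_ids[order]
        time, X = time[order], X[order]
        self.X, self.time = X, time
        self.n, self.p = n, p

        sd = X.std(axis=0)
        const = np.where(sd <= 1e-12)[0]
        const = [i for i in const if not np.allclose(X[:, i], 1.0)]  # intercept allowed
        if const:
            bad = ", ".join(self.column_names[i] for i in const)
            raise ValueError(f"singular design: predictor(s) constant across sample: {bad}")

        self.subj_codes, subj_first = pd.factorize(subject_ids)
        self.pair_codes, _ = pd.factorize(pair_ids)
        self.n_subjects = len(subj_first)
        self.n_pairs = self.pair_codes.max() + 1

        # subject -> pair and member position within pair
        subj_pair = np.zeros(self.n_subjects, dtype=int)
        subj_pair[self.subj_codes] = self.pair_codes
        members = np.zeros(self.n_subjects, dtype=int)
        pos = {}
        for s in range(self.n_subjects):
            g = subj_pair[s]
            members[s] = pos.get(g, 0)
            pos[g] = members[s] + 1
        self._subj_pair, self._subj_pos = subj_pair, members
        m_max = members.max() + 1
        self.q = 1 + 2 * m_max
        self._m_max = m_max
        comp = np.zeros((self.q, 3))
        comp[0, 0] = 1.0
        comp[1 : 1 + m_max, 1] = 1.0
        comp[1 + m_max :, 2] = 1.0
        self._comp_indicator = comp

        G, q = self.n_pairs, self.q
        ns = np.bincount(self.subj_codes, minlength=self.n_subjects)
        st = np.bincount(self.subj_codes, weights=time, minlength=self.n_subjects)
        st2 = np.bincount(self.subj_codes, weights=time * time, minlength=self.n_subjects)

        S = np.zeros((G, q, q))
        rs = 1 + members  # subject-intercept row index within the pair block
        rt = 1 + m_max + members
        np.add.at(S, (subj_pair, 0, 0), ns)  # accumulates to the pair's row count
        S[subj_pair, 0, rs] = ns
        S[subj_pair, rs, 0] = ns
        S[subj_pair, 0, rt] = st
        S[subj_pair, rt, 0] = st
        S[subj_pair, rs, rs] = ns
        S[subj_pair, rs, rt] = st
        S[subj_pair, rt, rs] = st
        S[subj_pair, rt, rt] = st2
        self._S = S

        SX = np.zeros((self.n_subjects, p))
        StX = np.zeros((self.n_subjects, p))
        np.add.at(SX, self.subj_codes, X)
        np.add.at(StX, self.subj_codes, X * time[:, None])
        T = np.zeros((G, q, p))
        np.add.at(T, (subj_pair, np.zeros_like(rs)), SX)
        T[subj_pair, rs] = SX
        T[subj_pair, rt] = StX
        self._T = T

        self.XtX = X.T @ X
        self._last_u: np.ndarray | None = None
        self.y = None if y is None else np.asarray(y, dtype=float)[order]

    # -- outcome-dependent cross products ----------------------------------
    def _y_parts(self, y: np.ndarray):
        sy = np.bincount(self.subj_codes, weights=y, minlength=self.n_subjects)
        sty = np.bincount(self.subj_codes, weights=self.time * y, minlength=self.n_subjects)
        Zty = np.zeros((self.n_pairs, self.q))
        np.add.at(Zty, (self._subj_pair, np.zeros(self.n_subjects, dtype=int)), sy)
        Zty[self._subj_pair, 1 + self._subj_pos] = sy
        Zty[self._subj_pair, 1 + self._m_max + self._subj_pos] = sty
        return Zty, self.X.T @ y, float(y @ y)

    def _lam(self, gamma: np.ndarray) -> np.ndarray:
        lam = np.empty(self.q)
        lam[0] = np.sqrt(gamma[0])
        lam[1 : 1 + self._m_max] = np.sqrt(gamma[1])
        lam[1 + self._m_max :] = np.sqrt(gamma[2])
        return lam

    def _profile(self, gamma: np.ndarray, yp, reml: bool, grad: bool = False):
        """Profiled -2 log-likelihood (constants dropped) and GLS quantities.

        With ``grad=True`` also returns the analytic gradient with respect to
        the three variance ratios (standard REML/ML score using the projection
        matrix P: tr terms from log|V| and log|X'V^-1 X|, the quadratic term
        from -|Z_i' P y|^2).
        """
        Zty, Xty, yty = yp
        p, q = self.p, self.q
        lam = self._lam(gamma)
        S, T = self._S, self._T
        M = lam[None, :, None] * S * lam[None, None, :]
        M[:, np.arange(q), np.arange(q)] += 1.0
        L = np.linalg.cholesky(M)
        logdetV = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        A = lam[None, :, None] * T
        b = lam[None, :] * Zty
        if grad:
            LamS = lam[:, None] * S  # rows scaled
            rhs = np.concatenate([A, b[:, :, None], LamS], axis=2)
        else:
            rhs = np.concatenate([A, b[:, :, None]], axis=2)
        W = np.linalg.solve(M, rhs)
        XVX = self.XtX - np.einsum("gqp,gqr->pr", A, W[:, :, :p])
        XVy = Xty - np.einsum("gqp,gq->p", A, W[:, :, p])
        yVy = yty - np.einsum("gq,gq->", b, W[:, :, p])
        beta = np.linalg.solve(XVX, XVy)
        rVr = max(yVy - beta @ XVy, 1e-300)
        dof = self.n - p if reml else self.n
        if reml:
            _, logdetXVX = np.linalg.slogdet(XVX)
            f = logdetV + logdetXVX + dof * np.log(rVr / dof)
        else:
            f = logdetV + self.n * np.log(rVr / self.n)
        sigma2 = rVr / dof
        if not grad:
            return f, beta, sigma2
        # Z'V^-1 Z diagonal, Z'V^-1 X, Z'V^-1 y per group
        SLam = S * lam[None, None, :]  # columns scaled
        Cdiag = np.diagonal(S, axis1=1, axis2=2) - np.einsum(
            "gqr,grq->gq", SLam, W[:, :, p + 1 :]
        )
        U = T - np.einsum("gqr,grp->gqp", SLam, W[:, :, :p])  # Z'V^-1 X
        zvy = Zty - np.einsum("gqr,gr->gq", SLam, W[:, :, p])
        e = zvy - np.einsum("gqp,p->gq", U, beta)  # Z' P y
        comp = self._comp_indicator  # (q, 3)
        term1 = np.einsum("gq,qc->c", Cdiag, comp)
        term3 = np.einsum("gq,qc->c", e * e, comp)
        g_vec = term1 - dof * term3 / rVr
        if reml:
            XVXinv = np.linalg.inv(XVX)
            term2 = np.einsum("gqp,pr,gqr->gq", U, XVXinv, U)
            g_vec = g_vec - np.einsum("gq,qc->c", term2, comp)
        return f, beta, sigma2, g_vec

    def fit(self, y: np.ndarray | None = None, reml: bool = True, start=None, presorted=False):
        """Estimate fixed effects and variance components.

        ``y`` defaults to the outcome supplied at construction.  ``start`` is
        an optional warm start (log variance ratios) — permutation loops pass
        the previous optimum.  Returns ``(beta, varcomps, converged, neg2ll,
        u_hat)`` with ``varcomps = (s2_pair, s2_subj, s2_time, s2_resid)``.
        """
        if y is None:
            if self.y is None:
                raise ValueError("no outcome vector supplied")
            yv = self.y
        else:
            yv = np.asarray(y, dtype=float)
            if not presorted:
                yv = yv[self._order]
        yp = self._y_parts(yv)
        u0 = np.asarray(start if start is not None else (
            self._last_u if self._last_u is not None else _DEFAULT_START
        ), dtype=float)

        def objective(u):
            gamma = np.exp(u)
            f, _, _, g = self._profile(gamma, yp, reml, grad=True)
            return f, g * gamma  # chain rule to log scale

        res = minimize(
            objective,
            u0,
            jac=True,
            method="L-BFGS-B",
            bounds=_LOG_GAMMA_BOUNDS,
            options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
        )
        converged = bool(res.success)
        if not converged:
            # L-BFGS-B line searches occasionally abort near flat/boundary
            # regions; polish derivative-free from the best point found
            x0 = res.x if np.isfinite(res.fun) else u0
            retry = minimize(
                lambda u: self._profile(np.exp(u), yp, reml)[0],
                x0,
                method="Nelder-Mead",
                bounds=_LOG_GAMMA_BOUNDS,
                options={"maxiter": 400, "fatol": 1e-10, "xatol": 1e-7},
            )
            if np.isfinite(retry.fun) and retry.fun <= (res.fun if np.isfinite(res.fun) else np.inf):
                res = retry
                converged = bool(retry.success)
        self._last_u = res.x.copy()
        gamma = np.exp(res.x)
        f, beta, sigma2 = self._profile(gamma, yp, reml)
        varcomps = np.array([gamma[0] * sigma2, gamma[1] * sigma2, gamma[2] * sigma2, sigma2])
        # ratios driven to the lower bound are boundary zeros
        varcomps[:3][gamma < 1e-9] = 0.0
        return beta, varcomps, converged, float(f), res.x.copy()


def _design_arrays(design: pd.DataFrame, predictor_items: Sequence[str]):
    lag_cols = [f"lag_{it}" for it in predictor_items]
    missing = [c for c in lag_cols if c not in design.columns]
    if missing:
        raise KeyError(f"design lacks lagged predictor columns: {missing}")
    n = len(design)
    X = np.empty((n, len(lag_cols) + 2))
    X[:, 0] = 1.0
    X[:, 1:-1] = design[lag_cols].to_numpy(dtype=float)
    X[:, -1] = design["beep_number"].to_numpy(dtype=float)
    names = ["intercept"] + lag_cols + ["time"]
    return X, names


def fit_lagged_model(design: pd.DataFrame, spec: ModelSpec, min_rows: int = 30) -> FitResult:
    """Fit the three-level lagged model for one outcome on a prepared design.

    Defaults to REML; on non-convergence the fit is retried under ML and, if
    that also fails, the result is returned flagged rather than dropped.
    """
    if len(design) < min_rows:
        raise ValueError(f"design has {len(design)} rows; need at least {min_rows}")
    if design["subject_id"].nunique() < 2 or design["pair_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects in at least 2 pairs")
    X, names = _design_arrays(design, spec.predictor_items)
    model = LaggedMixedModel(
        design["pair_id"].to_numpy(),
        design["subject_id"].to_numpy(),
        design["beep_number"].to_numpy(dtype=float),
        X,
        y=design["outcome_value"].to_numpy(dtype=float),
        column_names=names,
    )
    method = "reml" if spec.reml else "ml"
    beta, vc, conv, f, _ = model.fit(reml=spec.reml)
    if not conv and spec.reml:
        beta, vc, conv, f, _ = model.fit(reml=False)
        method = "ml"
    k = len(spec.predictor_items)
    return FitResult(
        outcome_item=spec.outcome_item,
        intercept=float(beta[0]),
        b_lag={it: float(beta[1 + i]) for i, it in enumerate(spec.predictor_items)},
        b_time=float(beta[1 + k]),
        var_pair_intercept=float(vc[0]),
        var_subject_intercept=float(vc[1]),
        var_subject_time_slope=float(vc[2]),
        var_residual=float(vc[3]),
        n_obs=model.n,
        n_subjects=model.n_subjects,
        n_pairs=model.n_pairs,
        converged=conv,
        method=method,
        neg2ll=f,
    )


def estimate_network(
    panel: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    scheme: str | None = None,
    stratum: str | None = None,
    items: Sequence[str] | None = None,
    reml: bool = True,
) -> EdgeMatrix:
    """Fit all k outcome models on one stratum and assemble the edge matrix.

    ``labels`` maps subject_id to a stratum column (``trauma_tertile`` or
    ``liability_class``); with ``labels=None`` the whole panel is one stratum.
    """
    if items is None:
        items = item_columns(panel)
    items = tuple(items)
    if labels is not None:
        col = {"trauma": "trauma_tertile", "liability": "liability_class"}.get(scheme, scheme)
        ids = labels.loc[labels[col] == stratum, "subject_id"]
        sub = panel[panel["subject_id"].isin(ids)]
    else:
        sub = panel
        stratum = stratum or "all"
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} is empty")
    k = len(items)
    w = np.full((k, k), np.nan)
    conv = np.zeros(k, dtype=bool)
    fits: dict[str, FitResult] = {}
    for j, outcome in enumerate(items):
        design = build_lagged_design(sub, outcome)
        fit = fit_lagged_model(design, ModelSpec(outcome, items, reml=reml))
        fits[outcome] = fit
        conv[j] = fit.converged
        for i, pred in enumerate(items):
            w[i, j] = fit.b_lag[pred]
    return EdgeMatrix(stratum=str(stratum), items=items, w=w, converged=conv, fits=fits)
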