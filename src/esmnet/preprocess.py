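"""Filtering, stratification and lag construction for ESM panels.

Turns a raw beep-level panel into the analysis tables the lagged network model
consumes: validity filtering on report delay, exclusion of low-compliance
subjects, trauma-tertile and co-twin genetic-liability stratum labels, and the
lag-1 design with person-mean-centered predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PANEL_META_COLUMNS, DEFAULT_CTQ_REVERSE_KEYS

__all__ = [
    "item_columns",
    "filter_valid_reports",
    "exclude_sparse_subjects",
    "score_ctq",
    "assign_trauma_tertiles",
    "assign_genetic_liability",
    "build_lagged_design",
    "person_mean_center",
    "screen_floor_effects",
    "FloorScreenReport",
]

log = logging.getLogger(__name__)


def item_columns(panel: pd.DataFrame) -> list[str]:
    """Affect-item columns of a panel (everything that is not schedule metadata)."""
    return [c for c in panel.columns if c not in PANEL_META_COLUMNS]


def filter_valid_reports(panel: pd.DataFrame, max_delay_min: float = 15.0) -> pd.DataFrame:
    """Drop reports completed more than ``max_delay_min`` after the beep.

    A delay of exactly the cutoff is retained (only *more than* 15 min is
    excluded); a missing delay counts as invalid.
    """
    delay = panel["response_delay_min"]
    keep = delay.notna() & (delay <= max_delay_min)
    dropped = int((~keep).sum())
    log.info("filter_valid_reports: dropped %d of %d reports", dropped, len(panel))
    out = panel.loc[keep].copy()
    if out.empty:
        log.warning("filter_valid_reports: no valid reports remain")
    return out


def exclude_sparse_subjects(panel: pd.DataFrame, min_valid: int = 17) -> pd.DataFrame:
    """Remove every row of subjects with fewer than ``min_valid`` valid reports.

    Applied after validity filtering; removal is all-or-nothing per subject.
    """
    counts = panel.groupby("subject_id")["beep_number"].size()
    keep_ids = counts.index[counts >= min_valid]
    n_excluded = counts.size - len(keep_ids)
    log.info("exclude_sparse_subjects: excluded %d of %d subjects", n_excluded, counts.size)
    return panel[panel["subject_id"].isin(keep_ids)].copy()


def score_ctq(items, reverse_keys=DEFAULT_CTQ_REVERSE_KEYS) -> float:
    """Mean trauma-questionnaire score with reverse-keyed items flipped (x -> 6 - x).

    ``reverse_keys`` are 0-based positions within the administered item list;
    the divisor is the number of administered items.
    """
    arr = np.asarray(items, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("missing trauma items are not allowed")
    if arr.min() < 1 or arr.max() > 5:
        raise ValueError("trauma items must lie in [1, 5]")
    keyed = arr.copy()
    rev = [i for i in reverse_keys if i < arr.size]
    keyed[rev] = 6 - keyed[rev]
    return float(keyed.mean())


def assign_trauma_tertiles(meta: pd.DataFrame) -> pd.DataFrame:
    """Partition subjects into low/medium/high trauma tertiles of ``ctq_mean``.

    Cut at the empirical 1/3 and 2/3 quantiles.  Ties at a boundary are
    resolved deterministically: subjects sorted by (score, subject_id) fill the
    lower tertile up to its quota (ceil of a third) before the next one starts,
    so the three groups always partition the sample with near-equal sizes.
    """
    if meta["ctq_mean"].isna().any():
        raise ValueError("ctq_mean missing for some subjects")
    if meta["ctq_mean"].nunique() < 3:
        raise ValueError("fewer than 3 distinct trauma scores; tertiles undefined")
    order = meta[["subject_id", "ctq_mean"]].sort_values(
        ["ctq_mean", "subject_id"], kind="mergesort"
    )
    n = len(order)
    n_low = -(-n // 3)
    n_med = -(-(n - n_low) // 2)
    labels = np.empty(n, dtype=object)
    labels[:n_low] = "low"
    labels[n_low : n_low + n_med] = "medium"
    labels[n_low + n_med :] = "high"
    out = pd.DataFrame({"subject_id": order["subject_id"].to_numpy(), "trauma_tertile": labels})
    return out.sort_values("subject_id", ignore_index=True)


def assign_genetic_liability(meta: pd.DataFrame, pct: float = 75.0) -> pd.DataFrame:
    """Classify twins by co-twin psychopathology and zygosity.

    The co-twin's averaged symptom-checklist score is dichotomised at the
    sample ``pct`` percentile (linear interpolation, computed over retained
    twins).  Classes: ``low`` (co-twin below cutoff, the reference),
    ``intermediate`` (DZ co-twin high), ``high`` (MZ co-twin high).  Non-twin
    sisters and twins without an identifiable co-twin are ``excluded``.
    """
    twins = meta[meta["zygosity"].isin(["MZ", "DZ"])]
    cutoff = float(np.percentile(twins["scl90_mean"].to_numpy(dtype=float), pct))
    scl = dict(zip(meta["subject_id"], meta["scl90_mean"]))

    co_twin: dict = {}
    for _, grp in twins.groupby("pair_id"):
        ids = grp["subject_id"].tolist()
        if len(ids) == 2:
            co_twin[ids[0]], co_twin[ids[1]] = ids[1], ids[0]

    labels = []
    for _, row in meta.iterrows():
        sid = row["subject_id"]
        if row["zygosity"] == "SIB" or sid not in co_twin:
            if row["zygosity"] != "SIB":
                log.info("assign_genetic_liability: subject %s has no co-twin; excluded", sid)
            labels.append("excluded")
            continue
        co_high = scl[co_twin[sid]] >= cutoff
        if not co_high:
            labels.append("low")
        elif row["zygosity"] == "DZ":
            labels.append("intermediate")
        else:
            labels.append("high")
    return pd.DataFrame({"subject_id": meta["subject_id"].to_numpy(), "liability_class": labels})


def build_lagged_design(
    panel: pd.DataFrame, outcome_item: str, center: bool = True
) -> pd.DataFrame:
    """Lag-1 design rows for one outcome item.

    A row pairs the outcome at beep t with all items at beep t-1 where the two
    reports are consecutive ``beep_in_day`` values of the same subject and day
    (the last beep of a day never lags the first beep of the next day) and both
    reports survived validity filtering.  A missing mid-day beep breaks both
    adjacent pairs.  Lagged predictor columns are named ``lag_<item>`` and, if
    ``center`` is set, person-mean-centered over this design's rows.
    """
    items = item_columns(panel)
    if outcome_item not in items:
        raise KeyError(f"unknown outcome item {outcome_item!r}")
    df = panel.sort_values(["subject_id", "beep_number"], kind="mergesort")
    grp = df.groupby("subject_id", sort=False)
    prev_day = grp["day"].shift(1)
    prev_bid = grp["beep_in_day"].shift(1)
    contiguous = (prev_day == df["day"]) & (df["beep_in_day"] - prev_bid == 1)

    lag = grp[items].shift(1)
    ok = contiguous & df[outcome_item].notna() & lag.notna().all(axis=1)

    design = pd.DataFrame(
        {
            "pair_id": df.loc[ok, "pair_id"].to_numpy(),
            "subject_id": df.loc[ok, "subject_id"].to_numpy(),
            "beep_number": df.loc[ok, "beep_number"].to_numpy(),
            "outcome_item": outcome_item,
            "outcome_value": df.loc[ok, outcome_item].to_numpy(dtype=float),
        }
    )
    for it in items:
        design[f"lag_{it}"] = lag.loc[ok, it].to_numpy(dtype=float)
    if center:
        design = person_mean_center(design)
    return design.reset_index(drop=True)


def person_mean_center(design: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject's own mean from every ``lag_*`` predictor column.

    Means are taken over the rows of this design, so each centered column sums
    to zero within every subject by construction.
    """
    out = design.copy()
    lag_cols = [c for c in design.columns if c.startswith("lag_")]
    means = out.groupby("subject_id")[lag_cols].transform("mean")
    out[lag_cols] = out[lag_cols] - means
    return out


@dataclass
class FloorScreenReport:
    """Per-item floor-effect screen: fraction of subjects with a horizontal
    lag-1 slope, plus the per-subject slope table."""

    proportion_horizontal: pd.Series
    slopes: pd.DataFrame  # columns: subject_id, item, slope (NaN = undefined), horizontal
    n_subjects_used: pd.Series


def screen_floor_effects(
    panel: pd.DataFrame, slope_eps: float = 0.05, min_pairs: int = 5
) -> FloorScreenReport:
    """Screen items for floor effects via per-subject autoregressive slopes.

    For every subject x item, regress the rating at t on the rating at t-1
    (contiguous within-day pairs).  The slope is *horizontal* when the lagged
    predictor has zero variance for that subject (slope undefined: the classic
    all-1 floor response) or |slope| <= ``slope_eps``.  Subjects contributing
    fewer than ``min_pairs`` lag pairs are excluded from the denominator.
    """
    items = item_columns(panel)
    df = panel.sort_values(["subject_id", "beep_number"], kind="mergesort")
    grp = df.groupby("subject_id", sort=False)
    contiguous = (grp["day"].shift(1) == df["day"]) & (
        df["beep_in_day"] - grp["beep_in_day"].shift(1) == 1
    )
    lag = grp[items].shift(1)

    records = []
    for item in items:
        y_all = df[item]
        x_all = lag[item]
        ok = contiguous & y_all.notna() & x_all.notna()
        sub = pd.DataFrame(
            {"subject_id": df.loc[ok, "subject_id"], "x": x_all[ok], "y": y_all[ok]}
        )
        for sid, g in sub.groupby("subject_id"):
            if len(g) < min_pairs:
                continue
            x = g["x"].to_numpy(dtype=float)
            y = g["y"].to_numpy(dtype=float)
            vx = x.var()
            if vx == 0.0:
                records.append((sid, item, np.nan, True))
            else:
                slope = np.cov(x, y, bias=True)[0, 1] / vx
                records.append((sid, item, slope, abs(slope) <= slope_eps))
    slopes = pd.DataFrame(records, columns=["subject_id", "item", "slope", "horizontal"])
    prop = slopes.groupby("item")["horizontal"].mean().reindex(items).fillna(0.0)
    n_used = slopes.groupby("item")["horizontal"].size().reindex(items).fillna(0).astype(int)
    return FloorScreenReport(proportion_horizontal=prop, slopes=slopes, n_subjects_used=n_used)
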