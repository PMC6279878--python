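"""End-to-end orchestration: simulate -> preprocess -> fit -> permute -> correct
-> centralities, with a results bundle on disk.

The bundle contains, per scheme (trauma tertile / genetic liability) and
stratum: the edge matrix (adjacency and edge-list CSV), edge p-values, the
Simes family decision, centrality indices and GraphML exports (full and
significance-masked), plus between-stratum difference tests for every stratum
pair and a manifest tying everything to the config hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import ensure_dir, read_meta, read_panel
from .metrics import centrality_report, export_graph
from .model import estimate_network
from .permutation import (
    null_distribution_edges,
    pvalue_matrix,
    simes_correct,
    stratum_difference_test,
)
from .preprocess import (
    assign_genetic_liability,
    assign_trauma_tertiles,
    exclude_sparse_subjects,
    filter_valid_reports,
    item_columns,
)
from .simulate import SimConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "preprocess_panel", "stratum_labels"]

log = logging.getLogger(__name__)

_SCHEME_COLS = {"trauma": "trauma_tertile", "liability": "liability_class"}
_STRATA = {"trauma": ("low", "medium", "high"), "liability": ("low", "intermediate", "high")}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    panel_path: str | None = None
    meta_path: str | None = None
    simulate: SimConfig | None = None
    schemes: tuple[str, ...] = ("trauma", "liability")
    n_perm: int = 1000
    alpha: float = 0.05
    max_delay_min: float = 15.0
    min_valid: int = 17
    liability_pct: float = 75.0
    tail: str = "signed"
    out_dir: str = "results"
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("simulate") is not None:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        if "schemes" in d:
            d["schemes"] = tuple(d["schemes"])
        return cls(**d)


def preprocess_panel(panel: pd.DataFrame, max_delay_min: float = 15.0, min_valid: int = 17) -> pd.DataFrame:
    """Validity filtering followed by sparse-subject exclusion."""
    return exclude_sparse_subjects(filter_valid_reports(panel, max_delay_min), min_valid)


def stratum_labels(meta: pd.DataFrame, panel: pd.DataFrame, liability_pct: float = 75.0) -> pd.DataFrame:
    """Both stratification schemes for the subjects retained in the panel."""
    retained = meta[meta["subject_id"].isin(panel["subject_id"].unique())].reset_index(drop=True)
    tert = assign_trauma_tertiles(retained)
    liab = assign_genetic_liability(retained, pct=liability_pct)
    out = retained[["subject_id", "pair_id", "zygosity"]].merge(tert, on="subject_id")
    return out.merge(liab, on="subject_id")


def validate_inputs(panel_path, meta_path) -> list[dict]:
    """Schema check of a panel/meta CSV pair; returns a violation list."""
    violations: list[dict] = []

    def add(table, kind, detail):
        violations.append({"table": table, "kind": kind, "detail": detail})

    try:
        panel = read_panel(panel_path)
    except OSError as e:
        raise OSError(f"cannot read panel: {e}") from e
    try:
        meta = read_meta(meta_path)
    except OSError as e:
        raise OSError(f"cannot read meta: {e}") from e

    required = ["pair_id", "subject_id", "day", "beep_in_day", "beep_number", "response_delay_min"]
    for c in required:
        if c not in panel.columns:
            add("panel", "missing_column", c)
    if not violations:
        dup = panel.duplicated(["subject_id", "beep_number"])
        for row in np.flatnonzero(dup.to_numpy())[:20]:
            add("panel", "duplicate_subject_beep", f"row {row}")
        bad_num = panel["beep_number"] != (panel["day"] - 1) * panel["beep_in_day"].max() + panel["beep_in_day"]
        for row in np.flatnonzero(bad_num.to_numpy())[:20]:
            add("panel", "beep_number_mismatch", f"row {row}")
        for item in item_columns(panel):
            vals = panel[item].dropna()
            out_of_range = vals[(vals < 1) | (vals > 7)]
            for row in out_of_range.index[:20]:
                add("panel", "rating_out_of_range", f"row {row}, column {item}, value {panel.loc[row, item]}")
        delay = panel["response_delay_min"].dropna()
        for row in delay.index[delay < 0][:20]:
            add("panel", "negative_delay", f"row {row}")
    for c in ("subject_id", "pair_id", "zygosity", "ctq_mean", "scl90_mean"):
        if c not in meta.columns:
            add("meta", "missing_column", c)
    if "subject_id" in meta.columns and meta["subject_id"].duplicated().any():
        add("meta", "duplicate_subject", "subject_id not unique")
    return violations


def _family_simes(pmats: dict[str, np.ndarray], alpha: float, family: str):
    """One Simes family across all strata of a scheme (3 x k x k tests)."""
    stacked = np.stack(list(pmats.values()))
    res = simes_correct(stacked, alpha=alpha, family=family)
    masks = {s: res.mask[i] for i, s in enumerate(pmats)}
    return res, masks


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for each requested scheme and write the results bundle.

    Returns a manifest dict (also written to ``out_dir/manifest.json``).
    """
    out = ensure_dir(config.out_dir)
    if config.simulate is not None:
        sim = config.simulate
        panel, meta = generate_cohort(sim)
        panel.to_csv(out / "panel.csv", index=False)
        meta.to_csv(out / "meta.csv", index=False)
    elif config.panel_path and config.meta_path:
        panel, meta = read_panel(config.panel_path), read_meta(config.meta_path)
    else:
        raise ValueError("config must give panel/meta paths or an inline simulation config")

    panel = preprocess_panel(panel, config.max_delay_min, config.min_valid)
    if panel.empty:
        raise RuntimeError("preprocess: no data left after filtering")
    labels = stratum_labels(meta, panel, config.liability_pct)
    labels.to_csv(out / "stratum_labels.csv", index=False)
    items = tuple(item_columns(panel))

    artifacts: dict[str, list[str]] = {}
    for scheme in config.schemes:
        col = _SCHEME_COLS[scheme]
        strata = [s for s in _STRATA[scheme] if (labels[col] == s).any()]
        pmats: dict[str, np.ndarray] = {}
        nets = {}
        files: list[str] = []
        for stratum in strata:
            seed = _stage_seed(config.master_seed, scheme, stratum)
            observed, dist = null_distribution_edges(
                panel, labels, scheme, stratum, n_perm=config.n_perm, seed=seed
            )
            nets[stratum] = observed
            pmats[stratum] = pvalue_matrix(observed.w, dist, tail=config.tail)
            base = out / f"{scheme}_{stratum}"
            observed.to_frame().to_csv(f"{base}_edges.csv")
            observed.to_edgelist().to_csv(f"{base}_edgelist.csv", index=False)
            pd.DataFrame(pmats[stratum], index=items, columns=items).to_csv(f"{base}_pvalues.csv")
            files += [f"{base}_edges.csv", f"{base}_edgelist.csv", f"{base}_pvalues.csv"]

        res, masks = _family_simes(pmats, config.alpha, family=f"{scheme}_edges")
        res.to_frame().to_csv(out / f"{scheme}_simes.csv", index=False)
        files.append(str(out / f"{scheme}_simes.csv"))
        cents = []
        for stratum in strata:
            base = out / f"{scheme}_{stratum}"
            export_graph(nets[stratum], f"{base}.graphml")
            export_graph(nets[stratum], f"{base}_significant.graphml", mask=masks[stratum])
            cents.append(centrality_report(nets[stratum]))
            files += [f"{base}.graphml", f"{base}_significant.graphml"]
        pd.concat(cents, ignore_index=True).to_csv(out / f"{scheme}_centrality.csv", index=False)
        files.append(str(out / f"{scheme}_centrality.csv"))

        comp_p = []
        for i in range(len(strata)):
            for j in range(i + 1, len(strata)):
                pair = (strata[i], strata[j])
                seed = _stage_seed(config.master_seed, scheme, f"{pair[0]}|{pair[1]}")
                comp = stratum_difference_test(
                    panel, labels, scheme, pair, n_perm=config.n_perm, seed=seed, tail=config.tail
                )
                comp.to_frame().to_csv(out / f"{scheme}_diff_{pair[0]}_vs_{pair[1]}.csv", index=False)
                files.append(str(out / f"{scheme}_diff_{pair[0]}_vs_{pair[1]}.csv"))
                comp_p.append(comp.pvalues)
        if comp_p:
            res_b = simes_correct(np.stack(comp_p), alpha=config.alpha, family=f"{scheme}_between")
            res_b.to_frame().to_csv(out / f"{scheme}_between_simes.csv", index=False)
            files.append(str(out / f"{scheme}_between_simes.csv"))
        artifacts[scheme] = [str(f) for f in files]

    cfg = config.to_dict()
    manifest = {
        "esmnet_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "master_seed": config.master_seed,
        "n_subjects": int(panel["subject_id"].nunique()),
        "n_reports": int(len(panel)),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_seed(master_seed: int, scheme: str, stratum: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{scheme}:{stratum}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
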