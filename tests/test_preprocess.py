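import numpy as np
import pandas as pd
import pytest

from esmnet.preprocess import (
    assign_genetic_liability,
    assign_trauma_tertiles,
    build_lagged_design,
    exclude_sparse_subjects,
    filter_valid_reports,
    person_mean_center,
    score_ctq,
    screen_floor_effects,
)
from esmnet.simulate import generate_cohort

from conftest import null_sim_config


def _mini_panel(rows):
    """Panel from (subject, day, beep_in_day, delay, ratings...) tuples."""
    recs = []
    for subject, day, bid, delay, vals in rows:
        rec = {
            "pair_id": subject // 10,
            "subject_id": subject,
            "zygosity": "MZ",
            "day": day,
            "beep_in_day": bid,
            "beep_number": (day - 1) * 10 + bid,
            "response_delay_min": delay,
        }
        for i, v in enumerate(vals):
            rec[f"item{i}"] = v
        recs.append(rec)
    return pd.DataFrame(recs)


class TestFilterValidReports:
    def test_cutoff_is_strictly_more_than(self):
        panel = _mini_panel(
            [(11, 1, b, d, (4, 4)) for b, d in [(1, 10.0), (2, 15.0), (3, 16.0), (4, np.nan)]]
        )
        out = filter_valid_reports(panel)
        kept = out["response_delay_min"].tolist()
        assert kept == [10.0, 15.0]  # 16 dropped, missing dropped, 15 exactly kept

    def test_identity_when_all_on_time(self):
        panel = _mini_panel([(11, 1, b, 0.0, (4, 4)) for b in range(1, 6)])
        pd.testing.assert_frame_equal(filter_valid_reports(panel), panel)

    def test_idempotent(self):
        panel, _ = generate_cohort(null_sim_config(p_invalid=0.3, seed=5))
        once = filter_valid_reports(panel)
        pd.testing.assert_frame_equal(filter_valid_reports(once), once)


class TestExcludeSparseSubjects:
    def test_boundary_at_min_valid(self):
        rows = [(11, 1 + b // 10, 1 + b % 10, 0.0, (4, 4)) for b in range(16)]
        rows += [(12, 1 + b // 10, 1 + b % 10, 0.0, (4, 4)) for b in range(17)]
        panel = _mini_panel(rows)
        out = exclude_sparse_subjects(panel, min_valid=17)
        assert set(out["subject_id"]) == {12}

    def test_all_or_nothing_and_idempotent(self):
        panel, _ = generate_cohort(null_sim_config(p_invalid=0.5, seed=8, n_days=5))
        valid = filter_valid_reports(panel)
        out = exclude_sparse_subjects(valid, min_valid=17)
        counts = out.groupby("subject_id").size()
        assert (counts >= 17).all()
        pd.testing.assert_frame_equal(exclude_sparse_subjects(out, 17), out)


class TestScoreCtq:
    def test_direct_arithmetic(self):
        assert score_ctq([1, 2, 3, 4, 5], reverse_keys=()) == 3.0
        assert score_ctq([1] * 10, reverse_keys=()) == 1.0

    def test_reversal_symmetry(self):
        # a reverse-keyed item scored 5 contributes 1
        assert score_ctq([5, 1, 1, 1, 1], reverse_keys=(0,)) == 1.0

    def test_out_of_range_signalled(self):
        with pytest.raises(ValueError):
            score_ctq([0, 3, 3], reverse_keys=())
        with pytest.raises(ValueError):
            score_ctq([3, np.nan, 3], reverse_keys=())


class TestTraumaTertiles:
    def test_distinct_scores_split_evenly(self):
        meta = pd.DataFrame({"subject_id": range(9), "ctq_mean": np.arange(9) / 10 + 1})
        lab = assign_trauma_tertiles(meta)
        assert lab["trauma_tertile"].value_counts().tolist() == [3, 3, 3]

    def test_585_distinct_scores(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {"subject_id": range(585), "ctq_mean": rng.permutation(585) / 100.0 + 1}
        )
        lab = assign_trauma_tertiles(meta)
        assert lab["trauma_tertile"].value_counts().to_dict() == {
            "low": 195,
            "medium": 195,
            "high": 195,
        }

    def test_tie_rule_keeps_value_blocks_together(self):
        meta = pd.DataFrame(
            {"subject_id": range(9), "ctq_mean": [1, 1, 1, 2, 2, 2, 3, 3, 3]}
        )
        lab = assign_trauma_tertiles(meta).merge(meta, on="subject_id")
        assert set(lab.loc[lab["ctq_mean"] == 1, "trauma_tertile"]) == {"low"}
        assert set(lab.loc[lab["ctq_mean"] == 2, "trauma_tertile"]) == {"medium"}
        assert set(lab.loc[lab["ctq_mean"] == 3, "trauma_tertile"]) == {"high"}

    def test_partition(self, small_cohort):
        _, _, meta = small_cohort
        lab = assign_trauma_tertiles(meta)
        assert len(lab) == len(meta)
        assert lab["subject_id"].is_unique
        assert set(lab["trauma_tertile"]) <= {"low", "medium", "high"}

    def test_too_few_distinct_values(self):
        meta = pd.DataFrame({"subject_id": range(6), "ctq_mean": [1, 1, 1, 2, 2, 2]})
        with pytest.raises(ValueError, match="distinct"):
            assign_trauma_tertiles(meta)


class TestGeneticLiability:
    @staticmethod
    def _meta():
        # pair 1 MZ (co-twin scores straddle the cutoff), pair 2 DZ, sib attached
        return pd.DataFrame(
            {
                "subject_id": [11, 12, 21, 22, 23, 31, 32, 41, 42],
                "pair_id": [1, 1, 2, 2, 2, 3, 3, 4, 4],
                "zygosity": ["MZ", "MZ", "DZ", "DZ", "SIB", "MZ", "MZ", "DZ", "DZ"],
                "scl90_mean": [200.0, 50.0, 210.0, 60.0, 100.0, 80.0, 90.0, 70.0, 65.0],
            }
        )

    def test_classes(self):
        lab = assign_genetic_liability(self._meta(), pct=75).set_index("subject_id")[
            "liability_class"
        ]
        assert lab[23] == "excluded"  # sister
        assert lab[12] == "high"  # MZ co-twin (11) above cutoff
        assert lab[22] == "intermediate"  # DZ co-twin (21) above cutoff
        assert lab[11] == "low"  # co-twin (12) below cutoff
        assert lab[31] == "low" and lab[42] == "low"

    def test_partition_of_twins(self, small_cohort):
        _, _, meta = small_cohort
        lab = assign_genetic_liability(meta)
        assert len(lab) == len(meta)
        sibs = meta.loc[meta["zygosity"] == "SIB", "subject_id"]
        assert (lab.set_index("subject_id").loc[sibs, "liability_class"] == "excluded").all()
        twins = lab[~lab["subject_id"].isin(sibs)]
        assert set(twins["liability_class"]) <= {"low", "intermediate", "high"}


class TestLaggedDesign:
    def test_full_schedule_yields_45_rows(self):
        panel, _ = generate_cohort(null_sim_config(n_pairs=2, n_days=5, beeps_per_day=10))
        design = build_lagged_design(panel, "cheerful")
        assert design.groupby("subject_id").size().eq(45).all()

    def test_no_row_crosses_a_day(self):
        panel, _ = generate_cohort(null_sim_config(n_pairs=3, n_days=5, beeps_per_day=10))
        design = build_lagged_design(panel, "down")
        # time column is the beep number of the outcome moment t; its lag
        # source t-1 must be the previous beep of the same day
        day_of_t = (design["beep_number"] - 1) // 10 + 1
        day_of_lag = (design["beep_number"] - 2) // 10 + 1
        assert (day_of_t == day_of_lag).all()
        assert ((design["beep_number"] - 1) % 10 + 1 >= 2).all()

    def test_missing_midday_beep_removes_two_rows(self):
        panel, _ = generate_cohort(null_sim_config(n_pairs=1, n_days=5, beeps_per_day=10))
        sid = panel["subject_id"].iloc[0]
        full = build_lagged_design(panel, "cheerful")
        n_full = (full["subject_id"] == sid).sum()
        drop = (panel["subject_id"] == sid) & (panel["day"] == 2) & (panel["beep_in_day"] == 5)
        design = build_lagged_design(panel[~drop], "cheerful")
        assert (design["subject_id"] == sid).sum() == n_full - 2
        day2 = design[(design["subject_id"] == sid) & ((design["beep_number"] - 1) // 10 == 1)]
        assert len(day2) == 7

    def test_unknown_outcome(self, small_cohort):
        _, panel, _ = small_cohort
        with pytest.raises(KeyError):
            build_lagged_design(panel, "serene")


class TestPersonMeanCenter:
    def test_arithmetic(self):
        design = pd.DataFrame(
            {"subject_id": [1, 1, 1], "lag_x": [2.0, 4.0, 6.0], "outcome_value": [0, 0, 0]}
        )
        out = person_mean_center(design)
        assert out["lag_x"].tolist() == [-2.0, 0.0, 2.0]

    def test_constant_within_subject_becomes_zero(self):
        design = pd.DataFrame(
            {"subject_id": [1, 1, 2, 2], "lag_x": [3.0, 3.0, 7.0, 7.0], "outcome_value": 0.0}
        )
        assert (person_mean_center(design)["lag_x"] == 0).all()

    def test_per_subject_sums_vanish(self, small_cohort):
        _, panel, _ = small_cohort
        design = build_lagged_design(filter_valid_reports(panel), "anxious")
        sums = design.groupby("subject_id")[
            [c for c in design.columns if c.startswith("lag_")]
        ].sum()
        assert np.abs(sums.to_numpy()).max() < 1e-10


class TestFloorScreen:
    def test_constant_subject_is_horizontal(self):
        rows = [(11, 1, b, 0.0, (1, 4 + (b % 2))) for b in range(1, 11)]
        panel = _mini_panel(rows)
        rep = screen_floor_effects(panel, slope_eps=0.05, min_pairs=3)
        sub = rep.slopes[(rep.slopes["subject_id"] == 11) & (rep.slopes["item"] == "item0")]
        assert sub["horizontal"].item()
        assert np.isnan(sub["slope"].item())

    def test_autoregressive_item_not_horizontal(self):
        from conftest import ar_sim_config

        cfg = ar_sim_config(seed=13, n_pairs=30, diag=0.5, cross=())
        panel, _ = generate_cohort(cfg)
        rep = screen_floor_effects(panel, slope_eps=0.05, min_pairs=10)
        assert rep.proportion_horizontal["cheerful"] < 0.1

    def test_proportions_valid_and_min_pairs_respected(self, small_cohort):
        _, panel, _ = small_cohort
        rep = screen_floor_effects(panel, slope_eps=0.05, min_pairs=5)
        assert rep.proportion_horizontal.between(0, 1).all()
        assert (rep.slopes.groupby(["subject_id", "item"]).size() == 1).all()
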