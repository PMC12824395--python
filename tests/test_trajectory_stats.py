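"""Dichotomization, initiation/discontinuation classes, trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medseq.states import AD_MONO, CENSORED, LACK, LITHIUM
from medseq.trajectory_stats import (
    TRAJECTORIES,
    classify_discontinuation,
    classify_initiation,
    classify_person,
    classify_trajectories,
    classify_trajectory,
    dichotomize,
    summarize_trajectories,
)


class TestDichotomize:
    def test_all_lack(self):
        assert dichotomize([LACK] * 12) == [0] * 12

    def test_ad_monotherapy_counts_as_treatment(self):
        assert dichotomize([AD_MONO] + [LACK] * 11) == [1] + [0] * 11

    def test_censoring_ends_evaluable_window(self):
        seq = [LACK] * 4 + [CENSORED] * 8
        assert dichotomize(seq) == [0, 0, 0, 0]


class TestInitiation:
    def test_period_one_is_early(self):
        assert classify_initiation([1] + [0] * 11) == ("early_0_3m", 1)

    def test_period_three_is_delayed_4_12(self):
        assert classify_initiation([0, 0, 1] + [0] * 9) == ("delayed_4_12m", 3)

    def test_period_five_is_delayed_ge12(self):
        assert classify_initiation([0] * 4 + [1] + [0] * 7)[0] == "delayed_ge12m"

    def test_never(self):
        assert classify_initiation([0] * 12) == ("never", None)

    def test_pre_diagnosis_ad_monotherapy_forces_early(self):
        cls, _ = classify_initiation([1] * 12, pre_dx_ad_monotherapy=True)
        assert cls == "early_0_3m"


class TestDiscontinuation:
    def test_gap_two_within_6m(self):
        assert classify_discontinuation([1, 1, 0] + [0] * 9, 1) == "within_6m"

    def test_continuous_treatment_none(self):
        assert classify_discontinuation([1] * 12, 1) == "none"

    def test_first_transition_governs(self):
        # 1 0 1 0 ...: first fall at period 2 (gap 1) despite re-initiation
        assert classify_discontinuation([1, 0, 1, 0] + [0] * 8, 1) == "within_6m"

    @pytest.mark.parametrize(
        "gap,expected",
        [(1, "within_6m"), (2, "within_6m"), (3, "within_1y"), (4, "within_1y"),
         (5, "within_2y"), (8, "within_2y"), (9, "after_2y"), (11, "after_2y")],
    )
    def test_gap_bins(self, gap, expected):
        seq = [1] * gap + [0] * (12 - gap)
        assert classify_discontinuation(seq, 1) == expected

    def test_censored_before_event_is_none(self):
        assert classify_discontinuation([1, 1, 1], 1) == "none"


class TestTrajectory:
    def test_cross_classification(self):
        assert classify_trajectory("early_0_3m", False) == "early_no_disc"
        assert classify_trajectory("early_0_3m", True) == "early_disc"
        assert classify_trajectory("delayed_4_12m", False) == "delayed_no_disc"
        assert classify_trajectory("delayed_ge12m", True) == "delayed_disc"
        assert classify_trajectory("never", False) == "continuous_lack"

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, bits):
        """Every evaluable person lands in exactly one trajectory."""
        states = [LACK if b == 0 else LITHIUM for b in bits]
        rec = classify_person("p", states)
        assert rec.trajectory in TRAJECTORIES
        assert rec.initiated == (rec.trajectory != "continuous_lack")
        if rec.trajectory.startswith("early"):
            assert rec.initiation_class == "early_0_3m"


def _records(spec):
    """spec: list of (group, states, n_copies)."""
    rows, groups = [], {}
    i = 0
    for group, states, n in spec:
        for _ in range(n):
            pid = f"p{i}"
            rows.append({"person_id": pid, **{f"s{k+1}": s for k, s in enumerate(states)}})
            groups[pid] = group
            i += 1
    seqs = pd.DataFrame(rows)
    recs = classify_trajectories(seqs)
    recs["group"] = recs["person_id"].map(groups)
    return recs


def test_summary_counts_and_denominators():
    T, L = LITHIUM, LACK
    recs = _records(
        [
            ("g", [T] * 12, 3),              # early, no disc
            ("g", [T, T, L] + [L] * 9, 2),   # early, disc within 6m
            ("g", [L, T] + [T] * 10, 1),     # delayed 4-12m, no disc
            ("g", [L] * 4 + [T] * 8, 1),     # delayed >=12m (period 5), no disc
            ("g", [L] * 12, 1),              # continuous lack
        ]
    )
    out = summarize_trajectories(recs, recs.set_index("person_id")["group"])

    def cell(section, row):
        r = out[(out["section"] == section) & (out["row"] == row)].iloc[0]
        return r["count"], r["denominator"]

    assert cell("initiation", "yes") == (7, 8)
    assert cell("time_to_initiation", "early_0_3m") == (5, 7)
    # discontinuation denominator: initiators within a year (periods 1-4)
    assert cell("discontinuation", "yes") == (2, 6)
    assert cell("time_to_discontinuation", "within_6m") == (2, 2)
    assert cell("trajectory", "continuous_lack") == (1, 8)
    # partition property: trajectory counts sum to the group size
    traj = out[out["section"] == "trajectory"]
    assert traj["count"].sum() == 8


def test_consistency_early_initiators_split():
    """Early initiators = early trajectories with and without
    discontinuation."""
    T, L = LITHIUM, LACK
    recs = _records(
        [
            ("g", [T] * 12, 4),
            ("g", [T, L] + [L] * 10, 3),
            ("g", [L, T] + [T] * 10, 2),
            ("g", [L] * 12, 1),
        ]
    )
    out = summarize_trajectories(recs, recs.set_index("person_id")["group"])
    early = out[(out["section"] == "time_to_initiation") & (out["row"] == "early_0_3m")]
    t1 = out[(out["section"] == "trajectory") & (out["row"] == "early_no_disc")]
    t2 = out[(out["section"] == "trajectory") & (out["row"] == "early_disc")]
    assert early.iloc[0]["count"] == t1.iloc[0]["count"] + t2.iloc[0]["count"] == 7
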