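"""Stream processing: despiking, merging, budgets, posture-change counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sowpatterns import ethogram as eth
from sowpatterns.errors import InputDataError
from sowpatterns.streams import (
    PostureStream,
    assemble_period_dataset,
    classify_standing_activity,
    count_posture_changes,
    daily_postural_budget,
    daily_standing_budget,
    despike,
    merge_postures,
)

S = PostureStream.from_labels

posture_seqs = st.lists(
    st.sampled_from(eth.POSTURES), min_size=2, max_size=60
).map(lambda labs: S(labs))


# --------------------------------------------------------------------------
# despiking
# --------------------------------------------------------------------------

class TestDespike:
    def test_single_spike_replaced_by_previous_posture(self):
        out = despike(S(["LL", "LL", "ST", "LL", "LL"]))
        assert list(out.posture_labels()) == ["LL", "LL", "LL", "LL", "LL"]

    def test_no_singletons_unchanged_and_idempotent(self):
        s = S(["LL", "LL", "ST", "ST", "SL", "SL"])
        once = despike(s)
        assert list(once.posture_labels()) == list(s.posture_labels())
        assert list(despike(once).posture_labels()) == list(once.posture_labels())

    def test_single_pass_semantics_uses_causal_replacement(self):
        # the SL singleton is replaced by the (preceding) ST, and the final
        # LL pair is long enough to survive
        out = despike(S(["LL", "ST", "ST", "SL", "LL", "LL"]))
        assert list(out.posture_labels()) == ["LL", "ST", "ST", "ST", "LL", "LL"]

    def test_leading_singleton_has_no_previous_observation(self):
        out = despike(S(["ST", "LL", "LL"]))
        assert list(out.posture_labels()) == ["ST", "LL", "LL"]

    def test_chain_of_singletons_collapses_onto_anchor(self):
        out = despike(S(["LL", "LL", "SI", "K", "ST", "LL", "LL"]))
        assert list(out.posture_labels()) == ["LL"] * 7

    def test_replaced_tick_activity_follows_new_posture(self):
        s = S(
            ["ST", "ST", "LL", "ST", "ST"],
            activities=["EAT", "EAT", None, "DRINK", "DRINK"],
        )
        out = despike(s)
        # LL singleton becomes ST and inherits the previous tick's activity
        assert out.tick(2) == ("ST", "EAT")
        s2 = S(["LL", "LL", "ST", "LL", "LL"], activities=[None, None, "EAT", None, None])
        assert despike(s2).tick(2) == ("LL", None)

    def test_empty_stream_rejected(self):
        with pytest.raises(InputDataError):
            despike(S([]))

    @given(posture_seqs)
    def test_output_runs_at_least_two_ticks_except_leading(self, s):
        out = despike(s).posture_labels()
        runs, cur = [], 1
        for a, b in zip(out, out[1:]):
            if a == b:
                cur += 1
            else:
                runs.append(cur)
                cur = 1
        runs.append(cur)
        assert all(r >= 2 for r in runs[1:])

    @given(posture_seqs)
    def test_despiking_never_increases_pcall(self, s):
        assert count_posture_changes(despike(s))[0] <= count_posture_changes(s)[0]


def test_merge_then_despike_can_differ_from_despike_then_merge():
    # two adjacent singletons that merge into one surviving run: the fixed
    # pipeline order (despike first) removes them, the reversed order keeps them
    s = S(["LL", "LL", "SI", "K", "LL", "LL"])
    fixed = merge_postures(despike(s))
    reversed_order = despike(merge_postures(s))
    assert list(fixed.posture_labels()) != list(reversed_order.posture_labels())


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------

class TestMerge:
    def test_identity_map_is_noop(self):
        s = S(["K", "SI", "ST"])
        out = merge_postures(s, {p: p for p in eth.POSTURES})
        assert list(out.posture_labels()) == ["K", "SI", "ST"]

    def test_default_map_pools_sitting_and_kneeling(self):
        out = merge_postures(S(["K", "SI", "ST"]))
        assert list(out.posture_labels()) == ["SI+K", "SI+K", "ST"]

    def test_merged_budget_is_sum_of_constituents(self):
        s = S(["K", "SI", "ST", "LL", "SI", "K", "K", "LL"])
        before = daily_postural_budget(s)
        after = daily_postural_budget(merge_postures(s))
        assert after["SI+K"] == pytest.approx(before["SI"] + before["K"])

    def test_unmapped_label_rejected(self):
        with pytest.raises(InputDataError):
            merge_postures(S(["ST"]), {"LL": "LL"})


# --------------------------------------------------------------------------
# standing activity classification
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "head, expected",
    [
        ((0.0, 0.0), "DRINK"),  # at the trough centre
        ((10.0, 10.0), "OTHER"),  # beyond both radii
        ((0.3, 0.0), "DRINK"),  # within both radii: drinking takes precedence
        ((5.0, 0.1), "EAT"),
    ],
)
def test_head_distance_activity_rule(head, expected):
    lab = classify_standing_activity(
        head, trough_xy=(0, 0), feeder_xy=(5, 0), r_drink=0.5, r_eat=0.5
    )
    assert lab == expected


def test_activity_radii_must_be_positive():
    with pytest.raises(InputDataError):
        classify_standing_activity((0, 0), (0, 0), (1, 1), r_drink=0.0, r_eat=1.0)


# --------------------------------------------------------------------------
# budgets
# --------------------------------------------------------------------------

class TestBudgets:
    def test_constant_day_is_pure_budget(self):
        b = daily_postural_budget(S(["LL"] * 40))
        assert b["LL"] == 1.0 and b.drop("LL").sum() == 0.0

    def test_even_split_counts(self):
        b = daily_postural_budget(S(["ST"] * 20 + ["LL"] * 20))
        assert b["ST"] == 0.5 and b["LL"] == 0.5

    def test_budget_closure(self):
        b = daily_postural_budget(S(["ST", "SI", "K", "SL", "LL", "LLU", "LL"]))
        assert b.sum() == pytest.approx(1.0, abs=1e-12)

    def test_standing_budget_shares(self):
        acts = ["EAT"] * 27 + ["DRINK"] * 21 + ["OTHER"] * 52
        s = S(["ST"] * 100, activities=acts)
        b = daily_standing_budget(s)
        assert (b["EAT"], b["DRINK"], b["OTHER"]) == (0.27, 0.21, 0.52)

    def test_all_eat_standing_budget(self):
        b = daily_standing_budget(S(["ST"] * 5, activities=["EAT"] * 5))
        assert list(b) == [1.0, 0.0, 0.0]

    def test_zero_standing_day_is_missing_not_zero(self):
        assert daily_standing_budget(S(["LL"] * 10)) is None


# --------------------------------------------------------------------------
# posture-change counts
# --------------------------------------------------------------------------

RISK = eth.RISK_CRUSH_TRANSITIONS


def oracle_counts(labels):
    """Independent brute-force scan of all adjacent pairs."""
    pc = pr = ps = 0
    for a, b in zip(labels, labels[1:]):
        if a != b:
            pc += 1
            if (a, b) in RISK:
                pr += 1
            if a == "LLU":
                ps += 1
    return pc, pr, ps


class TestCounts:
    def test_constant_stream_has_no_changes(self):
        assert count_posture_changes(S(["LL"] * 50)) == (0, 0, 0)

    def test_hand_enumerated_example(self):
        # ST->LL, LL->SL, SL->LLU, LLU->ST : 4 changes, of which ST->LL and
        # SL->LLU are crush risks and LLU->ST ends a nursing bout
        assert count_posture_changes(S(["ST", "LL", "LL", "SL", "LLU", "ST"])) == (4, 2, 1)

    @given(posture_seqs)
    def test_matches_brute_force_oracle(self, s):
        assert count_posture_changes(s) == oracle_counts(list(s.posture_labels()))

    @given(posture_seqs)
    def test_count_invariants(self, s):
        pc, pr, ps = count_posture_changes(s)
        assert 0 <= pr <= pc and 0 <= ps <= pc and pr + ps <= 2 * pc


# --------------------------------------------------------------------------
# period assembly
# --------------------------------------------------------------------------

def _traits_frame(sow_days):
    rows = [
        {"sow_id": s, "day": d, "pcall": 0, "pcriskcrush": 0, "pcstopnurse": 0,
         "total_ticks": 17280}
        for s, days in sow_days.items()
        for d in days
    ]
    return pd.DataFrame(rows)


def test_period_completeness_rules():
    traits = _traits_frame(
        {
            "A": range(-3, 8),  # all 11 days
            "B": [d for d in range(-3, 8) if d != -2],  # missing D-2
        }
    )
    for period, expect in (("bf", ["A"]), ("df", ["A", "B"]), ("af", ["A", "B"])):
        ds = assemble_period_dataset(traits, period)
        assert ds.complete_sows == expect


def test_period_day_windows():
    traits = _traits_frame({"A": range(-3, 8)})
    assert tuple(assemble_period_dataset(traits, "bf").days) == (-3, -2, -1)
    assert tuple(assemble_period_dataset(traits, "df").days) == (0,)
    assert tuple(assemble_period_dataset(traits, "af").days) == tuple(range(1, 8))
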