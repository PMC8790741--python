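"""Positional-history classification, CC fractions, and transition flows."""

import numpy as np
import pytest

from sivskit.history import (
    HistoryClass,
    classify_many,
    classify_position_history,
    continuously_circulating_fraction,
    is_ivas_positive,
    transition_flows,
)
from sivskit.labeling import BLOOD, TISSUE_LOCALIZED
from sivskit.trafficking import (
    AnimalSpec,
    CohortConfig,
    TissueSpec,
    simulate_cohort,
)

from conftest import lv, make_schedule, two_state


class TestIvasCall:
    def test_all_positive(self, schedule4):
        assert is_ivas_positive(lv("++++"), schedule4) is True

    def test_oldest_positive_only(self, schedule4):
        assert is_ivas_positive(lv("+---"), schedule4) is False

    def test_single_pulse_schedule(self):
        sched = make_schedule([0.0833])
        assert is_ivas_positive(lv("+"), sched) is True
        assert is_ivas_positive(lv("-"), sched) is False

    def test_masked_ivas_is_indeterminate(self, schedule4):
        assert is_ivas_positive(lv("++++", mask="1110"), schedule4) is None

    def test_schedule_without_ivas_pulse_rejected(self):
        sched = make_schedule([48.0, 24.0])
        with pytest.raises(ValueError):
            is_ivas_positive(lv("++"), sched)


class TestClassify:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ("----", HistoryClass.TISSUE_LOCALIZED),
            ("+---", HistoryClass.RECENT_IMMIGRANT),
            ("-+--", HistoryClass.RECENT_IMMIGRANT),
            ("---+", HistoryClass.IVAS_POS),
            ("+++-", HistoryClass.RECENT_IMMIGRANT),
            ("++++", HistoryClass.IVAS_POS),
        ],
    )
    def test_partition_examples(self, schedule4, calls, expected):
        assert classify_position_history(lv(calls), schedule4) is expected

    def test_all_earlier_masked_is_indeterminate_not_tl(self, schedule4):
        v = lv("----", mask="0001")
        assert (
            classify_position_history(v, schedule4) is HistoryClass.INDETERMINATE
        )

    def test_single_pulse_ivas_negative_indeterminate(self):
        sched = make_schedule([0.0833])
        assert (
            classify_position_history(lv("-"), sched)
            is HistoryClass.INDETERMINATE
        )

    def test_classify_many_matches_scalar(self, schedule4):
        cells = [lv(c) for c in ("----", "+---", "---+", "-++-")]
        assert classify_many(cells, schedule4) == [
            classify_position_history(v, schedule4) for v in cells
        ]

    def test_partition_counts_on_simulated_cohort(self, schedule4):
        cfg = CohortConfig(
            animals=(AnimalSpec("A0", schedule4),),
            subsets=(two_state(0.3, 0.2, name="s"),),
            tissues=(TissueSpec("LN"),),
            cell_counts={"s": {"LN": 5000}},
            seed=21,
        )
        cohort = simulate_cohort(cfg)
        from sivskit.labeling import calls_from_truth, LabelVector

        table = cohort.table[cohort.table["tissue"] == "LN"]
        truth = table[[f"truth_{c}" for c in cohort.channels]].to_numpy(dtype=object)
        calls = calls_from_truth(truth)
        cells = [
            LabelVector(calls=tuple(c), mask=(True,) * 4) for c in calls
        ]
        classes = classify_many(cells, schedule4)
        n = {
            cls: sum(1 for c in classes if c is cls)
            for cls in HistoryClass
        }
        # IVas+ + RI + TL partition every tissue cell with a valid IVas pulse
        assert (
            n[HistoryClass.IVAS_POS]
            + n[HistoryClass.RECENT_IMMIGRANT]
            + n[HistoryClass.TISSUE_LOCALIZED]
            == len(cells)
        )
        assert n[HistoryClass.INDETERMINATE] == 0

    def test_tl_ground_truth_never_in_blood_at_pulses(self, schedule4):
        # with labeling restricted to blood in a non-sinusoidal tissue, a TL
        # call is exact: the trajectory shows no blood residence at any pulse
        cfg = CohortConfig(
            animals=(AnimalSpec("A0", schedule4),),
            subsets=(two_state(0.4, 0.3, name="s"),),
            tissues=(TissueSpec("LN", sinusoidal=False),),
            cell_counts={"s": {"LN": 3000}},
            seed=8,
        )
        cohort = simulate_cohort(cfg, collect_trajectories=True)
        from sivskit.labeling import calls_from_truth, LabelVector

        table = cohort.table[cohort.table["tissue"] == "LN"]
        truth = table[[f"truth_{c}" for c in cohort.channels]].to_numpy(dtype=object)
        calls = calls_from_truth(truth)
        cells = [LabelVector(calls=tuple(c), mask=(True,) * 4) for c in calls]
        classes = classify_many(cells, schedule4)
        tl_ids = [
            cid
            for cid, cls in zip(table["cell_id"], classes)
            if cls is HistoryClass.TISSUE_LOCALIZED
        ]
        assert tl_ids, "expected some tissue-localized cells"
        for cid in tl_ids:
            traj = cohort.trajectories[cid]
            for t in schedule4.times:
                assert traj.compartment_at(t) != BLOOD


class TestContinuouslyCirculating:
    def test_seven_of_ten(self, schedule2):
        cells = [lv("++")] * 7 + [lv("-+"), lv("+-"), lv("--")]
        assert continuously_circulating_fraction(cells, schedule2, 6.0) == 0.7

    def test_short_lookback_ignores_old_pulses(self, schedule4):
        cells = [lv("--++")] * 4 + [lv("++++")] * 6
        assert continuously_circulating_fraction(cells, schedule4, 6.0) == 1.0
        assert continuously_circulating_fraction(cells, schedule4, 48.0) == 0.6

    def test_monotone_in_lookback(self, schedule4, rng):
        cells = [
            lv("".join("+" if rng.random() < 0.7 else "-" for _ in range(4)))
            for _ in range(200)
        ]
        fracs = [
            continuously_circulating_fraction(cells, schedule4, lb)
            for lb in (0.1, 6.0, 24.0, 48.0)
        ]
        assert all(f1 >= f2 for f1, f2 in zip(fracs, fracs[1:]))

    def test_masked_pulse_window_equals_reduced_schedule(self):
        # animal with the 48 h pulse uninterpretable: CC over 24 h equals
        # the same computation on the three-pulse schedule
        full = make_schedule([48.0, 24.0, 6.0, 0.0833], invalid=(0,))
        reduced = make_schedule([24.0, 6.0, 0.0833])
        patterns = ["++++", "-+++", "+-++", "++-+", "-+-+", "++--"]
        cells_full = [lv(p, mask="0111") for p in patterns]
        cells_reduced = [lv(p[1:]) for p in patterns]
        assert continuously_circulating_fraction(
            cells_full, full, 24.0
        ) == continuously_circulating_fraction(cells_reduced, reduced, 24.0)

    def test_empty_eligible_set_raises(self, schedule2):
        with pytest.raises(ValueError):
            continuously_circulating_fraction(
                [lv("++", mask="01")], schedule2, 6.0
            )


class TestTransitionFlows:
    def test_counts_example(self, schedule2):
        cells = [lv("++")] * 5 + [lv("+-")] * 3 + [lv("-+")] * 2
        flow = transition_flows(cells, schedule2)
        assert len(flow.pairs) == 1
        p = flow.pairs[0]
        assert (p.pos_pos, p.pos_neg, p.neg_pos, p.neg_neg) == (5, 3, 2, 0)
        assert p.denominator == 10

    def test_all_positive_only_pp(self, schedule4):
        flow = transition_flows([lv("++++")] * 7, schedule4)
        assert all(
            (p.pos_pos, p.pos_neg, p.neg_pos, p.neg_neg) == (7, 0, 0, 0)
            for p in flow.pairs
        )

    def test_single_pulse_yields_empty_flows(self):
        sched = make_schedule([0.0833])
        assert transition_flows([lv("+")] * 5, sched).pairs == ()

    def test_flow_conservation(self, schedule4, rng):
        cells = [
            lv("".join("+" if rng.random() < 0.6 else "-" for _ in range(4)))
            for _ in range(300)
        ]
        flow = transition_flows(cells, schedule4)
        calls = np.array([v.calls for v in cells])
        for p in flow.pairs:
            # outflow from the positive state at pulse i equals the number
            # of cells positive there
            assert p.pos_pos + p.pos_neg == int(calls[:, p.from_index].sum())
            assert p.denominator == len(cells)
        # marginals chain between consecutive pairs
        for p1, p2 in zip(flow.pairs, flow.pairs[1:]):
            assert p1.pos_pos + p1.neg_pos == p2.pos_pos + p2.pos_neg

    def test_masked_pulse_is_bridged(self):
        sched = make_schedule([48.0, 24.0, 6.0, 0.0833], invalid=(0,))
        cells = [lv("-+++", mask="0111")] * 4
        flow = transition_flows(cells, sched)
        assert [(p.from_index, p.to_index) for p in flow.pairs] == [(1, 2), (2, 3)]

    def test_fast_exchange_has_more_cross_flows(self, schedule4):
        # forced by rate ordering: a fast-exchanging subset transitions
        # between label states more than a vascular-retained one
        def cross_flow_count(exit_rate):
            cfg = CohortConfig(
                animals=(AnimalSpec("A0", schedule4),),
                subsets=(two_state(exit_rate, 0.3, name="s"),),
                tissues=(TissueSpec("LN"),),
                cell_counts={"s": {"LN": 4000}},
                seed=13,
            )
            cohort = simulate_cohort(cfg)
            from sivskit.labeling import calls_from_truth, LabelVector

            blood = cohort.table[cohort.table["tissue"] == "blood"]
            truth = blood[[f"truth_{c}" for c in cohort.channels]].to_numpy(dtype=object)
            cells = [
                LabelVector(calls=tuple(c), mask=(True,) * 4)
                for c in calls_from_truth(truth)
            ]
            flow = transition_flows(cells, schedule4)
            total = sum(p.pos_neg + p.neg_pos for p in flow.pairs)
            return total / len(cells)

        assert cross_flow_count(0.5) > cross_flow_count(0.02)

    def test_sankey_export_consistency(self, schedule2):
        cells = [lv("++")] * 5 + [lv("+-")] * 3 + [lv("-+")] * 2
        export = transition_flows(cells, schedule2).to_sankey()
        assert sum(l["count"] for l in export["links"]) == 10
        for link in export["links"]:
            assert link["fraction"] == link["count"] / 10
        node_ids = {n["id"] for n in export["nodes"]}
        for link in export["links"]:
            assert link["source"] in node_ids and link["target"] in node_ids
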