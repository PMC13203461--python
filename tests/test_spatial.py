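import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gazeseq as gz

import oracles
from conftest import make_records

finite_pts = st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))


class TestEuclidean:
    def test_hand_values(self):
        assert gz.euclidean((0, 0), (3, 4)) == 5.0
        assert gz.euclidean((2, 7), (2, 7)) == 0.0
        assert gz.euclidean((1, 1), (4, 5)) == 5.0

    @settings(deadline=None, derandomize=True)
    @given(a=finite_pts, b=finite_pts, c=finite_pts)
    def test_metric_axioms(self, a, b, c):
        dab, dba = gz.euclidean(a, b), gz.euclidean(b, a)
        assert dab >= 0 and dab == dba
        assert gz.euclidean(a, c) <= dab + gz.euclidean(b, c) + 1e-9
        assert dab == pytest.approx(oracles.euclidean(a, b), abs=1e-10)


class TestPathLength:
    def test_hand_values(self):
        assert gz.path_length([(0, 0), (1, 0), (3, 0)]) == 3.0
        assert gz.path_length([(5, 5)]) == 0.0
        assert gz.path_length([(0, 0), (3, 4), (3, 4)]) == 5.0

    @settings(deadline=None, derandomize=True)
    @given(pts=st.lists(finite_pts, min_size=1, max_size=10))
    def test_bounded_below_by_endpoint_distance_and_matches_oracle(self, pts):
        pl = gz.path_length(pts)
        assert pl >= gz.euclidean(pts[0], pts[-1]) - 1e-9
        assert pl == pytest.approx(oracles.path_length(pts), abs=1e-10)


class TestAnchorTransitions:
    def _trial(self, pid, trial, anchor_xy, target_xy, condition):
        """One trial with a single anchor fixation and a single target fixation."""
        base = trial * 10_000.0
        anchor_event = "context" if condition == "pre_context" else "response"
        rows = []
        if condition == "pre_context":
            rows.append((pid, "I1", trial, anchor_event, base, 200.0, *anchor_xy, True))
            rows.append((pid, "I1", trial, "target", base + 500, 200.0, *target_xy, True))
        else:
            rows.append((pid, "I1", trial, "target", base, 200.0, *target_xy, True))
            rows.append((pid, "I1", trial, anchor_event, base + 4000, 200.0, *anchor_xy, True))
        return rows

    def test_distance_and_landing_zone(self, layout):
        cx, cy = layout["CFZ"].center
        rows = self._trial("P1", 1, (cx, cy), (cx + 3, cy + 4), "pre_context")
        table, skipped = gz.anchor_transitions(make_records(rows), layout, "pre_context")
        assert len(table) == 1
        assert table.loc[0, "distance_px"] == 5.0
        assert table.loc[0, "landing_zone"] == "CFZ"
        assert skipped == {"no_anchor": 0, "no_target": 0}

    def test_post_context_uses_previous_trial_response(self, layout):
        cx, cy = layout["CFZ"].center
        rows = self._trial("P1", 1, (100.0, 100.0), (cx, cy), "post_context") \
             + self._trial("P1", 2, (500.0, 500.0), (103.0, 104.0), "post_context")
        table, skipped = gz.anchor_transitions(make_records(rows), layout, "post_context")
        # trial 1 has no preceding response screen -> skipped
        assert skipped["no_anchor"] == 1
        assert len(table) == 1
        assert table.loc[0, "trial"] == 2
        # anchor is trial 1's response fixation at (100, 100)
        assert table.loc[0, "distance_px"] == 5.0

    def test_trial_without_anchor_fixations_skipped(self, layout):
        cx, cy = layout["CFZ"].center
        rows = [("P1", "I1", 1, "target", 0.0, 200.0, cx, cy, True)]
        table, skipped = gz.anchor_transitions(make_records(rows), layout, "pre_context")
        assert len(table) == 0 and skipped["no_anchor"] == 1

    def test_unknown_condition_rejected(self, layout):
        with pytest.raises(ValueError):
            gz.anchor_transitions(make_records([]), layout, "mid_context")


class TestStabilityTable:
    def _zone_visit(self, layout, durations, xs, pid="P1", trial=1):
        z = layout["CFZ"]
        cy = z.center[1]
        return [(pid, "I1", trial, "target", i * 300.0, d, x, cy, True)
                for i, (d, x) in enumerate(zip(durations, xs))]

    def test_single_visit_arithmetic(self, layout):
        x0 = layout["CFZ"].x_min + 10
        rows = self._zone_visit(layout, (200.0, 300.0, 500.0), (x0, x0 + 50, x0 + 100))
        table = gz.stability_table(make_records(rows), layout)
        assert len(table) == 1
        r = table.iloc[0]
        assert r.total_duration_ms == 1000.0
        assert r.path_length_px == 100.0
        assert r.stability == 10.0

    def test_duration_scaling_law(self, layout):
        x0 = layout["CFZ"].x_min + 10
        rows1 = self._zone_visit(layout, (200.0, 300.0), (x0, x0 + 40))
        rows2 = self._zone_visit(layout, (400.0, 600.0), (x0, x0 + 40))
        s1 = gz.stability_table(make_records(rows1), layout).iloc[0].stability
        s2 = gz.stability_table(make_records(rows2), layout).iloc[0].stability
        assert s2 == pytest.approx(2 * s1)

    def test_single_fixation_zone_excluded_and_logged(self, layout, caplog):
        z = layout["UFZ"]
        x0 = layout["CFZ"].x_min + 10
        rows = self._zone_visit(layout, (200.0, 300.0), (x0, x0 + 40))
        rows.append(("P1", "I1", 1, "target", 900.0, 250.0, *z.center, True))
        with caplog.at_level("INFO", logger="gazeseq.spatial"):
            table = gz.stability_table(make_records(rows), layout)
        assert set(table.zone) == {"CFZ"}
        assert any("zero-path" in r.message for r in caplog.records)

    def test_cross_zone_pairs_count_for_neither_zone(self, layout):
        cz, lz = layout["CFZ"], layout["LFZ"]
        x = cz.center[0]
        rows = [("P1", "I1", 1, "target", 0.0, 200.0, x, cz.y_min + 10, True),
                ("P1", "I1", 1, "target", 300.0, 200.0, x, cz.y_min + 60, True),
                ("P1", "I1", 1, "target", 600.0, 200.0, x, lz.y_min + 10, True),
                ("P1", "I1", 1, "target", 900.0, 200.0, x, lz.y_min + 40, True)]
        table = gz.stability_table(make_records(rows), layout)
        by_zone = table.set_index("zone")
        assert by_zone.loc["CFZ", "path_length_px"] == 50.0
        assert by_zone.loc["LFZ", "path_length_px"] == 30.0

    def test_event_level_grain(self, layout):
        x0 = layout["CFZ"].x_min + 10
        rows = self._zone_visit(layout, (200.0, 300.0), (x0, x0 + 40), trial=1) \
             + self._zone_visit(layout, (200.0, 300.0), (x0, x0 + 40), trial=2)
        table = gz.stability_table(make_records(rows), layout,
                                   level="participant_aoi_event",
                                   condition="pre_context")
        assert len(table) == 2
        assert set(table.trial) == {1, 2}
        assert (table.condition == "pre_context").all()


class TestKruskalWallis:
    def test_matches_bruteforce_on_hand_groups(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = gz.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(
            oracles.kruskal_h(list(groups.values())), abs=1e-10)

    def test_identical_groups_near_zero(self):
        res = gz.kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.effect_size == pytest.approx(0.0, abs=1e-9)

    def test_epsilon_squared_convention(self):
        """epsilon^2 = H / (n - 1): 11.06 at n = 149 gives 0.075."""
        assert 11.06 / (149 - 1) == pytest.approx(0.075, abs=5e-4)
        groups = {"a": list(range(50)), "b": list(range(25, 75)),
                  "c": list(range(49))}
        res = gz.kruskal_wallis(groups)
        assert res.effect_size == pytest.approx(res.statistic / 148, abs=1e-12)

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            gz.kruskal_wallis({"a": [1, 2, 3], "b": []})


class TestPairwiseWilcoxonHolm:
    def test_identical_groups_adjusted_to_one(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
        for r in gz.pairwise_wilcoxon_holm(g):
            assert r.p_adjusted == pytest.approx(1.0)

    def test_holm_rule_hand_application(self):
        assert oracles.holm([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])
        from statsmodels.stats.multitest import multipletests
        assert multipletests([0.01, 0.02, 0.04], method="holm")[1] == pytest.approx(
            [0.03, 0.04, 0.04])

    def test_adjusted_ge_raw_and_monotone(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(loc, 1, 12) for k, loc in
             zip("abc", (0.0, 0.8, 2.0))}
        results = gz.pairwise_wilcoxon_holm(g)
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-15
            assert abs(r.effect_size) <= 1.0
        ordered = sorted(results, key=lambda r: r.p_raw)
        adj = [r.p_adjusted for r in ordered]
        assert adj == sorted(adj)

    def test_adjustment_matches_oracle(self):
        rng = np.random.default_rng(3)
        g = {k: rng.normal(loc, 1, 10) for k, loc in zip("abc", (0, 0.5, 1.2))}
        results = gz.pairwise_wilcoxon_holm(g)
        raw = [r.p_raw for r in results]
        expect = oracles.holm(raw)
        assert [r.p_adjusted for r in results] == pytest.approx(expect, abs=1e-12)
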