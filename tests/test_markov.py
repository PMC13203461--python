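import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gazeseq as gz
from gazeseq.markov import EstimationError, signed_rank_v

import oracles

U, C, L = "UFZ", "CFZ", "LFZ"

label_seqs = st.lists(
    st.lists(st.sampled_from([U, C, L]), min_size=1, max_size=12),
    min_size=1, max_size=8,
)


class TestEstimateTransitions:
    def test_first_order_hand_count(self):
        m = gz.estimate_transitions([[U, C, C, L]], 1)
        assert m.n_transitions == 3
        assert m.prob(U, C) == 1.0
        assert m.prob(C, C) == 0.5
        assert m.prob(C, L) == 0.5
        assert not m.observed((L,))
        assert np.isnan(m.probabilities[2]).all()

    def test_degenerate_sequence(self):
        m = gz.estimate_transitions([[C, C, C, C]], 1)
        assert m.prob(C, C) == 1.0
        assert not m.observed((U,)) and not m.observed((L,))

    def test_second_order_hand_count(self):
        m = gz.estimate_transitions([[U, C, L, C]], 2)
        assert m.n_transitions == 2
        assert m.prob((U, C), L) == 1.0
        assert m.prob((C, L), C) == 1.0

    def test_no_usable_sequence_raises(self):
        with pytest.raises(EstimationError):
            gz.estimate_transitions([[C], [U]], 1)
        with pytest.raises(EstimationError):
            gz.estimate_transitions([[C, U]], 2)

    @settings(deadline=None, derandomize=True)
    @given(seqs=label_seqs, order=st.sampled_from([1, 2]))
    def test_counts_conserved_and_rows_stochastic(self, seqs, order):
        try:
            m = gz.estimate_transitions(seqs, order)
        except EstimationError:
            assert all(len(s) <= order for s in seqs)
            return
        assert m.n_transitions == sum(max(len(s) - order, 0) for s in seqs)
        assert m.counts.sum() == m.n_transitions
        rows = m.probabilities.reshape(-1, 3)
        observed = ~np.isnan(rows).any(axis=1)
        assert np.allclose(rows[observed].sum(axis=1), 1.0, atol=1e-12)


class TestEntropy:
    def test_uniform_row_is_maximal(self):
        h_bits, h_norm = gz.row_entropy([1 / 3, 1 / 3, 1 / 3])
        assert h_norm == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_row_is_zero(self):
        assert gz.row_entropy([1, 0, 0]) == (0.0, 0.0)

    def test_two_point_row_closed_form(self):
        h_bits, h_norm = gz.row_entropy([0.5, 0.5, 0])
        assert h_bits == pytest.approx(1.0, abs=1e-12)
        assert h_norm == pytest.approx(1 / np.log2(3), abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            gz.row_entropy([-0.1, 0.6, 0.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 1.0), min_size=3, max_size=3))
    def test_norm_entropy_bounds(self, raw):
        p = np.array(raw) / sum(raw)
        _, h_norm = gz.row_entropy(p)
        assert -1e-12 <= h_norm <= 1 + 1e-12

    def test_global_uniform_model(self):
        m = gz.estimate_transitions(
            [[U, U, C, L], [C, U, L, U], [L, L, U, C], [U, L, C, C],
             [C, C, U, U], [L, C, L, L]], 1)
        # not uniform, but weights must sum to 1 and mix per-context values
        es = gz.global_entropy(m)
        w = sum(v[2] for v in es.per_context.values())
        assert w == pytest.approx(1.0, abs=1e-12)
        mix = sum(v[0] * v[2] for v in es.per_context.values())
        assert es.global_h_bits == pytest.approx(mix, abs=1e-12)

    def test_single_observed_context_weight_one(self):
        m = gz.estimate_transitions([[C, C, C, L]], 1)
        es = gz.global_entropy(m)
        assert list(es.per_context) == [(C,)]
        assert es.global_h_bits == pytest.approx(es.per_context[(C,)][0])
        assert set(es.unobserved) == {(U,), (L,)}

    def test_printed_normalization_arithmetic(self):
        assert gz.normalized_from_bits(np.log2(3)) == pytest.approx(1.0)
        h_bits, h_norm = gz.row_entropy([0.25, 0.25, 0.5])
        assert h_norm == pytest.approx(h_bits / np.log2(3), abs=1e-15)


class TestParticipantEntropies:
    def _seq(self, pid, labels):
        pts = [(0.0, 0.0, 100.0)] * len(labels)
        return gz.AOISequence(pid, "I1", 1, "target", labels, pts)

    def test_constant_scanpath_has_zero_entropy(self):
        h = gz.participant_entropies([self._seq("P1", [C] * 20)], 1)
        assert h["P1"] == 0.0

    def test_short_sequence_participant_excluded_and_logged(self, caplog):
        seqs = [self._seq("P1", [C, U, C, L, C]), self._seq("P2", [C])]
        with caplog.at_level("INFO", logger="gazeseq.markov"):
            h = gz.participant_entropies(seqs, 1)
        assert list(h.index) == ["P1"]
        assert any("P2" in r.message for r in caplog.records)

    def test_no_usable_participant_raises(self):
        with pytest.raises(EstimationError):
            gz.participant_entropies([self._seq("P1", [C])], 1)

    def test_cohort_recovers_fixture_entropy(self):
        """Mean participant H1 approaches the fixture's analytic global entropy."""
        matrix = gz.build_fixture_matrix(1)
        pi = gz.stationary_distribution(matrix.probabilities)
        analytic_bits = sum(
            pi[i] * gz.row_entropy(matrix.probabilities[i])[0] for i in range(3)
        )
        analytic = analytic_bits / np.log2(3)
        rng = np.random.default_rng(123)
        seqs = [
            self._seq(f"P{p:02d}", gz.sample_markov_sequence(matrix, 2001, rng))
            for p in range(10)
        ]
        h = gz.participant_entropies(seqs, 1)
        assert h.mean() == pytest.approx(analytic, abs=0.05)


class TestCompareOrders:
    def _series(self, values, prefix="P"):
        return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])

    def test_all_zero_differences_degenerate(self):
        h = self._series([0.3, 0.4, 0.5, 0.6, 0.7])
        res = gz.compare_orders(h, h, n_boot=200, seed=0)
        assert res.median_diff == 0 and (res.ci_low, res.ci_high) == (0, 0)
        assert res.wilcoxon_v == 0 and res.p_value == 1.0

    def test_constant_positive_difference(self):
        h1 = self._series([0.31, 0.41, 0.51, 0.61, 0.71])
        res = gz.compare_orders(h1, h1 - 0.01, n_boot=200, seed=0)
        assert res.median_diff == pytest.approx(0.01)
        assert res.ci_low == pytest.approx(0.01) and res.ci_high == pytest.approx(0.01)
        assert res.wilcoxon_v == 15  # all 5 ranks positive

    def test_v_matches_enumeration_oracle(self):
        d = [1, 2, 3, -1, 4, 5, 2]
        h1 = self._series([float(x) for x in d])
        res = gz.compare_orders(h1, h1 - h1 + 0.0, n_boot=100, seed=0)
        v_oracle, _ = oracles.signed_rank_exact_p(d)
        assert res.wilcoxon_v == pytest.approx(v_oracle, abs=1e-10)
        assert signed_rank_v(np.array(d, float)) == pytest.approx(v_oracle, abs=1e-10)

    def test_exact_p_matches_enumeration_when_tie_free(self):
        d = [0.11, -0.07, 0.23, 0.05, -0.02, 0.17, 0.31, 0.09]
        v_oracle, p_oracle = oracles.signed_rank_exact_p(d)
        h1 = self._series(d)
        res = gz.compare_orders(h1, h1 * 0.0, n_boot=100, seed=0)
        assert res.wilcoxon_v == pytest.approx(v_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_participant_order_invariance_and_seed_determinism(self):
        rng = np.random.default_rng(5)
        h1 = self._series(rng.uniform(0.2, 0.6, 12))
        h2 = h1 - rng.uniform(-0.02, 0.05, 12)
        a = gz.compare_orders(h1, h2, n_boot=500, seed=9)
        b = gz.compare_orders(h1.iloc[::-1], h2.iloc[::-1], n_boot=500, seed=9)
        assert (a.median_diff, a.ci_low, a.ci_high, a.wilcoxon_v, a.p_value) == (
            b.median_diff, b.ci_low, b.ci_high, b.wilcoxon_v, b.p_value)
        assert a.ci_low <= a.median_diff <= a.ci_high

    def test_too_few_pairs_rejected(self):
        h = self._series([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            gz.compare_orders(h, h)
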