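"""Transition counting, MLE normalization, stage aggregation, matrix I/O."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ethochain import (
    BehaviorState,
    Ethogram,
    EventSequence,
    Stage,
    TransitionCounts,
    aggregate_stages,
    count_transitions,
    estimate_matrix,
    next_behavior_range,
    read_matrix_tsv,
    sequence_log_likelihood,
    write_matrix_tsv,
)
from ethochain.transitions import TransitionMatrix, write_stage_tsv


def seq(eth, *names):
    return EventSequence("s", [eth.index_of(n) for n in names])


class TestCountTransitions:
    def test_hand_counted_chain(self, eth):
        s = seq(eth, "parade", "demonstration", "attack", "chase", "retreat", "parade")
        counts = count_transitions([s], eth).counts
        expected_pairs = [
            ("parade", "demonstration"),
            ("demonstration", "attack"),
            ("attack", "chase"),
            ("chase", "retreat"),
            ("retreat", "parade"),
        ]
        assert counts.sum() == 5
        for a, b in expected_pairs:
            assert counts[eth.index_of(a), eth.index_of(b)] == 1

    def test_single_state_sequence_contributes_nothing(self, eth):
        counts = count_transitions([seq(eth, "fight")], eth).counts
        assert counts.sum() == 0

    def test_additivity_over_duplicate_sequences(self, eth):
        s = seq(eth, "parade", "demonstration", "attack")
        once = count_transitions([s], eth).counts
        twice = count_transitions([s, s], eth).counts
        assert (twice == 2 * once).all()

    def test_empty_sequence_list_gives_zero_matrix(self, eth):
        assert count_transitions([], eth).counts.sum() == 0


class TestEstimateMatrix:
    def test_direct_normalization(self):
        counts = TransitionCounts(np.array([[0, 3], [1, 0]]), ("a", "b"))
        m = estimate_matrix(counts)
        assert np.allclose(m.probs, [[0, 1], [1, 0]])

    def test_pseudocount_only_on_allowed_cells(self):
        counts = TransitionCounts(np.zeros((2, 2), dtype=int), ("a", "b"))
        m = estimate_matrix(counts, pseudocount=1.0, allow_self=False)
        assert np.allclose(m.probs, [[0, 1], [1, 0]])

    def test_zero_support_row_is_undefined(self):
        counts = TransitionCounts(np.array([[0, 2], [0, 0]]), ("a", "b"))
        m = estimate_matrix(counts)
        assert m.defined.tolist() == [True, False]
        assert np.isnan(m.probs[1]).all()

    def test_negative_pseudocount_rejected(self):
        counts = TransitionCounts(np.zeros((2, 2), dtype=int), ("a", "b"))
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_matrix(counts, pseudocount=-0.1)

    def test_self_transitions_kept_when_observed(self):
        counts = TransitionCounts(np.array([[2, 2], [0, 4]]), ("a", "b"))
        m = estimate_matrix(counts)
        assert np.allclose(m.probs, [[0.5, 0.5], [0.0, 1.0]])

    @given(
        c=arrays(np.int64, (4, 4), elements=st.integers(0, 50)),
    )
    def test_rows_with_support_are_stochastic(self, c):
        np.fill_diagonal(c, 0)
        m = estimate_matrix(TransitionCounts(c, ("a", "b", "c", "d")))
        sums = m.probs[m.defined].sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-9)

    def test_mle_maximizes_training_log_likelihood(self, eth):
        """Perturbing any cell of the MLE and renormalizing never improves
        the training log-likelihood."""
        rng = np.random.default_rng(7)
        seqs = [
            EventSequence(f"s{k}", rng.integers(0, 9, size=40).tolist())
            for k in range(4)
        ]
        mle = estimate_matrix(count_transitions(seqs, eth))
        base = sum(sequence_log_likelihood(mle, s) for s in seqs)
        eps = 1e-3
        for i in range(9):
            if not mle.defined[i]:
                continue
            for j in range(9):
                if mle.probs[i, j] in (0.0, 1.0):
                    continue
                for sign in (+eps, -eps):
                    p = mle.probs.copy()
                    p[i, j] += sign
                    p[i] = np.clip(p[i], 0, None)
                    p[i] /= p[i].sum()
                    alt = TransitionMatrix(p, mle.states)
                    perturbed = sum(sequence_log_likelihood(alt, s) for s in seqs)
                    assert perturbed <= base + 1e-9


class TestPackagedVannameiMatrix:
    def test_named_cells_match_printed_table(self, matrix):
        assert matrix.prob("fight", "retreat") == pytest.approx(0.6718, abs=1e-12)
        assert matrix.prob("parade", "demonstration") == pytest.approx(1.0, abs=1e-12)
        assert matrix.prob("impact", "retreat") == pytest.approx(0.7601, abs=1e-12)

    def test_all_nine_rows_defined_and_stochastic(self, matrix):
        assert matrix.all_defined
        assert np.allclose(matrix.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_rendered_percent_rows_total_exactly_100(self, matrix):
        percents = np.round(matrix.probs * 100.0, 2)
        assert np.all(percents.sum(axis=1) == 100.0)

    def test_empty_cells_are_exact_zeros_and_diagonal_empty(self, matrix):
        assert int((matrix.probs > 0).sum()) == 20
        assert np.all(np.diag(matrix.probs) == 0.0)


class TestAggregateStages:
    def test_feint_row_matches_printed_stage_table(self, matrix, eth):
        sm = aggregate_stages(matrix, eth)
        assert sm.prob("feint", "contact") == pytest.approx(0.4012, abs=1e-4)
        assert sm.prob("feint", "withdrawal") == pytest.approx(0.5988, abs=1e-4)

    def test_temporary_retreat_row(self, matrix, eth):
        sm = aggregate_stages(matrix, eth)
        assert sm.prob("temporary retreat", "encounter") == pytest.approx(0.4547, abs=1e-4)
        assert sm.prob("temporary retreat", "contact") == pytest.approx(0.5453, abs=1e-4)

    def test_identity_aggregation_with_singleton_stages(self, matrix, eth):
        singleton = Ethogram(
            eth.states,
            tuple(Stage(s.name, (s.name,)) for s in eth.states),
            name="singleton",
        )
        sm = aggregate_stages(matrix, singleton)
        assert np.allclose(sm.probs, matrix.probs)

    @given(
        c=arrays(np.int64, (4, 4), elements=st.integers(0, 30)),
    )
    def test_aggregation_commutes_with_normalization(self, c):
        """Normalize-then-aggregate equals aggregate-counts-then-normalize."""
        np.fill_diagonal(c, 0)
        states = (
            BehaviorState("a", "A", 0),
            BehaviorState("b", "B", 1),
            BehaviorState("c", "C", 2),
            BehaviorState("d", "D", 3),
        )
        eth4 = Ethogram(states, (Stage("s1", ("a", "c")), Stage("s2", ("b", "d"))))
        m = estimate_matrix(TransitionCounts(c, eth4.state_names))
        via_probs = aggregate_stages(m, eth4).probs
        stage_counts = np.stack(
            [c[:, [0, 2]].sum(axis=1), c[:, [1, 3]].sum(axis=1)], axis=1
        ).astype(float)
        totals = c.sum(axis=1)
        via_counts = np.full_like(stage_counts, np.nan)
        via_counts[totals > 0] = stage_counts[totals > 0] / totals[totals > 0, None]
        defined = totals > 0
        assert np.allclose(via_probs[defined], via_counts[defined], atol=1e-12)
        assert np.isnan(via_probs[~defined]).all()

    def test_state_mismatch_rejected(self, matrix, tiny_eth):
        with pytest.raises(ValueError, match="do not match"):
            aggregate_stages(matrix, tiny_eth)


class TestNextBehaviorRange:
    def test_retreat_range_over_contact_behaviors(self, matrix):
        lo, hi = next_behavior_range(matrix, "retreat", ["fight", "chase", "impact", "feint"])
        assert (lo, hi) == pytest.approx((0.3568, 0.7601), abs=1e-12)

    def test_singleton_source(self, matrix):
        lo, hi = next_behavior_range(matrix, "retreat", ["fight"])
        assert lo == hi == pytest.approx(0.6718)

    def test_unreachable_target_gives_zero_zero(self, matrix):
        assert next_behavior_range(matrix, "attack", ["parade", "retreat"]) == (0.0, 0.0)

    def test_undefined_source_row_rejected(self):
        counts = TransitionCounts(np.array([[0, 2], [0, 0]]), ("a", "b"))
        m = estimate_matrix(counts)
        with pytest.raises(ValueError, match="undefined"):
            next_behavior_range(m, "a", ["b"])

    def test_empty_sources_rejected(self, matrix):
        with pytest.raises(ValueError, match="nonempty"):
            next_behavior_range(matrix, "retreat", [])


class TestMatrixIO:
    def test_proportion_round_trip(self, matrix):
        buf = io.StringIO()
        write_matrix_tsv(matrix, buf)
        buf.seek(0)
        again = read_matrix_tsv(buf, delimiter="\t")
        assert again.states == matrix.states
        assert np.allclose(again.probs, matrix.probs, atol=1e-12)

    def test_table_style_percent_round_trip(self, matrix):
        buf = io.StringIO()
        write_matrix_tsv(matrix, buf, table_style=True)
        text = buf.getvalue()
        assert "67.18" in text and "100.00" in text
        again = read_matrix_tsv(io.StringIO(text), percent=True, delimiter="\t")
        assert np.allclose(again.probs, matrix.probs, atol=1e-9)

    def test_stage_tsv_mirrors_table_layout(self, matrix, eth):
        buf = io.StringIO()
        write_stage_tsv(aggregate_stages(matrix, eth), buf, percent=True)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "behavior\tencounter\tcontact\twithdrawal"
        assert "temporary retreat\t45.47\t54.53\t0.0" in buf.getvalue()
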