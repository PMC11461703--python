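import numpy as np
import pytest

from gazentropy.entropy import (
    TransitionModel,
    aggregate_condition_matrix,
    analytic_entropies,
    compute_gte,
    compute_sge,
    estimate_model,
    normalize_entropy,
    stationary_distribution,
    transition_counts,
)
from gazentropy.exceptions import InsufficientDataError, ValidationError
from gazentropy.scanpath import AOISequence


def seq_of(symbols, dwells=None):
    symbols = np.asarray(symbols)
    dwells = np.ones(len(symbols)) if dwells is None else np.asarray(dwells)
    return AOISequence("P1", "T1", symbols, dwells)


def brute_force_counts(symbols, n):
    counts = np.zeros((n, n), dtype=int)
    for a, b in zip(symbols[:-1], symbols[1:]):
        counts[a - 1, b - 1] += 1
    return counts


def power_iteration_stationary(P, iters=10_000):
    pi = np.full(P.shape[0], 1.0 / P.shape[0])
    for _ in range(iters):
        pi = pi @ P
        pi /= pi.sum()
    return pi


class TestEstimateModel:
    def test_hand_counts_1213(self):
        m = estimate_model(seq_of([1, 2, 1, 3]), 3)
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = 1  # 1 -> 2
        expected[1, 0] = 1  # 2 -> 1
        expected[0, 2] = 1  # 1 -> 3
        assert m.counts.tolist() == expected.tolist()
        np.testing.assert_allclose(m.p_ij[0], [0, 0.5, 0.5])
        np.testing.assert_allclose(m.p_i, [0.5, 0.25, 0.25])
        assert m.n_transitions == 3

    def test_alternating_chain_deterministic(self):
        m = estimate_model(seq_of([1, 2] * 50), 3)
        assert m.p_ij[0, 1] == 1.0 and m.p_ij[1, 0] == 1.0
        assert m.p_i[2] == 0.0
        assert np.all(m.p_ij[2] == 0.0)  # unvisited row stays all-zero

    def test_left_eigenvector_matches_power_iteration(self):
        m = estimate_model(seq_of([1, 2] * 50), 3, p_i_estimator="left_eigenvector")
        np.testing.assert_allclose(m.p_i, [0.5, 0.5, 0.0], atol=1e-12)
        # independent oracle on an irreducible random chain
        rng = np.random.default_rng(7)
        sym = rng.integers(1, 4, 500)
        sym = sym[np.r_[True, sym[1:] != sym[:-1]]]
        m2 = estimate_model(seq_of(sym), 3, p_i_estimator="left_eigenvector")
        np.testing.assert_allclose(m2.p_i, power_iteration_stationary(m2.p_ij), atol=1e-9)

    def test_dwell_weighted_estimator(self):
        m = estimate_model(seq_of([1, 2], [300.0, 100.0]), 2, p_i_estimator="dwell_weighted")
        np.testing.assert_allclose(m.p_i, [0.75, 0.25])

    def test_too_short_sequence_errors_with_ids(self):
        with pytest.raises(InsufficientDataError, match="P1/T1"):
            estimate_model(seq_of([1]), 3)

    def test_oracle_equivalence_random_sequences(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            sym = rng.integers(1, 4, n)
            assert (
                transition_counts(sym, 3).tolist()
                == brute_force_counts(sym, 3).tolist()
            )

    def test_streaming_update_changes_one_cell(self, rng):
        sym = rng.integers(1, 4, 30)
        c0 = transition_counts(sym, 3)
        c1 = transition_counts(np.append(sym, 2), 3)
        assert (c1 - c0).sum() == 1 and ((c1 - c0) != 0).sum() == 1


class TestSGE:
    def test_uniform_is_log2_n(self):
        assert abs(compute_sge(np.ones(3) / 3) - np.log2(3)) < 1e-12

    def test_degenerate_is_zero(self):
        assert compute_sge(np.array([1.0, 0, 0])) == 0.0

    def test_hand_case_half_quarter_quarter(self):
        assert abs(compute_sge(np.array([0.5, 0.25, 0.25])) - 1.5) < 1e-12

    def test_unnormalized_vector_rejected(self):
        with pytest.raises(ValidationError):
            compute_sge(np.array([0.5, 0.4]))

    def test_permutation_invariance(self, rng):
        p = rng.dirichlet(np.ones(4))
        assert abs(compute_sge(p) - compute_sge(p[::-1])) < 1e-12


class TestGTE:
    def test_deterministic_cycle_is_zero(self):
        P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        assert compute_gte(np.ones(3) / 3, P) == 0.0

    def test_uniform_over_two_destinations_is_one_bit(self):
        P = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        assert abs(compute_gte(np.ones(3) / 3, P) - 1.0) < 1e-12

    def test_only_weighted_rows_count(self):
        P = np.array([[0, 0.5, 0.5], [1, 0, 0], [1, 0, 0]], dtype=float)
        assert abs(compute_gte(np.array([1.0, 0, 0]), P) - 1.0) < 1e-12

    def test_zero_support_rows_contribute_zero(self):
        P = np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0]], dtype=float)
        assert compute_gte(np.array([1.0, 0, 0]), P) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_gte(np.ones(2) / 2, np.eye(3))

    def test_conditioning_reduces_entropy(self, rng):
        """H_t <= H_s for any stationary (pi, P): conditioning cannot add
        information."""
        for _ in range(100):
            P = rng.dirichlet(np.ones(3), size=3)
            pi = stationary_distribution(P)
            assert compute_gte(pi, P) <= compute_sge(pi) + 1e-12

    def test_joint_permutation_invariance(self, rng):
        P = rng.dirichlet(np.ones(3), size=3)
        pi = stationary_distribution(P)
        perm = np.array([2, 0, 1])
        assert abs(
            compute_gte(pi[perm], P[np.ix_(perm, perm)]) - compute_gte(pi, P)
        ) < 1e-12


class TestNormalize:
    def test_max_sge(self):
        assert normalize_entropy(np.log2(3), 3, exclude_self=False) == 1.0

    def test_zero(self):
        assert normalize_entropy(0.0, 3, exclude_self=True) == 0.0

    def test_max_gte_with_self_exclusion(self):
        # log2(3 - 1) = 1, so 1 bit is the ceiling
        assert normalize_entropy(1.0, 3, exclude_self=True) == 1.0

    def test_small_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            normalize_entropy(0.5, 1)


class TestAggregate:
    def make(self, p12):
        counts = np.array([[0, 10, 0], [10, 0, 0], [0, 0, 0]])
        P = np.array([[0, p12, 1 - p12], [1, 0, 0], [0, 0, 0]], dtype=float)
        return TransitionModel(3, counts, np.array([0.5, 0.5, 0.0]), P, 20)

    def test_single_model_identity(self):
        m = self.make(0.2)
        np.testing.assert_allclose(aggregate_condition_matrix([m]), m.p_ij)

    def test_mean_of_two(self):
        agg = aggregate_condition_matrix([self.make(0.2), self.make(0.4)])
        assert abs(agg[0, 1] - 0.3) < 1e-12

    def test_mismatched_sizes_rejected(self):
        bad = TransitionModel(
            2, np.array([[0, 1], [1, 0]]), np.array([0.5, 0.5]),
            np.array([[0.0, 1], [1, 0]]), 2,
        )
        with pytest.raises(ValidationError):
            aggregate_condition_matrix([self.make(0.2), bad])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_condition_matrix([])


def test_analytic_entropies_match_hand_values():
    P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    sge, gte = analytic_entropies(P)
    assert abs(sge - np.log2(3)) < 1e-9
    assert gte == 0.0
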