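import numpy as np
import pytest

from irdyn.norms import named_norm
from irdyn.reputation import (
    birth_death_probs,
    build_transition_matrix,
    stationary_distribution,
    stationary_frame,
)
from irdyn.strategies import InteractionProbs, interaction_probs, named_strategy

from conftest import BASE_ERRORS


def chain_probs(strategy_name, norm_name, errors=BASE_ERRORS):
    return interaction_probs(named_strategy(strategy_name), named_norm(norm_name), errors)


def symmetric_probs(c, g):
    return InteractionProbs(c_g=c, c_b=c, g_g=g, g_b=g)


class TestBirthDeathProbs:
    def test_boundary_states_block_the_impossible_move(self):
        probs = symmetric_probs(0.5, 0.5)
        up, down, *_ = birth_death_probs(3, 1, 3, 5, probs, probs)  # h = k
        assert up == 0.0
        up, down, *_ = birth_death_probs(0, 1, 3, 5, probs, probs)  # h = 0
        assert down == 0.0

    def test_symmetric_assignment_collapses_inner_average(self):
        # with G_G = G_B = g the recipient mix is irrelevant: H_p^+ = (k-h)/Z * g
        g = 0.37
        probs = symmetric_probs(0.5, g)
        up, *_ = birth_death_probs(1, 1, 2, 4, probs, probs)
        assert up == pytest.approx((2 - 1) / 4 * g)

    def test_out_of_bounds_state_rejected(self):
        probs = symmetric_probs(0.5, 0.5)
        with pytest.raises(ValueError):
            birth_death_probs(4, 0, 3, 5, probs, probs)

    def test_event_probabilities_sum_below_one(self):
        p = chain_probs("Disc", "SJ")
        pp = chain_probs("AllD", "SJ")
        for h in range(4):
            for hp in range(3):
                four = birth_death_probs(h, hp, 3, 5, p, pp)
                assert all(v >= 0 for v in four)
                assert sum(four) <= 1 + 1e-12


class TestTransitionMatrix:
    def test_state_count_and_shape(self):
        chain = build_transition_matrix(1, 2, symmetric_probs(0.5, 0.5), symmetric_probs(0.5, 0.5))
        assert chain.n_states == 4
        assert chain.H.shape == (4, 4)

    def test_rows_are_stochastic(self):
        chain = build_transition_matrix(3, 7, chain_probs("Disc", "SJ"), chain_probs("AllD", "SJ"))
        sums = np.asarray(chain.H.sum(axis=1)).ravel()
        assert sums == pytest.approx(np.ones(chain.n_states), abs=1e-12)

    def test_linear_index_map(self):
        chain = build_transition_matrix(2, 5, symmetric_probs(0.5, 0.5), symmetric_probs(0.5, 0.5))
        assert chain.state_index(1, 2) == 1 * (5 - 2 + 1) + 2
        assert chain.state_of(chain.state_index(2, 3)) == (2, 3)
        with pytest.raises(ValueError):
            chain.state_index(3, 0)

    def test_all_good_state_absorbing_under_all_forgiving_assignment(self):
        probs = symmetric_probs(0.5, 1.0)
        chain = build_transition_matrix(2, 5, probs, probs)
        i = chain.state_index(2, 3)
        assert chain.H[i, i] == pytest.approx(1.0)

    def test_camp_swap_symmetry(self):
        # swapping (p, k) with (p', Z-k) transposes the (h, h') indexing
        p = chain_probs("Disc", "SS")
        pp = chain_probs("AllC", "SS")
        Z, k = 6, 2
        a = build_transition_matrix(k, Z, p, pp)
        b = build_transition_matrix(Z - k, Z, pp, p)
        for h in range(k + 1):
            for hp in range(Z - k + 1):
                for h2 in range(k + 1):
                    for hp2 in range(Z - k + 1):
                        assert a.H[a.state_index(h, hp), a.state_index(h2, hp2)] == pytest.approx(
                            b.H[b.state_index(hp, h), b.state_index(hp2, h2)], abs=1e-15
                        )


class TestStationaryDistribution:
    def test_absorbing_all_good_and_all_bad_limits(self):
        Z, k = 5, 2
        all_good = symmetric_probs(0.5, 1.0)
        chain = build_transition_matrix(k, Z, all_good, all_good)
        sigma = stationary_distribution(chain)
        expected = np.zeros(chain.n_states)
        expected[chain.state_index(k, Z - k)] = 1.0
        assert sigma == pytest.approx(expected, abs=1e-12)

        all_bad = symmetric_probs(0.5, 0.0)
        chain = build_transition_matrix(k, Z, all_bad, all_bad)
        sigma = stationary_distribution(chain)
        assert sigma[chain.state_index(0, 0)] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("norm_name", ["SJ", "SS", "SH", "IS"])
    def test_sigma_is_invariant_normalized_and_positive(self, norm_name):
        chain = build_transition_matrix(
            4, 9, chain_probs("Disc", norm_name), chain_probs("AllD", norm_name)
        )
        sigma = stationary_distribution(chain)
        assert sigma.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.abs(sigma @ chain.H - sigma).max() < 1e-10
        # with alpha, chi > 0 the chain is irreducible: strictly positive law
        assert sigma.min() > 0

    def test_matches_monte_carlo_occupancy(self):
        from oracle_utils import chain_occupancy

        chain = build_transition_matrix(
            2, 5, chain_probs("Disc", "SJ"), chain_probs("AllD", "SJ")
        )
        sigma = stationary_distribution(chain)
        occupancy = chain_occupancy(chain, n_steps=1_000_000, seed=7)
        tv = 0.5 * np.abs(sigma - occupancy).sum()
        assert tv < 0.02

    def test_monomorphic_chain_is_one_dimensional(self):
        probs = chain_probs("Disc", "SJ")
        chain = build_transition_matrix(8, 8, probs, probs)
        assert chain.n_states == 9
        sigma = stationary_distribution(chain)
        assert sigma.sum() == pytest.approx(1.0, abs=1e-10)

    def test_large_sparse_chain_agrees_with_dense_solver(self):
        # straddle the dense/sparse cutoff with the same physical chain
        p, pp = chain_probs("Disc", "SS"), chain_probs("AllC", "SS")
        chain = build_transition_matrix(15, 30, p, pp)  # S = 256 -> sparse path
        sigma_sparse = stationary_distribution(chain)
        dense = np.linalg.matrix_power(chain.H.toarray(), 1 << 40)
        # the repeated-squaring oracle itself carries ~1e-6 accumulation error
        assert sigma_sparse == pytest.approx(dense[0], abs=1e-5)


def test_stationary_frame_layout():
    chain = build_transition_matrix(2, 4, symmetric_probs(0.4, 0.6), symmetric_probs(0.4, 0.6))
    sigma = stationary_distribution(chain)
    frame = stationary_frame(chain, sigma)
    assert list(frame.columns) == ["h", "h_prime", "probability"]
    assert len(frame) == chain.n_states
    assert frame["probability"].sum() == pytest.approx(1.0)
    row = frame.iloc[chain.state_index(1, 2)]
    assert (row["h"], row["h_prime"]) == (1, 2)
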