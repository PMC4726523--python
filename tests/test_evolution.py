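import numpy as np
import pytest

from irdyn.evolution import (
    ModelParams,
    _fixation_from_deltas,
    cooperation_index,
    delta_fitness_profile,
    embedded_chain,
    fermi_prob,
    fixation_probability,
    monomorphic_stats,
    pairwise_fixation_matrix,
    transition_graph,
)
from irdyn.norms import Norm, mirror, named_norm
from irdyn.strategies import STRATEGY_ORDER, ErrorRates, named_strategy

from conftest import base_params


class TestFermiRule:
    def test_tie_and_neutral_drift_give_half(self):
        assert fermi_prob(0.0, 3.7) == 0.5
        assert fermi_prob(123.4, 0.0) == 0.5

    def test_deterministic_imitation_limit(self):
        assert fermi_prob(1e6, 1.0) == pytest.approx(1.0, abs=1e-12)
        assert fermi_prob(-1e6, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_no_overflow_at_strong_selection(self):
        assert np.isfinite(fermi_prob(-800.0, 10.0))

    def test_rejects_negative_selection_strength(self):
        with pytest.raises(ValueError):
            fermi_prob(0.1, -1.0)


class TestFixationProbability:
    def test_neutral_fixation_is_one_over_Z(self):
        params = base_params(Z=8, beta=0.0)
        rho = fixation_probability(named_strategy("Disc"), named_strategy("AllD"), params)
        assert rho == pytest.approx(1 / 8, rel=1e-14)

    def test_constant_advantage_beats_neutral(self):
        Z = 10
        deltas = np.full(Z - 1, 0.3)
        assert _fixation_from_deltas(deltas, 1.0, Z) > 1 / Z
        assert _fixation_from_deltas(-deltas, 1.0, Z) < 1 / Z

    def test_log_space_stability_at_large_beta(self):
        Z = 30
        deltas = np.linspace(-4, -2, Z - 1)
        rho = _fixation_from_deltas(deltas, 10.0, Z)
        assert 0.0 <= rho < 1e-20  # underflows gracefully, never overflows

    def test_identical_strategies_rejected(self):
        with pytest.raises(ValueError):
            fixation_probability(named_strategy("Disc"), named_strategy("Disc"), base_params(4))

    def test_matches_birth_death_simulation(self, rng):
        """Closed form vs the empirical fixation frequency of the simulated
        pairwise-comparison walk, using the same per-k fitness differences."""
        from oracle_utils import sample_fixation

        params = base_params(Z=6, norm_name="SJ")
        mutant, resident = named_strategy("AllD"), named_strategy("Disc")
        deltas = delta_fitness_profile(mutant, resident, params)
        rho = _fixation_from_deltas(deltas, params.beta, params.Z)
        n_runs = 100_000
        emp = sample_fixation(deltas, params.beta, params.Z, n_runs, seed=5)
        se = np.sqrt(rho * (1 - rho) / n_runs)
        assert abs(emp - rho) < 3 * se + 1e-12


class TestEmbeddedChain:
    def test_neutral_limit_uniform(self):
        params = base_params(Z=6, beta=0.0)
        rho = pairwise_fixation_matrix(params)
        off = rho[~np.isnan(rho)]
        assert off == pytest.approx(np.full(12, 1 / 6), rel=1e-12)
        T, lam = embedded_chain(rho)
        assert lam == pytest.approx(np.full(4, 0.25), abs=1e-12)

    def test_rows_of_T_are_stochastic_and_lambda_stationary(self):
        params = base_params(Z=10)
        rho = pairwise_fixation_matrix(params)
        T, lam = embedded_chain(rho)
        assert T.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)
        assert lam @ T == pytest.approx(lam, abs=1e-12)
        assert lam.sum() == pytest.approx(1.0)

    def test_ordered_pair_reduction_matches_direct_evaluation(self):
        # rho built from the reversed-profile shortcut equals the direct
        # mutant/resident computation
        params = base_params(Z=8, norm_name="SS")
        rho = pairwise_fixation_matrix(params)
        i, j = STRATEGY_ORDER.index("AllD"), STRATEGY_ORDER.index("Disc")
        # rho[i, j] is the fixation probability of a p_j mutant among p_i residents
        assert rho[i, j] == pytest.approx(
            fixation_probability(named_strategy("AllD"), named_strategy("Disc"), params),
            rel=1e-10,
        )
        assert rho[j, i] == pytest.approx(
            fixation_probability(named_strategy("Disc"), named_strategy("AllD"), params),
            rel=1e-10,
        )


class TestCooperationIndex:
    def test_total_execution_failure_kills_cooperation(self):
        params = ModelParams(
            Z=8, norm=named_norm("SJ"), errors=ErrorRates(alpha=0.01, epsilon=1.0, chi=0.01)
        )
        eta, _ = cooperation_index(params)
        assert eta == pytest.approx(0.0, abs=1e-12)

    def test_neutral_error_free_all_forgiving_norm_gives_half(self):
        # lambda uniform; AllC and Disc donate fully in the all-Good
        # population, AllD and pDisc never do
        params = ModelParams(
            Z=8, norm=Norm(1, 1, 1, 1), errors=ErrorRates(0, 0, 0), beta=0.0
        )
        eta, result = cooperation_index(params)
        assert eta == pytest.approx(0.5, abs=1e-12)
        donation = {m.strategy: m.donation_fraction for m in result.monomorphic}
        assert donation == pytest.approx(
            {"AllC": 1.0, "AllD": 0.0, "Disc": 1.0, "pDisc": 0.0}, abs=1e-12
        )

    def test_eta_within_unit_interval_and_lambda_normalized(self):
        eta, result = cooperation_index(base_params(Z=10, norm_name="SH"))
        assert 0.0 <= eta <= 1.0
        assert result.lam.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("norm_name", ["SJ", "SH"])
    def test_mirror_invariance_small(self, norm_name):
        params = base_params(Z=8, norm_name=norm_name)
        mirrored = ModelParams(
            Z=8, norm=mirror(params.norm), payoff=params.payoff,
            errors=params.errors, beta=params.beta,
        )
        eta, _ = cooperation_index(params)
        eta_m, _ = cooperation_index(mirrored)
        assert eta_m == pytest.approx(eta, abs=1e-8)


class TestMonomorphicStats:
    def test_all_defectors_never_donate(self):
        stats = monomorphic_stats("AllD", base_params(Z=10))
        assert stats.donation_fraction == 0.0

    def test_cooperators_under_stern_judging_stay_good(self):
        stats = monomorphic_stats("Disc", base_params(Z=20, norm_name="SJ"))
        assert stats.good_fraction > 0.8
        assert stats.donation_fraction > 0.7


class TestTransitionGraph:
    def test_neutral_dynamics_draw_no_edges(self):
        _, result = cooperation_index(base_params(Z=6, beta=0.0))
        g = transition_graph(result)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == set(STRATEGY_ORDER)

    def test_edges_are_strictly_above_neutral(self):
        _, result = cooperation_index(base_params(Z=10, norm_name="IS"))
        g = transition_graph(result)
        for _, _, attrs in g.edges(data=True):
            assert attrs["weight"] > 1.0

    def test_node_annotations_present(self):
        _, result = cooperation_index(base_params(Z=6))
        g = transition_graph(result)
        for _, attrs in g.nodes(data=True):
            assert {"stationary_probability", "donation_fraction", "good_fraction"} <= set(attrs)
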