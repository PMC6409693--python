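import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import ieaco
from ieaco.entropy import Strategy
from ieaco.search import (
    ConfigurationError,
    InvalidStateError,
    PheromoneState,
    SamplingError,
    SearchConfig,
    _sample_sets,
    negative_feedback_weights,
    run_search,
    sample_snp_set,
    selection_probs_negative,
    selection_probs_positive,
    update_pheromones,
)

positive_vectors = st.lists(
    st.floats(min_value=1e-3, max_value=1e6), min_size=2, max_size=30
)


class TestSelectionProbs:
    def test_uniform_state_gives_uniform_probs(self):
        p = selection_probs_positive(np.full(8, 100.0), 1.0)
        np.testing.assert_allclose(p, 1 / 8, atol=1e-15)

    def test_zero_exponents_ignore_state(self):
        tau = np.array([10.0, 500.0, 3.0])
        p = selection_probs_positive(tau, 1.0, alpha=0.0, beta=0.0)
        np.testing.assert_allclose(p, 1 / 3, atol=1e-15)

    def test_proportional_to_pheromone_share(self):
        # one colony update after three ants deposited 50/40/20 on pairs
        tau = np.array([145, 145, 135, 135, 115, 115, 95, 95, 95, 95], dtype=float)
        p = selection_probs_positive(tau, 1.0)
        np.testing.assert_allclose(p, tau / 1170.0, atol=1e-15)
        assert p[0] == pytest.approx(0.12393, abs=5e-6)

    @given(positive_vectors, positive_vectors)
    def test_normalization(self, tau, eta):
        n = min(len(tau), len(eta))
        p = selection_probs_positive(np.asarray(tau[:n]), np.asarray(eta[:n]))
        assert abs(p.sum() - 1.0) < 1e-12
        w = negative_feedback_weights(np.asarray(tau[:n]), mu=1e7)
        q = selection_probs_negative(np.asarray(tau[:n]), np.asarray(eta[:n]), w)
        assert abs(q.sum() - 1.0) < 1e-12

    def test_nonpositive_state_rejected(self):
        with pytest.raises(InvalidStateError):
            selection_probs_positive(np.array([1.0, 0.0]), 1.0)
        with pytest.raises(InvalidStateError):
            selection_probs_positive(np.array([1.0, 2.0]), -1.0)


class TestNegativeFeedback:
    def test_worked_example(self):
        # a neglected locus with tau = 81 under mu = 300 gets weight 219
        w = negative_feedback_weights(np.array([81.0]), mu=300.0)
        assert w[0] == pytest.approx(219.0, abs=1e-12)

    def test_empty_locus_gets_full_bound(self):
        assert negative_feedback_weights(np.array([0.0]), mu=300.0)[0] == 300.0

    def test_saturated_locus_clamped_to_floor(self):
        w = negative_feedback_weights(np.array([300.0, 450.0]), mu=300.0)
        assert np.all(w == 1e-6)

    def test_gamma_zero_reduces_to_positive_rule(self):
        rng = np.random.default_rng(5)
        tau = rng.uniform(10, 200, size=12)
        eta = rng.uniform(0.5, 2.0, size=12)
        w = negative_feedback_weights(tau, mu=300.0)
        np.testing.assert_allclose(
            selection_probs_negative(tau, eta, w, gamma=0.0),
            selection_probs_positive(tau, eta),
            atol=1e-14,
        )

    def test_hand_worked_two_locus_probs(self):
        # tau (200, 100), mu 300 -> w (100, 200); products equal -> 50/50
        tau = np.array([200.0, 100.0])
        w = negative_feedback_weights(tau, mu=300.0)
        p = selection_probs_negative(tau, 1.0, w)
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-14)


class TestSampleSNPSet:
    def test_forced_and_degenerate_draws(self):
        rng = np.random.default_rng(0)
        assert sample_snp_set([0.5, 0.5], 2, rng) == (0, 1)
        assert sample_snp_set([1.0, 0.0, 0.0], 1, rng) == (0,)
        with pytest.raises(SamplingError):
            sample_snp_set([1.0, 0.0, 0.0], 2, rng)

    def test_uniform_pair_frequencies(self):
        rng = np.random.default_rng(123)
        draws = _sample_sets(np.full(4, 0.25), 2, 60000, rng)
        pairs, counts = np.unique(draws, axis=0, return_counts=True)
        assert len(pairs) == 6
        sigma = np.sqrt((1 / 6) * (5 / 6) / 60000)
        assert np.all(np.abs(counts / 60000 - 1 / 6) < 4 * sigma)

    def test_matches_sequential_enumeration(self):
        """Unordered-pair frequencies match the exhaustive enumeration of
        sequential without-replacement sampling probabilities:
        P({a,b}) = p_a p_b (1/(1-p_a) + 1/(1-p_b))."""
        p = np.array([0.40, 0.25, 0.15, 0.12, 0.08])
        rng = np.random.default_rng(321)
        n = 60000
        draws = _sample_sets(p, 2, n, rng)
        codes = draws[:, 0] * 5 + draws[:, 1]
        expected = {}
        for a, b in itertools.combinations(range(5), 2):
            expected[a * 5 + b] = p[a] * p[b] * (1 / (1 - p[a]) + 1 / (1 - p[b]))
        observed = [np.sum(codes == c) for c in expected]
        gof = stats.chisquare(observed, n * np.array(list(expected.values())))
        assert gof.pvalue > 0.001


class TestUpdatePheromones:
    def test_pure_evaporation(self):
        state = PheromoneState(tau=np.full(3, 100.0))
        new = update_pheromones(state, np.empty((0, 2), dtype=int), [], rho=0.05)
        np.testing.assert_allclose(new.tau, 95.0)
        assert new.iteration == 1

    def test_single_ant_deposit(self):
        state = PheromoneState(tau=np.full(4, 100.0))
        new = update_pheromones(state, [(0, 1)], [50.0], rho=0.05)
        np.testing.assert_allclose(new.tau, [145.0, 145.0, 95.0, 95.0])

    def test_deposits_add_across_ants(self):
        state = PheromoneState(tau=np.full(3, 100.0))
        new = update_pheromones(state, [(0, 2), (1, 2)], [10.0, 20.0], rho=0.0)
        np.testing.assert_allclose(new.tau, [110.0, 120.0, 130.0])

    def test_negative_fitness_rejected(self):
        state = PheromoneState(tau=np.full(3, 100.0))
        with pytest.raises(InvalidStateError):
            update_pheromones(state, [(0, 1)], [-1.0], rho=0.05)


class TestRunSearch:
    def test_two_locus_dataset_reports_the_only_pair(self, models):
        ds = ieaco.simulate_dataset(
            models["model8"], 2, 200, 200, pair_positions=(0, 1), seed=4
        )
        res = run_search(ds, SearchConfig(n_ants=10, n_iterations=3, seed=0))
        assert res.top_hit == (0, 1)
        assert all(p.p_value < 0.05 for _, p in res.reported)

    def test_theta_below_any_change_reduces_to_aco(self, small_dataset):
        """theta = -1 keeps |dH| > theta forever, so the ieaco trajectory is
        the standard positive-feedback colony."""
        kw = dict(n_ants=30, n_iterations=15, seed=9)
        ie = run_search(small_dataset, SearchConfig(mode="ieaco", theta=-1.0, **kw))
        aco = run_search(small_dataset, SearchConfig(mode="aco", **kw))
        assert ie.per_iteration_best == aco.per_iteration_best
        assert ie.reported == aco.reported
        assert all(s is Strategy.POSITIVE for s in ie.strategies)

    def test_gamma_zero_reduces_to_aco(self, small_dataset):
        kw = dict(n_ants=30, n_iterations=15, seed=9)
        ie = run_search(small_dataset, SearchConfig(mode="ieaco", gamma=0.0, theta=10.0, **kw))
        aco = run_search(small_dataset, SearchConfig(mode="aco", **kw))
        assert ie.per_iteration_best == aco.per_iteration_best
        np.testing.assert_allclose(ie.pheromones, aco.pheromones)

    def test_forced_switch_uses_negative_feedback_after_first_iteration(self, small_dataset):
        res = run_search(
            small_dataset,
            SearchConfig(theta=100.0, n_ants=20, n_iterations=5, seed=2),
        )
        assert res.strategies[0] is Strategy.POSITIVE
        assert all(s is Strategy.NEGATIVE for s in res.strategies[1:])

    def test_seeded_run_is_reproducible(self, small_dataset):
        cfg = SearchConfig(n_ants=25, n_iterations=10, seed=77)
        a = run_search(small_dataset, cfg)
        b = run_search(small_dataset, cfg)
        assert a.per_iteration_best == b.per_iteration_best
        assert a.reported == b.reported
        np.testing.assert_array_equal(a.pheromones, b.pheromones)
        c = run_search(small_dataset, SearchConfig(n_ants=25, n_iterations=10, seed=78))
        assert a.per_iteration_best != c.per_iteration_best

    def test_state_invariants_after_run(self, small_dataset):
        res = run_search(small_dataset, SearchConfig(n_ants=20, n_iterations=10, seed=1))
        assert np.all(res.pheromones > 0)
        h = res.entropy_history.values
        assert len(h) == 11
        assert all(0 <= v <= np.log2(small_dataset.n_snps) + 1e-9 for v in h)
        assert len(res.per_iteration_best) == 10
        # reported candidates are distinct and ranked by chi2 descending
        sets = [s for s, _ in res.reported]
        assert len(sets) == len(set(sets))
        chis = [f.chi2 for _, f in res.reported]
        assert chis == sorted(chis, reverse=True)

    def test_entropy_decreases_once_deposits_concentrate(self, model1):
        """On this seeded run the pheromone distribution concentrates on the
        embedded pair and entropy falls monotonically."""
        ds = ieaco.simulate_dataset(model1, 30, 500, 500, pair_positions=(4, 21), seed=11)
        res = run_search(ds, SearchConfig(n_iterations=40, seed=42))
        h = np.array(res.entropy_history.values)
        assert np.all(np.diff(h) <= 1e-9)
        assert res.top_hit == (4, 21)

    def test_aco_mode_has_no_entropy_history(self, small_dataset):
        res = run_search(small_dataset, SearchConfig(mode="aco", n_ants=5, n_iterations=2, seed=0))
        assert res.entropy_history is None

    def test_config_validation(self, small_dataset):
        with pytest.raises(ConfigurationError):
            SearchConfig(mode="pso")
        with pytest.raises(ConfigurationError):
            SearchConfig(rho=1.0)
        with pytest.raises(ConfigurationError):
            SearchConfig(mode="ieaco", mu=50.0, tau0=100.0)
        with pytest.raises(ConfigurationError):
            run_search(small_dataset, SearchConfig(set_size=21))

    def test_resolved_defaults_follow_dataset_size(self):
        cfg = SearchConfig().resolved(500)
        assert (cfg.n_ants, cfg.n_iterations) == (500, 100)
        cfg = SearchConfig().resolved(5000)
        assert (cfg.n_ants, cfg.n_iterations) == (200, 1000)
        explicit = SearchConfig(n_ants=7, n_iterations=3).resolved(5000)
        assert (explicit.n_ants, explicit.n_iterations) == (7, 3)
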