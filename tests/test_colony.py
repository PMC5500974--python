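"""Colony engine: selection rules, combination construction, pheromones."""

import numpy as np
import pytest
from scipy import stats

from epiaco import AcoParams, ColonyState
from epiaco.colony import (
    construct_combination,
    q_threshold,
    select_probabilistic,
    select_stochastic,
    update_pheromones,
)
from epiaco.scoring import CombinationScore


def make_state(tau, params=None, iteration=1):
    tau = np.asarray(tau, dtype=float)
    params = params or AcoParams()
    state = ColonyState(tau=tau, eta=np.ones_like(tau), params=params)
    state.iteration = iteration
    return state


def score(snps, sv):
    return CombinationScore(snps=snps, mi=sv, k2_log=1.0, svalue=sv)


class TestQThreshold:
    @pytest.mark.parametrize("t, T, expected", [(1, 25, 0.04), (13, 25, 0.52),
                                                (25, 25, 1.0)])
    def test_ratio(self, t, T, expected):
        assert q_threshold(t, T) == pytest.approx(expected)

    @pytest.mark.parametrize("t, T", [(0, 25), (26, 25)])
    def test_out_of_range(self, t, T):
        with pytest.raises(ValueError):
            q_threshold(t, T)


class TestProbabilisticSelection:
    def test_uniform_weights_uniform_draws(self):
        state = make_state(np.ones(5))
        rng = np.random.default_rng(0)
        draws = [select_probabilistic(state, np.arange(5), rng)
                 for _ in range(10_000)]
        counts = np.bincount(draws, minlength=5)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_weighted_draws_track_pheromones(self):
        state = make_state([3.0, 1.0])
        rng = np.random.default_rng(1)
        draws = np.array([select_probabilistic(state, np.arange(2), rng)
                          for _ in range(4000)])
        frac0 = np.mean(draws == 0)
        assert abs(frac0 - 0.75) < 3 * np.sqrt(0.75 * 0.25 / 4000)

    def test_single_available(self):
        state = make_state(np.ones(4))
        rng = np.random.default_rng(2)
        assert select_probabilistic(state, [3], rng) == 3

    def test_empty_available_errors(self):
        state = make_state(np.ones(4))
        with pytest.raises(ValueError):
            select_probabilistic(state, [], np.random.default_rng(0))

    def test_alpha_exponent_applied(self):
        params = AcoParams(alpha=2.0)
        state = make_state([2.0, 1.0], params=params)
        rng = np.random.default_rng(3)
        draws = np.array([select_probabilistic(state, np.arange(2), rng)
                          for _ in range(4000)])
        assert abs(np.mean(draws == 0) - 0.8) < 0.03  # 4/(4+1)


class TestStochasticSelection:
    def test_lower_half_only(self):
        state = make_state([4.0, 3.0, 2.0, 1.0])
        rng = np.random.default_rng(4)
        draws = {select_stochastic(state, np.arange(4), rng)
                 for _ in range(200)}
        assert draws == {2, 3}

    def test_ties_broken_by_index(self):
        state = make_state(np.ones(5))
        # descending sort of equal pheromones keeps index order; latter
        # floor(5/2)=2 entries are indices 3, 4
        assert set(state.lower_half()) == {3, 4}

    def test_fallback_when_intersection_empty(self):
        state = make_state([4.0, 3.0, 2.0, 1.0])
        rng = np.random.default_rng(5)
        assert select_stochastic(state, [0], rng) == 0

    def test_uniform_over_pool(self):
        state = make_state([4.0, 3.0, 2.0, 1.0])
        rng = np.random.default_rng(6)
        draws = [select_stochastic(state, np.arange(4), rng)
                 for _ in range(4000)]
        counts = np.bincount(draws, minlength=4)[2:]
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestConstructCombination:
    def test_distinct_sorted_indices(self):
        params = AcoParams(n_ants=10, n_iterations=5, order=3)
        state = make_state(np.ones(8), params=params, iteration=2)
        rng = np.random.default_rng(7)
        for _ in range(100):
            combo = construct_combination(state, rng)
            assert len(set(combo)) == 3
            assert combo == tuple(sorted(combo))

    def test_full_set_when_order_equals_n(self):
        params = AcoParams(n_ants=3, n_iterations=4, order=4)
        state = make_state(np.ones(4), params=params)
        rng = np.random.default_rng(8)
        assert construct_combination(state, rng) == (0, 1, 2, 3)

    def test_final_iteration_fully_probabilistic(self):
        """At t=T the low-pheromone half is never the selection pool."""
        params = AcoParams(n_ants=10, n_iterations=5)
        # one SNP holds nearly all roulette mass; stochastic draws would
        # come uniformly from the lower half {2, 3} instead
        state = make_state([1e9, 1e9, 1.0, 1.0], params=params, iteration=5)
        rng = np.random.default_rng(9)
        combos = [construct_combination(state, rng) for _ in range(200)]
        assert all(c == (0, 1) for c in combos)

    def test_reproducible_given_seed(self):
        params = AcoParams(n_ants=5, n_iterations=6)
        state = make_state(np.arange(1.0, 11.0), params=params, iteration=3)
        a = [construct_combination(state, np.random.default_rng(42))
             for _ in range(1)]
        b = [construct_combination(state, np.random.default_rng(42))
             for _ in range(1)]
        assert a == b

    def test_stochastic_fraction_tracks_iteration_ratio(self):
        """Ants avoid the high-pheromone pair at rate ~ (1 - t/T)^2."""
        T = 10
        params = AcoParams(n_ants=10, n_iterations=T)
        for t in (2, 5, 8):
            # probabilistic draws almost surely take SNPs 0 or 1; a combo
            # without them implies both choices were stochastic
            state = make_state([1e9, 1e9] + [1.0] * 18, params=params,
                               iteration=t)
            rng = np.random.default_rng(100 + t)
            n = 3000
            misses = sum(
                1 for _ in range(n)
                if not set(construct_combination(state, rng)) & {0, 1}
            )
            expected = (1 - t / T) ** 2
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(misses / n - expected) < 4 * se + 1e-9


class TestPheromoneUpdate:
    def test_pure_evaporation_identity(self):
        state = make_state([1.0, 2.0, 3.0])
        tau = update_pheromones(state, [], None)
        np.testing.assert_allclose(tau, [0.8, 1.6, 2.4], atol=1e-15)

    def test_single_ant_candidate_reward(self):
        state = make_state(np.ones(4))
        s = 0.5
        tau = update_pheromones(state, [score((0, 1), s)], {(0, 1)})
        xi = state.params.xi
        np.testing.assert_allclose(
            tau, [0.8 + s + xi * s, 0.8 + s + xi * s, 0.8, 0.8], atol=1e-12
        )

    def test_non_candidate_gets_no_bonus(self):
        state = make_state(np.ones(3))
        tau = update_pheromones(state, [score((0, 1), 0.5)], set())
        np.testing.assert_allclose(tau, [1.3, 1.3, 0.8], atol=1e-12)

    def test_duplicate_ants_deposit_twice(self):
        state = make_state(np.ones(3))
        tau = update_pheromones(
            state, [score((0, 1), 0.5), score((0, 1), 0.5)], set()
        )
        np.testing.assert_allclose(tau, [1.8, 1.8, 0.8], atol=1e-12)

    def test_xi_zero_reduces_to_plain_update(self):
        params = AcoParams(xi=0.0)
        state = make_state(np.ones(3), params=params)
        with_candidate = update_pheromones(state, [score((0, 1), 0.5)], {(0, 1)})
        without = update_pheromones(state, [score((0, 1), 0.5)], set())
        np.testing.assert_allclose(with_candidate, without, atol=1e-15)

    def test_scale_divides_deposits(self):
        state = make_state(np.ones(2))
        tau = update_pheromones(state, [score((0, 1), 0.5)], set(), scale=0.5)
        np.testing.assert_allclose(tau, [1.8, 1.8], atol=1e-12)

    def test_pheromones_stay_positive(self):
        state = make_state(np.full(5, 1e-6))
        tau = update_pheromones(state, [], None)
        assert np.all(tau > 0)


class TestParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_ants": 2},
        {"order": 1},
        {"rho": 1.0},
        {"xi": 1.5},
        {"tau0": 0.0},
        {"n_iterations": 0},
        {"deposit_normalization": "bogus"},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            AcoParams(**kwargs)
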