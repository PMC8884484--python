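"""Unit and property tests for the transition-kernel building blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chase import (
    CityMap,
    DegenerateMapError,
    ModelParameters,
    ParameterError,
    PopulationState,
    attraction_weight,
    beta_schedule,
    build_kernels,
    staying_probability,
    transition_kernel,
)
from conftest import random_state


class TestBetaSchedule:
    @pytest.mark.parametrize(
        "t,tau,expected",
        [
            (0, 60.0, 0.0),  # mindsets start at distance-only decisions
            (60, 60.0, 1.0 - math.exp(-1.0)),
            (0, 0.0, 1.0),  # tau=0 means the exponent is pinned at 1
            (5000, 0.0, 1.0),
            (1_000_000, 60.0, 1.0),
        ],
    )
    def test_values(self, t, tau, expected):
        assert beta_schedule(t, tau) == pytest.approx(expected, abs=1e-12)

    def test_vectorized(self):
        out = beta_schedule(np.arange(5), 10.0)
        assert out.shape == (5,)
        assert out[0] == 0.0

    @given(
        t=st.floats(0, 1e6),
        dt=st.floats(0, 1e6),
        tau=st.floats(0, 1e4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_t_and_rate(self, t, dt, tau):
        b1 = beta_schedule(t, tau)
        assert 0.0 <= b1 <= 1.0
        assert beta_schedule(t + dt, tau) >= b1
        # a faster mindset change (smaller tau) never lowers beta
        if tau > 1.0:
            assert beta_schedule(t, tau / 2 if tau / 2 > 0 else 0.0) >= b1

    @pytest.mark.parametrize("t,tau", [(-1, 60.0), (5, -0.1)])
    def test_invalid(self, t, tau):
        with pytest.raises(ParameterError):
            beta_schedule(t, tau)


class TestStayingProbability:
    def test_max_at_characteristic_size(self):
        # (e)(n/K)e^{-n/K} peaks at exactly 1 when n = K and beta = 1
        assert staying_probability(5000.0, 5000.0, 1.0, 0.2) == pytest.approx(1.0, abs=1e-12)

    def test_empty_city_beta_zero(self):
        assert staying_probability(0.0, 5000.0, 0.0, 0.2) == pytest.approx(1.0, abs=1e-12)

    def test_crowded_city_approaches_floor(self):
        # at n = 100 K the bonus term is ~1e-41, so w_jj -> 1 - delta
        assert staying_probability(500_000.0, 5000.0, 1.0, 0.2) == pytest.approx(0.8, abs=1e-12)

    @given(
        n=st.floats(0, 1e6),
        K=st.floats(1.0, 1e5),
        beta=st.floats(0.0, 1.0),
        delta=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds(self, n, K, beta, delta):
        p = staying_probability(n, K, beta, delta)
        assert 1.0 - delta - 1e-12 <= p <= 1.0 + 1e-12

    def test_invalid_K(self):
        with pytest.raises(ParameterError):
            staying_probability(10.0, 0.0, 1.0, 0.2)


class TestAttractionWeight:
    def _state(self, L=3):
        n = np.zeros((L, L))
        n[1, 0] = 100.0  # destination city 1 holds 100 origin-0 people
        return PopulationState(n=n)

    def test_social_ties_amplify_own_origin(self):
        # unit distance 0 -> 1, so the weight is the bare population factor
        cmap1 = CityMap.from_coords([(0.0, 0.0), (1.0, 0.0), (0.5, 5.0)], K=5000.0)
        p = ModelParameters(gamma=50.0, alpha=1.0)
        w = attraction_weight(1, 0, 0, self._state(), cmap1, p, beta=1.0)
        assert w == pytest.approx(5000.0 * math.exp(-0.02), rel=1e-12)

    def test_neutral_gamma_reduces_to_total_population(self):
        cmap1 = CityMap.from_coords([(0.0, 0.0), (1.0, 0.0), (0.5, 5.0)], K=5000.0)
        p = ModelParameters(gamma=1.0, alpha=1.0)
        w = attraction_weight(1, 0, 0, self._state(), cmap1, p, beta=1.0)
        assert w == pytest.approx(100.0 * math.exp(-0.02), rel=1e-12)

    def test_empty_destination_zero_for_positive_beta(self, small_map):
        st_ = PopulationState(n=np.zeros((3, 3)))
        w = attraction_weight(1, 0, 0, st_, small_map, ModelParameters(), beta=1.0)
        assert w == 0.0

    def test_empty_destination_unit_population_factor_at_beta_zero(self, small_map):
        st_ = PopulationState(n=np.zeros((3, 3)))
        w = attraction_weight(1, 0, 0, st_, small_map, ModelParameters(), beta=0.0)
        d = small_map.dist[1, 0]
        assert w == pytest.approx(d**-1.0, rel=1e-12)

    def test_same_city_is_contract_violation(self, small_map):
        with pytest.raises(ParameterError):
            attraction_weight(1, 1, 0, self._state(), small_map, ModelParameters(), 1.0)


class TestTransitionKernel:
    def test_columns_sum_to_one_randomized(self, ten_city_map):
        rng = np.random.default_rng(7)
        for trial in range(20):
            st_ = random_state(rng, 10, scale=2000.0)
            p = ModelParameters(
                delta=float(rng.uniform(0.05, 1.0)),
                gamma=float(rng.choice([0.0, 1.0, 10.0, 50.0])),
                tau_beta=float(rng.choice([0.0, 60.0, 120.0])),
            )
            W = build_kernels(st_, int(rng.integers(0, 200)), ten_city_map, p)
            assert np.all(W >= 0) and np.all(W <= 1 + 1e-12)
            assert np.max(np.abs(W.sum(axis=1) - 1.0)) < 1e-12

    def test_diagonal_bounded_below_by_one_minus_delta(self, ten_city_map):
        rng = np.random.default_rng(11)
        st_ = random_state(rng, 10)
        p = ModelParameters(delta=0.3)
        W = build_kernels(st_, 10, ten_city_map, p)
        diag = W[:, np.arange(10), np.arange(10)]
        assert np.all(diag >= 1 - 0.3 - 1e-12) and np.all(diag <= 1 + 1e-12)

    def test_limit_beta_to_zero_matches_distance_only_kernel(self, ten_city_map):
        # beta = 1 - exp(-1/1e8) ~ 1e-8 must agree with the beta = 0 form
        rng = np.random.default_rng(3)
        for _ in range(5):
            st_ = random_state(rng, 10)
            p = ModelParameters(gamma=50.0)
            W_small = build_kernels(st_, 1, ten_city_map, p.with_(tau_beta=1e8))
            W_zero = build_kernels(st_, 0, ten_city_map, p.with_(tau_beta=60.0))
            assert np.max(np.abs(W_small - W_zero)) < 1e-6

    def test_invariant_under_map_rescaling(self, ten_city_map):
        rng = np.random.default_rng(5)
        st_ = random_state(rng, 10)
        p = ModelParameters()
        W = build_kernels(st_, 30, ten_city_map, p)
        for c in (0.01, 3.7, 1000.0):
            scaled = CityMap(
                coords=ten_city_map.coords * c,
                dist=ten_city_map.dist * c,
                K=ten_city_map.K,
            )
            W_scaled = build_kernels(st_, 30, scaled, p)
            assert np.max(np.abs(W - W_scaled)) < 1e-12

    def test_homophily_monotone_in_gamma(self, small_map):
        # city 1 is richer in origin-0 people than city 2 (equal totals,
        # equal distance from city 0); stronger ties must not lower the
        # probability of choosing city 1
        n = np.zeros((3, 3))
        n[0, 0] = 1000.0
        n[1] = [300.0, 50.0, 50.0]
        n[2] = [100.0, 150.0, 150.0]
        st_ = PopulationState(n=n)
        p = ModelParameters(tau_beta=0.0)  # beta = 1
        prev = -1.0
        for gamma in (0.0, 0.5, 1.0, 2.0, 10.0, 50.0, 200.0):
            k = transition_kernel(st_, 5, 0, small_map, p.with_(gamma=gamma))
            p_rich = k.w[1, 0]
            assert p_rich >= prev - 1e-12
            prev = p_rich

    def test_symmetric_two_city_probabilities_equal(self):
        cmap = CityMap.from_coords([(0.0, 0.0), (1.0, 0.0), (0.5, 0.5)], K=500.0)
        n = np.full((3, 3), 10.0)
        st_ = PopulationState(n=n)
        k = transition_kernel(st_, 3, 0, cmap, ModelParameters(tau_beta=0.0))
        # cities 0 and 1 have identical composition and d(0,2) = d(1,2)
        assert k.w[0, 2] == pytest.approx(k.w[1, 2], rel=1e-12)

    def test_lonely_populated_city_keeps_everyone(self, small_map):
        n = np.zeros((3, 3))
        n[0, 0] = 900.0
        st_ = PopulationState(n=n)
        k = transition_kernel(st_, 10, 0, small_map, ModelParameters(tau_beta=0.0))
        assert k.w[0, 0] == 1.0
        assert np.all(k.w[1:, 0] == 0.0)

    def test_dimension_mismatch(self, small_map):
        st_ = PopulationState(n=np.eye(4))
        with pytest.raises(ParameterError):
            build_kernels(st_, 0, small_map, ModelParameters())


class TestDomainTypes:
    def test_map_requires_consistent_distances(self):
        coords = np.array([(0.0, 0.0), (1.0, 0.0)])
        bad = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.raises(DegenerateMapError):
            CityMap(coords=coords, dist=bad, K=np.ones(2))

    def test_map_rejects_nonpositive_K(self):
        with pytest.raises(ParameterError):
            CityMap.from_coords([(0, 0), (1, 0)], K=0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta": 0.0},
            {"delta": 1.5},
            {"alpha": -1.0},
            {"gamma": -0.1},
            {"tau_beta": -5.0},
            {"n0": 0.0},
            {"epsilon": -1.0},
            {"mode": "hybrid"},
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ParameterError):
            ModelParameters(**kwargs)

    def test_state_rejects_negative_population(self):
        with pytest.raises(ParameterError):
            PopulationState(n=np.array([[1.0, -1.0], [0.0, 0.0]]))
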