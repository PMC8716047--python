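"""Unit tests for the continuous-space population mechanics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from ratdrive import (CalibrationError, Landscape, ParameterSet, Population,
                      average_competition, competition_weight, disperse,
                      edge_compensation, migration_step, select_mate,
                      solve_density_tuning)
from ratdrive.demography import (competition_totals, find_mates,
                                 survival_probabilities, survival_step)


class TestCompetitionWeight:
    def test_maximum_at_zero_distance(self):
        assert competition_weight(0.0, 75.0) == 1.0

    def test_value_at_interaction_distance(self):
        # sigma = R/3, so d = R is 3 sigma out: exp(-4.5)
        assert competition_weight(75.0, 75.0) == pytest.approx(
            math.exp(-4.5), rel=1e-12)

    def test_truncated_beyond_interaction_distance(self):
        assert competition_weight(76.0, 75.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            competition_weight(-1.0, 75.0)

    @given(st.floats(0.0, 74.0), st.floats(0.0, 74.0))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_inside_radius(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert competition_weight(lo, 75.0) >= competition_weight(hi, 75.0)

    def test_continuous_up_to_radius(self):
        d = np.linspace(0.0, 75.0, 2000)
        w = competition_weight(d, 75.0)
        assert np.all(np.abs(np.diff(w)) < 1e-3)


class TestEdgeCompensation:
    landscape = Landscape(2000.0)

    def test_interior_is_one(self):
        assert edge_compensation(1000.0, 1000.0, 75.0, self.landscape) == 1.0

    def test_edge_doubles(self):
        got = edge_compensation(0.0, 1000.0, 75.0, self.landscape)
        assert got == pytest.approx(2.0, rel=1e-6)

    def test_corner_quadruples(self):
        got = edge_compensation(0.0, 0.0, 75.0, self.landscape)
        assert got == pytest.approx(4.0, rel=1e-6)

    @pytest.mark.parametrize("frac", [0.2, 0.5, 0.8])
    def test_matches_numeric_integration_oracle(self, frac):
        # disc area beyond a chord at distance a: circular segment formula
        R, a = 75.0, 75.0 * frac
        seg = R * R * math.acos(a / R) - a * math.sqrt(R * R - a * a)
        expected = math.pi * R * R / (math.pi * R * R - seg)
        got = edge_compensation(a, 1000.0, R, self.landscape)
        assert got == pytest.approx(expected, rel=2e-3)

    @pytest.mark.parametrize("frac", [0.0, 0.4, 0.9])
    def test_kernel_mass_variant_matches_dblquad(self, frac):
        R, a = 75.0, 75.0 * frac
        sig2 = 2.0 * (R / 3.0) ** 2

        def g(y, x):
            return math.exp(-(x * x + y * y) / sig2)

        full, _ = integrate.dblquad(
            g, -R, R, lambda x: -math.sqrt(R * R - x * x),
            lambda x: math.sqrt(R * R - x * x))
        inside, _ = integrate.dblquad(
            g, -a, R, lambda x: -math.sqrt(R * R - x * x),
            lambda x: math.sqrt(R * R - x * x))
        got = edge_compensation(a, 1000.0, R, self.landscape,
                                method="kernel_mass")
        assert got == pytest.approx(full / inside, rel=2e-3)


class TestAverageCompetition:
    def test_printed_formula_arithmetic(self):
        # sigma=25 m, D=0.001 / m^2, L=4 -> 2 pi 625 * 0.001 * 3
        p = ParameterSet(interaction_distance=75.0, density=1000.0,
                         litter_size=4.0)
        assert average_competition(p) == pytest.approx(11.78, abs=0.01)

    def test_zero_litter_and_density_limit(self):
        p = ParameterSet(density=1e-6, litter_size=0.0)
        assert average_competition(p) == pytest.approx(0.0, abs=1e-8)

    def test_monte_carlo_pairwise_oracle(self, defaults, rng):
        # mean summed kernel over a uniform population should match the
        # closed form within a few percent (edge effects excluded by
        # sampling targets away from the boundary)
        side = defaults.island_side_m
        n_adults = defaults.carrying_capacity
        n_total = int(n_adults * (1 + defaults.litter_size / 2))
        x = rng.uniform(0, side, n_total)
        y = rng.uniform(0, side, n_total)
        pop = Population(x, y, np.zeros(n_total), np.ones(n_total),
                         np.zeros(n_total, bool), np.zeros(n_total),
                         np.zeros(n_total))
        interior = np.flatnonzero(
            (x > 100) & (x < side - 100) & (y > 100) & (y < side - 100))
        comp = competition_totals(pop, defaults, interior[:3000])
        expected = average_competition(defaults)
        assert comp.mean() == pytest.approx(expected, rel=0.05)


class TestDensityTuning:
    def test_algebra_of_printed_recurrence(self):
        p = ParameterSet(survival_rate=0.9, migrant_frequency=0.1,
                         litter_size=4.0)
        s_d = (1 - (1 - 0.1) * 0.9) / (4 / 2 + 0.1)
        assert s_d == pytest.approx(0.0905, abs=1e-4)
        c = solve_density_tuning(p)
        assert c == pytest.approx(
            (0.9 - s_d) / average_competition(p, truncated=True), rel=1e-12)

    def test_recurrence_fixed_point(self):
        # iterating the recurrence with the solved s_d keeps N at K
        p = ParameterSet()
        s0, M, L = p.survival_rate, p.migrant_frequency, p.litter_size
        c = solve_density_tuning(p)
        s_d = s0 - c * average_competition(p, truncated=True)
        n = float(p.carrying_capacity)
        for _ in range(50):
            n = n * (1 - M) * s0 + n * (L / 2 + M) * s_d
        assert n == pytest.approx(p.carrying_capacity, rel=1e-9)

    def test_infeasible_parameters_raise(self):
        p = ParameterSet(survival_rate=0.2, litter_size=2.0,
                         migrant_frequency=0.0)
        with pytest.raises(CalibrationError):
            solve_density_tuning(p)


class TestMateChoice:
    def test_single_candidate_in_range(self, rng):
        idx = select_mate((0.0, 0.0), np.array([74.9]), np.array([0.0]),
                          75.0, rng)
        assert idx == 0

    def test_no_male_within_radius(self, rng):
        idx = select_mate((0.0, 0.0), np.array([80.0]), np.array([0.0]),
                          75.0, rng)
        assert idx == -1

    def test_equidistant_males_chosen_uniformly(self, defaults, rng):
        # three males 50 m from the female; 30000 vectorized searches
        fx = np.full(30000, 500.0)
        fy = np.full(30000, 500.0)
        mx = np.array([550.0, 450.0, 500.0])
        my = np.array([500.0, 500.0, 550.0])
        chosen = find_mates(fx, fy, mx, my, defaults, rng)
        counts = np.bincount(chosen, minlength=3)
        _, pvalue = stats.chisquare(counts)
        assert pvalue > 1e-4


class TestDisperse:
    landscape = Landscape(100000.0)

    def test_zero_mean_distance_stays_put(self, rng):
        x, y = disperse(50.0, 60.0, 0.0, self.landscape, rng)
        assert x[0] == 50.0 and y[0] == 60.0

    def test_mean_displacement_matches_exponential(self, rng):
        n = 100000
        x, y = disperse(np.full(n, 50000.0), np.full(n, 50000.0), 250.0,
                        self.landscape, rng)
        d = np.hypot(x - 50000.0, y - 50000.0)
        assert d.mean() == pytest.approx(250.0, rel=0.02)

    def test_corner_origin_respects_bounds(self, rng):
        small = Landscape(1000.0)
        x, y = disperse(np.zeros(5000), np.zeros(5000), 400.0, small, rng)
        assert np.all((x >= 0) & (x <= 1000) & (y >= 0) & (y <= 1000))


def _uniform_population(params, n, rng, age=1):
    side = params.island_side_m
    return Population(rng.uniform(0, side, n), rng.uniform(0, side, n),
                      (rng.random(n) < 0.5).astype(np.int8),
                      np.full(n, age, np.int32), np.zeros(n, bool),
                      np.zeros(n, np.int8), np.zeros(n, np.int8))


class TestMigration:
    def test_zero_frequency_moves_nobody(self, small_params, rng):
        pop = _uniform_population(small_params, 200, rng)
        x0 = pop.x.copy()
        migration_step(pop, ParameterSet(**{**small_params.to_dict(),
                                            "migrant_frequency": 0.0}), rng)
        assert np.array_equal(pop.x, x0)
        assert not pop.migrant.any()

    def test_full_frequency_moves_all_adults(self, small_params, rng):
        pop = _uniform_population(small_params, 200, rng)
        pop.age[:50] = 0  # juveniles never migrate
        p = ParameterSet(**{**small_params.to_dict(), "migrant_frequency": 1.0})
        x0 = pop.x.copy()
        migration_step(pop, p, rng)
        assert pop.migrant[50:].all()
        assert not pop.migrant[:50].any()
        assert np.array_equal(pop.x[:50], x0[:50])

    def test_migrant_count_binomially_distributed(self, small_params, rng):
        n = 10000
        pop = _uniform_population(small_params, n, rng)
        migration_step(pop, small_params, rng)
        count = int(pop.migrant.sum())
        se = math.sqrt(n * 0.1 * 0.9)
        assert abs(count - 0.1 * n) < 4 * se


class TestSurvival:
    def test_lone_adult_has_flat_rate(self, defaults):
        pop = Population(np.array([1000.0]), np.array([1000.0]),
                         np.array([1]), np.array([5]), np.array([False]),
                         np.array([0]), np.array([0]))
        p = survival_probabilities(pop, solve_density_tuning(defaults),
                                   defaults)
        assert p[0] == defaults.survival_rate

    def test_isolated_newborn_keeps_flat_rate(self, defaults):
        pop = Population(np.array([1000.0]), np.array([1000.0]),
                         np.array([0]), np.array([0]), np.array([False]),
                         np.array([0]), np.array([0]))
        p = survival_probabilities(pop, solve_density_tuning(defaults),
                                   defaults)
        assert p[0] == pytest.approx(defaults.survival_rate)

    def test_dense_cluster_clamps_to_zero(self, defaults):
        n = 300  # stacked at one point: competition far exceeds s0 / c
        pop = Population(np.full(n, 1000.0), np.full(n, 1000.0),
                         np.zeros(n), np.zeros(n), np.zeros(n, bool),
                         np.zeros(n), np.zeros(n))
        p = survival_probabilities(pop, solve_density_tuning(defaults),
                                   defaults)
        assert np.all(p == 0.0)

    def test_migrant_flags_cleared_after_survival(self, defaults, rng):
        pop = _uniform_population(defaults, 500, rng)
        pop.migrant[:] = True
        survival_step(pop, solve_density_tuning(defaults), defaults, rng)
        assert not pop.migrant.any()


class TestBruteForceEquality:
    def test_cell_list_matches_exhaustive_pairwise_loop(self, defaults, rng):
        """Optimized competition equals an O(N^2) scan bitwise (N = 500)."""
        n = 500
        pop = _uniform_population(defaults, n, rng)
        optimized = competition_totals(pop, defaults)
        R = defaults.interaction_distance
        two_sig2 = 2.0 * defaults.sigma * defaults.sigma
        for i in range(n):
            total = 0.0
            for j in range(n):
                if j == i:
                    continue
                dx = pop.x[i] - pop.x[j]
                dy = pop.y[i] - pop.y[j]
                d2 = dx * dx + dy * dy
                if d2 <= R * R:
                    total += math.exp(-d2 / two_sig2)
            assert optimized[i] == total
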