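import numpy as np
import pytest

from torsionfold.errors import DomainError
from torsionfold.optimizer import (JSOAConfig, OptimizerConfig,
                                   SpiderPopulation, bioperturbation,
                                   build_cooling_schedule,
                                   iterations_for_alpha, jsoa_strategy_update,
                                   low_pheromone_update, metropolis_accept,
                                   minimize, pheromone_rates,
                                   regression_slope)


class Quadratic:
    """Separable quadratic with known global minimum 0 at the origin."""

    supports_batch = True

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return float(np.dot(x, x))
        return np.einsum("ij,ij->i", x, x)


class TestCoolingSchedule:
    def test_halvings(self):
        assert iterations_for_alpha(8, 1, 0.5) == 3

    def test_direct_evaluation(self):
        # ceil(ln 100 / ln(1/0.9)) = ceil(4.60517 / 0.10536) = 44
        assert iterations_for_alpha(100, 1, 0.9) == 44

    def test_equal_temperatures_need_no_iterations(self):
        assert iterations_for_alpha(5, 5, 0.7) == 0

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            iterations_for_alpha(10, 1, 1.5)

    def test_iteration_count_nondecreasing_in_alpha(self):
        alphas = np.linspace(0.05, 0.95, 19)
        counts = [iterations_for_alpha(100, 1, a) for a in alphas]
        assert counts == sorted(counts)

    def test_five_sections_with_stepped_alphas(self):
        cs = build_cooling_schedule(1000, 1, alpha0=0.75, alpha_step=0.05,
                                    alpha_max=0.95)
        assert [round(a, 2) for *_, a in cs.sections] == [0.75, 0.80, 0.85, 0.90, 0.95]
        assert all(0.70 <= a <= 0.95 for *_, a in cs.sections)

    def test_golden_section_boundaries(self):
        cs = build_cooling_schedule(1000, 1)
        assert cs.sections[1][0] == pytest.approx(618.0)
        for s in range(len(cs.sections) - 1):
            assert cs.sections[s + 1][0] == pytest.approx(0.618 * cs.sections[s][0])
        assert cs.sections[-1][1] == 1.0

    def test_inverted_range_rejected(self):
        with pytest.raises(DomainError):
            build_cooling_schedule(1, 10)

    def test_ladder_temperatures_strictly_decreasing(self):
        temps = [t for t, _ in build_cooling_schedule(100, 0.1).temperature_ladder()]
        assert all(b < a for a, b in zip(temps, temps[1:]))
        assert all(t >= 0.1 for t in temps)


class TestStopCriterion:
    def test_constant_series_has_zero_slope(self):
        assert regression_slope([4.2] * 5) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_fit(self):
        e = [2 * i + 1 for i in range(1, 6)]
        assert regression_slope(e) == pytest.approx(2.0)

    def test_as_printed_formula_on_constant_tail(self):
        # literal simplified formula: (12*14 - 6*4*4) / 120 = 0.6
        assert regression_slope([9.0, 1, 1, 1, 1], mode="as_printed") == pytest.approx(0.6)

    def test_corrected_matches_closed_form_least_squares(self, rng):
        """Oracle: closed-form covariance/variance slope on random series."""
        for _ in range(200):
            k = int(rng.integers(2, 9))
            e = rng.normal(0, 50, k)
            i = np.arange(1, k + 1)
            oracle = np.sum((i - i.mean()) * (e - e.mean())) / np.sum((i - i.mean()) ** 2)
            assert regression_slope(e) == pytest.approx(oracle, abs=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(DomainError):
            regression_slope([1.0])


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1.0, t, rng) for t in (1e-6, 1.0, 1e6))

    def test_huge_uphill_rejected_at_low_temperature(self, rng):
        assert not any(metropolis_accept(1e6, 1e-3, rng) for _ in range(100))

    def test_empirical_acceptance_at_half_probability(self):
        rng = np.random.default_rng(2024)
        n = 100_000
        t = 1.7
        d_e = t * np.log(2.0)  # analytic acceptance probability 0.5
        hits = sum(metropolis_accept(d_e, t, rng) for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert hits / n == pytest.approx(0.5, abs=3 * se)

    def test_as_printed_mode_inverts_probability(self):
        rng = np.random.default_rng(7)
        n = 20_000
        t, d_e = 1.0, 2.0  # exp(-2) ~ 0.135
        hits = sum(metropolis_accept(d_e, t, rng, mode="as_printed")
                   for _ in range(n))
        assert hits / n == pytest.approx(1 - np.exp(-2.0), abs=0.02)

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(DomainError):
            metropolis_accept(1.0, 0.0, rng)


class TestSpiderStrategies:
    def setup_method(self):
        self.cfg = JSOAConfig()

    def _pop(self, agents, fitness):
        return SpiderPopulation(np.asarray(agents, float), np.asarray(fitness, float))

    def test_persecution_halves_the_difference(self, rng):
        pop = self._pop([[4.0], [2.0]], [1.0, 0.0])
        new = jsoa_strategy_update("persecution", 0, pop, self.cfg, rng, r=1)
        assert new[0] == pytest.approx(1.0)

    def test_jump_projectile_update(self, rng):
        # x tan(a) - x^2 g / (2 V0^2 cos^2 a), a = 0.5 pi/180, V0=100, g=9.80665
        pop = self._pop([[1.0], [0.0]], [1.0, 0.0])
        new = jsoa_strategy_update("jump", 0, pop, self.cfg, rng, phi=0.5)
        assert new[0] == pytest.approx(0.0082365, abs=1e-6)

    def test_local_with_zero_walk_returns_best(self, rng):
        pop = self._pop([[30.0], [-10.0]], [5.0, 1.0])
        new = jsoa_strategy_update("local", 0, pop, self.cfg, rng, walk=0.0)
        assert new[0] == pytest.approx(-10.0)

    def test_global_with_zero_lambda_returns_best(self, rng):
        pop = self._pop([[30.0], [-10.0]], [5.0, 1.0])
        new = jsoa_strategy_update("global", 0, pop, self.cfg, rng, lam=0.0)
        assert new[0] == pytest.approx(-10.0)

    def test_results_are_wrapped_into_bounds(self, rng):
        pop = self._pop([[170.0], [-170.0]], [1.0, 0.0])
        new = jsoa_strategy_update("global", 0, pop, self.cfg, rng, lam=100.0)
        assert -180.0 <= new[0] < 180.0


class TestPheromone:
    def test_minmax_normalization(self):
        pop = SpiderPopulation(np.zeros((3, 1)), np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(pheromone_rates(pop), [1.0, 0.5, 0.0])

    def test_equal_fitness_degenerates_to_ones(self):
        pop = SpiderPopulation(np.zeros((3, 1)), np.full(3, 7.0))
        np.testing.assert_allclose(pheromone_rates(pop), 1.0)

    def test_rates_always_in_unit_interval(self, rng):
        pop = SpiderPopulation(np.zeros((8, 2)), rng.normal(0, 100, 8))
        r = pheromone_rates(pop)
        assert np.all(r >= 0) and np.all(r <= 1)

    @pytest.mark.parametrize("sigma,expected", [(0, -1.0), (1, 3.0)])
    def test_replacement_formula(self, sigma, expected):
        class PinnedRng:
            def choice(self, n, size, replace):
                return np.array([1, 2])

            def integers(self, n):
                return sigma

        pop = SpiderPopulation(np.array([[0.0], [2.0], [4.0]]),
                               np.array([0.0, 5.0, 10.0]))
        agents, replaced = low_pheromone_update(pop, JSOAConfig(), PinnedRng())
        assert list(replaced) == [False, False, True]
        assert agents[2, 0] == pytest.approx(expected)
        assert agents[1, 0] == 2.0  # rate 0.5 > threshold: untouched

    def test_small_population_rejected(self, rng):
        pop = SpiderPopulation(np.zeros((2, 1)), np.array([0.0, 1.0]))
        with pytest.raises(DomainError):
            low_pheromone_update(pop, JSOAConfig(), rng)


class TestBioperturbation:
    def test_seeded_determinism(self):
        quad = Quadratic()
        cfg = JSOAConfig(max_iter=5)
        a, fa = bioperturbation(np.full(4, 50.0), quad,
                                cfg, np.random.default_rng(3))
        b, fb = bioperturbation(np.full(4, 50.0), quad,
                                cfg, np.random.default_rng(3))
        assert np.array_equal(a, b) and fa == fb

    def test_never_worse_than_initial_population_best(self, rng):
        quad = Quadratic()
        x0 = np.full(6, 120.0)
        _, f = bioperturbation(x0, quad, JSOAConfig(max_iter=3), rng)
        assert f <= quad(x0)

    def test_output_dimension_preserved(self, rng):
        x, _ = bioperturbation(np.zeros(7), Quadratic(), JSOAConfig(max_iter=2), rng)
        assert x.shape == (7,)


class TestMinimize:
    def test_quadratic_recovery_and_trace_contracts(self):
        res = minimize(Quadratic(),
                       np.random.default_rng(1).uniform(-180, 180, 5),
                       OptimizerConfig(seed=1))
        assert res.best_energy < 1e-2
        temps = [t for _, t, _ in res.trace]
        assert all(b < a for a, b in zip(temps, temps[1:]))
        best = [e for *_, e in res.trace]
        assert all(b <= a for a, b in zip(best, best[1:]))
        assert res.best_energy <= res.initial_energy
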