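"""Prairie-dog optimizer contracts: Tent map, t-mutation, minimize, compare."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from affwdi import benchmarks as B
from affwdi.pdo import (OptimizerConfig, compare_variants, comparison_frame,
                        minimize, t_perturbation, tent_sequence)


def _sphere(x):
    return float(np.sum(x * x))


class TestTentSequence:
    def test_map_definition_below_and_above_alpha(self):
        seq = tent_sequence(1, 3, x0=0.3, alpha=0.5).ravel()
        assert seq[0] == pytest.approx(0.3)
        assert seq[1] == pytest.approx(0.6)    # 0.3 / 0.5
        assert seq[2] == pytest.approx(0.8)    # (1 - 0.6) / (1 - 0.5)

    def test_matrix_stays_inside_unit_interval_without_stalling(self):
        m = tent_sequence(30, 30, x0=0.37).ravel()
        assert np.all((m > 0) & (m < 1))
        run = max_run = 1
        for a, b in zip(m, m[1:]):
            run = run + 1 if abs(a - b) < 1e-12 else 1
            max_run = max(max_run, run)
        assert max_run <= 10

    def test_degenerate_rational_seed_escapes_via_jitter(self):
        # 0.5 maps to 1.0, a fixed point of collapse without the jitter
        m = tent_sequence(1, 50, x0=0.25, alpha=0.5).ravel()
        assert np.all((m > 0) & (m < 1))

    @pytest.mark.parametrize("x0", [0.0, 1.0, -0.2, 1.3])
    def test_rejects_seed_outside_unit_interval(self, x0):
        with pytest.raises(ValueError):
            tent_sequence(2, 2, x0=x0)

    @given(x0=st.floats(0.01, 0.99), alpha=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_orbit_confined_to_open_unit_interval(self, x0, alpha):
        m = tent_sequence(4, 8, x0=x0, alpha=alpha).ravel()
        assert np.all((m > 0) & (m < 1))


class TestTPerturbation:
    def test_zero_probability_is_a_noop(self):
        rng = np.random.default_rng(0)
        x = np.array([1.0, -2.0, 3.0])
        out = t_perturbation(x, 3.0, rng, mutation_probability=0.0)
        np.testing.assert_array_equal(out, x)

    def test_zero_vector_is_a_fixed_point_of_multiplicative_mutation(self):
        rng = np.random.default_rng(0)
        out = t_perturbation(np.zeros(5), 1.0, rng, mutation_probability=1.0)
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_low_df_draws_are_heavier_tailed_than_gaussian(self):
        rng = np.random.default_rng(123)
        t_draws = rng.standard_t(3, 100_000)
        n_draws = rng.standard_normal(100_000)
        assert sps.kurtosis(t_draws) > sps.kurtosis(n_draws) + 1.0

    def test_rejects_non_finite_position_and_low_df(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="finite"):
            t_perturbation(np.array([np.nan, 1.0]), 3.0, rng)
        with pytest.raises(ValueError, match="degrees_of_freedom"):
            t_perturbation(np.ones(2), 0.5, rng)

    def test_result_respects_bounds(self):
        rng = np.random.default_rng(5)
        lo, hi = np.full(10, -1.0), np.full(10, 1.0)
        x = rng.uniform(-1, 1, 10)
        for _ in range(50):
            out = t_perturbation(x, 1.0, rng, 1.0, lo, hi)
            assert np.all(out >= lo) and np.all(out <= hi)


class TestMinimize:
    def _cfg(self, variant, seed=0, dim=2, span=100.0, **kw):
        return OptimizerConfig(dimension=dim, lower_bounds=-span,
                               upper_bounds=span, seed=seed, variant=variant,
                               **kw)

    @pytest.mark.parametrize("variant", ["pdo", "ipdo"])
    def test_constant_objective_returns_the_constant(self, variant):
        res = minimize(lambda x: 7.0, self._cfg(variant, max_iterations=20))
        assert res.best_fitness == 7.0
        assert np.all(res.convergence_trace == 7.0)

    @pytest.mark.parametrize("variant", ["pdo", "ipdo"])
    def test_sphere_2d_converges_below_threshold(self, variant):
        for seed in range(5):
            res = minimize(_sphere, self._cfg(variant, seed=seed))
            assert res.best_fitness < 1e-2

    def test_rastrigin_2d_ipdo_median_below_one(self):
        finals = []
        for seed in range(10):
            cfg = OptimizerConfig(dimension=2, lower_bounds=-5.12,
                                  upper_bounds=5.12, seed=seed, variant="ipdo")
            finals.append(minimize(
                lambda x: float(np.sum(x * x - 10 * np.cos(2 * np.pi * x) + 10)),
                cfg).best_fitness)
        assert np.median(finals) < 1.0

    @pytest.mark.parametrize("variant", ["pdo", "ipdo"])
    def test_trace_is_monotone_and_positions_in_bounds(self, variant):
        fn = B.get_function("ackley")
        cfg = OptimizerConfig.for_function(fn, seed=3, variant=variant,
                                           max_iterations=60)
        res = minimize(lambda x: fn(x), cfg)
        assert np.all(np.diff(res.convergence_trace) <= 1e-15)
        assert res.best_fitness == res.convergence_trace[-1]
        assert np.all(res.best_position >= fn.lower - 1e-12)
        assert np.all(res.best_position <= fn.upper + 1e-12)

    @pytest.mark.parametrize("variant", ["pdo", "ipdo"])
    def test_fixed_seed_gives_bit_identical_results(self, variant):
        cfg = self._cfg(variant, seed=9, max_iterations=40)
        r1 = minimize(_sphere, cfg)
        r2 = minimize(_sphere, cfg)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.convergence_trace, r2.convergence_trace)
        assert r1.evaluations_used == r2.evaluations_used

    def test_non_finite_objective_aborts_with_diagnostic(self):
        with pytest.raises(RuntimeError, match="non-finite"):
            minimize(lambda x: float("inf"), self._cfg("pdo", max_iterations=5))

    def test_target_fitness_terminates_early(self):
        cfg = self._cfg("ipdo", max_iterations=200, target_fitness=1e-4)
        res = minimize(_sphere, cfg)
        assert res.best_fitness <= 1e-4
        assert res.convergence_trace.size < 200

    def test_config_validation(self):
        with pytest.raises(ValueError, match="population_size"):
            OptimizerConfig(dimension=2, lower_bounds=0, upper_bounds=1,
                            population_size=1)
        with pytest.raises(ValueError, match="strictly below"):
            OptimizerConfig(dimension=2, lower_bounds=1, upper_bounds=1)
        with pytest.raises(ValueError, match="variant"):
            OptimizerConfig(dimension=2, lower_bounds=0, upper_bounds=1,
                            variant="cuckoo")


class TestCompareVariants:
    def test_mean_traces_have_full_length_and_matched_variants(self):
        fn = B.get_function("sphere")
        s = compare_variants(fn, repeats=2, base_seed=0, max_iterations=50)
        assert set(s.mean_trace) == {"pdo", "ipdo"}
        assert all(t.size == 50 for t in s.mean_trace.values())
        frame = comparison_frame(s)
        assert set(frame["variant"]) == {"pdo", "ipdo"}
        assert len(frame) == 100

    def test_repeated_invocation_is_deterministic(self):
        fn = B.get_function("quartic_noise")  # exercises the seeded noise path
        s1 = compare_variants(fn, repeats=2, base_seed=4, max_iterations=20)
        s2 = compare_variants(fn, repeats=2, base_seed=4, max_iterations=20)
        assert s1.mean_final == s2.mean_final
        for v in ("pdo", "ipdo"):
            np.testing.assert_array_equal(s1.mean_trace[v], s2.mean_trace[v])

    def test_rejects_single_repeat(self):
        with pytest.raises(ValueError, match="repeats"):
            compare_variants(B.get_function("sphere"), repeats=1, base_seed=0)
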