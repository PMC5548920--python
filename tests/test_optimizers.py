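"""Latin-hypercube sampling, damped least squares, Powell, GLSDC, traces."""

import numpy as np
import pytest

import relfit as rf
from relfit.exceptions import ConfigurationError, InputError
from relfit.objectives import EvaluationCounter
from relfit.optimizers import (
    OptimizerConfig,
    RunTrace,
    convergence_summary,
    glsdc_run,
    latin_hypercube_sample,
    levmar_minimize,
    powell_search,
)


class TestLatinHypercube:
    def test_one_sample_per_log_stratum(self):
        bounds = [(1e-2, 1e2), (1e-3, 1e3)]
        n = 4
        pts = latin_hypercube_sample(bounds, n, seed=0)
        assert pts.shape == (4, 2)
        for d, (lo, hi) in enumerate(bounds):
            z = (np.log10(pts[:, d]) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
            strata = np.floor(z * n).astype(int)
            assert sorted(strata) == [0, 1, 2, 3]

    def test_single_point_inside_box(self):
        pts = latin_hypercube_sample([(0.1, 10.0)], 1, seed=3)
        assert 0.1 <= pts[0, 0] <= 10.0

    def test_seed_determinism(self):
        a = latin_hypercube_sample([(0.1, 10.0)] * 3, 8, seed=42)
        b = latin_hypercube_sample([(0.1, 10.0)] * 3, 8, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            latin_hypercube_sample([(-1.0, 1.0)], 4, seed=0)


def _counted(fn, counter):
    def wrapped(x):
        counter.count_objective()
        return fn(x)
    return wrapped


class TestLevmarMinimize:
    def test_linear_least_squares_oracle(self):
        """Full-rank linear residuals converge to the normal-equations solution."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=(12, 4))
        b = rng.normal(size=12)
        x_star = np.linalg.solve(a.T @ a, a.T @ b)
        counter = EvaluationCounter()
        res = levmar_minimize(
            _counted(lambda x: a @ x - b, counter),
            lambda x: a,
            np.zeros(4),
            OptimizerConfig(max_iter=100),
            counter=counter,
        )
        np.testing.assert_allclose(res.best_x, x_star, atol=1e-8)

    def test_rosenbrock_as_residuals(self):
        counter = EvaluationCounter()

        def r(x):
            counter.count_objective()
            return np.array([10 * (x[1] - x[0] ** 2), 1 - x[0]])

        def jac(x):
            return np.array([[-20 * x[0], 10.0], [-1.0, 0.0]])

        res = levmar_minimize(r, jac, np.array([-1.2, 1.0]),
                              OptimizerConfig(max_iter=200), counter=counter)
        np.testing.assert_allclose(res.best_x, [1.0, 1.0], atol=1e-6)

    def test_stationary_start_terminates_quickly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 3))
        x_star = np.array([0.5, -1.0, 2.0])
        b = a @ x_star
        counter = EvaluationCounter()
        res = levmar_minimize(
            _counted(lambda x: a @ x - b, counter), lambda x: a, x_star,
            OptimizerConfig(max_iter=100), counter=counter,
        )
        assert res.termination_reason in ("ftol", "xtol")
        assert res.n_iterations <= 2
        assert res.best_objective < 1e-20

    def test_result_objective_consistent_with_best_x(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=8)
        counter = EvaluationCounter()
        res = levmar_minimize(
            _counted(lambda x: a @ x - b, counter), lambda x: a, np.zeros(3),
            OptimizerConfig(), counter=counter,
        )
        r = a @ res.best_x - b
        assert res.best_objective == pytest.approx(float(r @ r), abs=1e-10)

    def test_trace_monotone_best(self):
        counter = EvaluationCounter()

        def r(x):
            counter.count_objective()
            return np.array([10 * (x[1] - x[0] ** 2), 1 - x[0]])

        res = levmar_minimize(
            r, lambda x: np.array([[-20 * x[0], 10.0], [-1.0, 0.0]]),
            np.array([-1.2, 1.0]), OptimizerConfig(max_iter=200), counter=counter,
        )
        best = [rec["best_objective_so_far"] for rec in res.trace.records]
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(best, best[1:]))


class TestPowell:
    def test_quadratic_minimum(self):
        x, f = powell_search(lambda x: (x[0] - 3.0) ** 2, np.array([0.0]), tol=1e-10)
        assert x[0] == pytest.approx(3.0, abs=1e-6)

    def test_idempotent_at_optimum(self):
        x, f = powell_search(lambda x: (x[0] - 3.0) ** 2, np.array([3.0]), tol=1e-10)
        assert x[0] == pytest.approx(3.0, abs=1e-8)
        assert f <= 1e-16

    def test_separable_quadratic_recovers_both_coordinates(self):
        x, f = powell_search(
            lambda x: (x[0] - 1.0) ** 2 + 4 * (x[1] + 2.0) ** 2,
            np.array([5.0, 5.0]), tol=1e-12,
        )
        np.testing.assert_allclose(x, [1.0, -2.0], atol=1e-6)


class TestGlsdc:
    def test_double_well_finds_global_minimum(self):
        """f = (x^2-1)^2 + 0.1 x has its global minimum near x = -1."""

        def f(x):
            return float((x[0] ** 2 - 1) ** 2 + 0.1 * x[0])

        grid = np.linspace(-2, 2, 200001)
        fg = (grid**2 - 1) ** 2 + 0.1 * grid
        x_global = grid[np.argmin(fg)]
        assert x_global < 0  # oracle: the deeper well is on the negative side

        cfg = OptimizerConfig(algorithm="glsdc", max_evals=2000, seed=5,
                              population_size=20, max_seconds=60)
        res = glsdc_run(f, [(-2.0, 2.0)], cfg)
        assert res.best_x[0] == pytest.approx(x_global, abs=1e-3)

    def test_convex_quadratic_matches_powell(self):
        def f(x):
            return float((x[0] - 0.7) ** 2 + (x[1] + 0.2) ** 2)

        cfg = OptimizerConfig(algorithm="glsdc", max_evals=3000, seed=1,
                              population_size=12, max_seconds=60)
        res = glsdc_run(f, [(-2.0, 2.0), (-2.0, 2.0)], cfg)
        xp, fp = powell_search(f, np.array([0.0, 0.0]), tol=1e-12)
        assert res.best_objective <= fp + 1e-6

    def test_trace_counts_actual_invocations(self):
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            return float(x @ x)

        cfg = OptimizerConfig(algorithm="glsdc", max_evals=500, seed=2,
                              population_size=10, max_seconds=60)
        res = glsdc_run(f, [(-1.0, 1.0)] * 2, cfg)
        assert res.counter.objective_calls == calls["n"]
        assert len(res.trace) == calls["n"]

    def test_seed_determinism(self):
        def f(x):
            return float((x[0] ** 2 - 1) ** 2 + 0.1 * x[0])

        cfg = OptimizerConfig(algorithm="glsdc", max_evals=800, seed=9,
                              population_size=10, max_seconds=60)
        a = glsdc_run(f, [(-2.0, 2.0)], cfg)
        b = glsdc_run(f, [(-2.0, 2.0)], cfg)
        assert a.best_objective == b.best_objective
        np.testing.assert_array_equal(a.best_x, b.best_x)

    def test_small_population_rejected(self):
        cfg = OptimizerConfig(algorithm="glsdc", population_size=3)
        with pytest.raises(ConfigurationError):
            glsdc_run(lambda x: 0.0, [(-1.0, 1.0)], cfg)


class TestConvergenceSummary:
    def _trace(self, values, dt=1.0):
        tr = RunTrace()
        for i, v in enumerate(values):
            tr.record(dt * (i + 1), i + 1, i + 1, v)
        return tr

    def test_constant_traces_median(self):
        traces = [self._trace([1.0]), self._trace([2.0]), self._trace([3.0])]
        df = convergence_summary(traces, [0.5, 10.0])
        assert df["median"].tolist() == [2.0, 2.0]

    def test_single_trace_percentiles_collapse(self):
        df = convergence_summary([self._trace([5.0, 4.0, 3.0])], [2.5])
        assert df.loc[0, "q25"] == df.loc[0, "median"] == df.loc[0, "q75"] == 4.0

    def test_cutoff_before_first_record_uses_first_value(self):
        df = convergence_summary([self._trace([7.0, 1.0])], [0.1])
        assert df.loc[0, "median"] == 7.0

    def test_short_trace_contributes_final_value(self):
        traces = [self._trace([5.0, 1.0]), self._trace([3.0])]
        df = convergence_summary(traces, [100.0])
        assert df.loc[0, "median"] == pytest.approx(2.0)

    def test_empty_trace_list_rejected(self):
        with pytest.raises(InputError):
            convergence_summary([], [1.0])


class TestMultistart:
    def test_single_start_equals_plain_levmar(self, styx_problem):
        problem, _ = styx_problem
        spec = rf.ObjectiveSpec("dns", "ls")
        cfg = OptimizerConfig(algorithm="levmar_se", n_starts=1, seed=3,
                              max_iter=40, max_seconds=120)
        ens1, _ = rf.multistart_levmar(problem, spec, cfg)
        ens2, _ = rf.multistart_levmar(problem, spec, cfg)
        assert ens1.n_runs == 1
        np.testing.assert_array_equal(ens1.estimates, ens2.estimates)

    def test_ensemble_metadata_and_shapes(self, styx_problem):
        problem, _ = styx_problem
        spec = rf.ObjectiveSpec("dns", "ls")
        cfg = OptimizerConfig(algorithm="levmar_fd", n_starts=2, seed=3,
                              max_iter=15, max_seconds=120)
        ens, trace = rf.multistart_levmar(problem, spec, cfg)
        assert ens.estimates.shape == (2, 10)
        assert ens.metadata["algorithm"] == "levmar_fd"
        assert len(trace) > 0
        best = [rec["best_objective_so_far"] for rec in trace.records]
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(best, best[1:]))
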