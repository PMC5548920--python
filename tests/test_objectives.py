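"""Free-vector assembly, residuals, LS/LL objectives, gradients, counters."""

import numpy as np
import pytest

import relfit as rf
from relfit.exceptions import ConfigurationError
from relfit.objectives import (
    ObjectiveAdapter,
    _predictions,
    assemble_free_vector,
    fd_gradient,
    se_jacobian,
)


def spec(scaling="dns", form="ls"):
    return rf.ObjectiveSpec(scaling, form)


class TestAssembleFreeVector:
    @pytest.mark.parametrize(
        "scaling,form,extra",
        [("dns", "ls", 0), ("sf", "ls", 8), ("dns", "ll", 2), ("sf", "ll", 10)],
    )
    def test_layout_lengths(self, egfhrg_problem, scaling, form, extra):
        """10 kinetic parameters, 8 observables: DNS-LS estimates 10, SF-LS
        10 + 8, and LL always adds the two error-model parameters."""
        problem, _ = egfhrg_problem
        fv = assemble_free_vector(problem, spec(scaling, form))
        assert len(fv) == 10 + extra

    def test_segment_order_and_names(self, egfhrg_problem):
        problem, _ = egfhrg_problem
        fv = assemble_free_vector(problem, spec("sf", "ll"))
        assert list(fv.names[:10]) == list(problem.free_names)
        assert all(n.startswith("alpha_") for n in fv.names[10:18])
        assert list(fv.names[18:]) == ["s_a", "s_b"]
        assert fv.layout["kinetic"] == slice(0, 10)

    def test_deterministic_assembly(self, egfhrg_problem):
        problem, _ = egfhrg_problem
        a = assemble_free_vector(problem, spec("sf", "ls"))
        b = assemble_free_vector(problem, spec("sf", "ls"))
        assert a.names == b.names
        np.testing.assert_array_equal(a.values, b.values)


class TestResiduals:
    def test_dns_zero_at_truth_despite_gains(self, styx_problem):
        """Arbitrary replicate gains cancel under shared normalisation."""
        problem, _ = styx_problem
        fv = assemble_free_vector(problem, spec("dns", "ls"))
        r = rf.residuals(fv, problem, spec("dns", "ls"))
        assert np.max(np.abs(r)) < 1e-10

    def test_ls_objective_zero_at_truth(self, styx_problem):
        problem, _ = styx_problem
        fv = assemble_free_vector(problem, spec("dns", "ls"))
        assert rf.objective_ls(fv, problem, spec("dns", "ls")) < 1e-12

    def test_sf_alpha_absorbs_normalisation_scale(self, styx_problem):
        """Normalised data equal y/mean(y); the exact scaling factor is
        1/mean of the simulated observable over the measured points."""
        problem, truth = styx_problem
        sp = spec("sf", "ls")
        fv = assemble_free_vector(problem, sp)
        ys = []
        for cond in problem.conditions:
            traj = rf.simulate(problem.model, truth.theta_true, cond,
                               problem.measurement_times(cond.name))
            ys.append(problem.output_map.values("obs1", traj.states, truth.theta_true))
        alpha_star = 1.0 / np.mean(np.concatenate(ys))
        vals = fv.values.copy()
        vals[fv.layout["scaling_factors"]] = alpha_star
        assert rf.objective_ls(fv.with_values(vals), problem, sp) < 1e-10

    def test_sf_residual_is_direct_subtraction(self, styx_problem):
        problem, _ = styx_problem
        sp = spec("sf", "ls")
        fv = assemble_free_vector(problem, sp)  # alpha = 1
        ytilde, mu, _ = _predictions(problem, sp, fv, with_sens=False)
        r = rf.residuals(fv, problem, sp)
        np.testing.assert_allclose(r, ytilde - mu, rtol=1e-12)


class TestObjectiveLL:
    def test_zero_residual_unit_sigma_contribution(self, styx_problem):
        problem, _ = styx_problem
        sp = spec("dns", "ll")
        fv = assemble_free_vector(problem, sp)
        vals = fv.values.copy()
        sl = fv.layout["error_model"]
        vals[sl] = [1.0, 1e-6]  # sigma ~ 1 everywhere
        ll = rf.objective_ll(fv.with_values(vals), problem, sp)
        # residuals ~0 at truth, ln(1) = 0; the s_b >= 1e-6 bound floor leaves
        # a sum of ~n * 1e-6 * |mu| in the log term
        assert abs(ll) < 1e-4

    def test_sb_zero_optimal_sa_is_rms(self):
        """With sigma = s_a, the ML value of s_a is the residual RMS."""
        r = np.array([0.5, -1.0, 2.0, 0.3])

        def nll(s_a):
            return float(np.sum(r**2 / (2 * s_a**2) + np.log(s_a)))

        grid = np.linspace(0.05, 5.0, 20000)
        s_grid = grid[np.argmin([nll(s) for s in grid])]
        assert s_grid == pytest.approx(np.sqrt(np.mean(r**2)), rel=1e-3)

    def test_ll_affine_in_ls_when_sigma_fixed(self, styx_problem):
        """With s_b = 0 and s_a fixed, NLL = LS/(2 s_a^2) + n ln s_a."""
        problem, _ = styx_problem
        sp_ll, sp_ls = spec("dns", "ll"), spec("dns", "ls")
        fv_ll = assemble_free_vector(problem, sp_ll)
        fv_ls = assemble_free_vector(problem, sp_ls)
        s_a = 0.37
        rng = np.random.default_rng(0)
        for _ in range(3):
            kin = fv_ls.values * np.exp(rng.normal(0, 0.1, fv_ls.values.size))
            vals_ll = np.concatenate([kin, [s_a, 1e-6]])
            ls = rf.objective_ls(fv_ls.with_values(kin), problem, sp_ls)
            ll = rf.objective_ll(fv_ll.with_values(vals_ll), problem, sp_ll)
            n = len(problem.dataset)
            assert ll == pytest.approx(ls / (2 * s_a**2) + n * np.log(s_a), rel=1e-4)


class TestFdGradient:
    def test_quadratic_gradient(self):
        g = fd_gradient(lambda x: float(x[0] ** 2), np.array([1.0]), h=1e-6)
        assert g[0] == pytest.approx(2.0, abs=1e-5)

    def test_costs_p_plus_one_calls(self):
        counter = rf.EvaluationCounter()
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            return float(x @ x)

        fd_gradient(f, np.zeros(2), counter=counter)
        assert calls["n"] == 3  # p + 1 for p = 2
        assert counter.objective_calls == 3
        assert counter.gradient_calls == 1

    def test_constant_function_zero_gradient(self):
        g = fd_gradient(lambda x: 1.0, np.array([0.3, -2.0, 5.0]))
        np.testing.assert_array_equal(g, np.zeros(3))


class TestSeJacobian:
    def test_matches_fd_jacobian_on_cascade(self, styx_problem):
        problem, _ = styx_problem
        sp = spec("dns", "ls")
        ad_se = ObjectiveAdapter(problem, sp, gradient="se")
        ad_fd = ObjectiveAdapter(problem, sp, gradient="fd", fd_step=1e-6)
        z = ad_se.z0 + 0.05
        j_se, j_fd = ad_se.jacobian_z(z), ad_fd.jacobian_z(z)
        denom = np.max(np.abs(j_fd))
        assert np.max(np.abs(j_se - j_fd)) / denom < 1e-4

    def test_sf_alpha_column_is_minus_y(self, styx_problem):
        problem, _ = styx_problem
        sp = spec("sf", "ls")
        fv = assemble_free_vector(problem, sp)
        jac = se_jacobian(fv, problem, sp)
        ytilde, mu, _ = _predictions(problem, sp, fv, with_sens=False)
        col = fv.layout["scaling_factors"].start
        # alpha = 1, so mu = y and d r / d alpha = -y (up to the solver
        # tolerance difference between the plain and the augmented run)
        np.testing.assert_allclose(jac[:, col], -mu, atol=1e-6)

    def test_counter_conventions(self, styx_problem):
        """SE gradient: 1 per-call objective call but p + 1 fd-equivalents."""
        problem, _ = styx_problem
        sp = spec("dns", "ls")
        counter = rf.EvaluationCounter()
        fv = assemble_free_vector(problem, sp)
        se_jacobian(fv, problem, sp, counter=counter)
        assert counter.objective_calls == 1
        assert counter.gradient_calls == 1
        assert counter.fd_equivalent_evals == len(fv) + 1


class TestAdapterCounters:
    def test_fd_jacobian_consumes_p_plus_one_objective_calls(self, styx_problem):
        problem, _ = styx_problem
        ad = ObjectiveAdapter(problem, spec("dns", "ls"), gradient="fd")
        before = ad.counter.objective_calls
        ad.jacobian_z(ad.z0)
        assert ad.counter.objective_calls - before == ad.p + 1
        assert ad.counter.fd_equivalent_evals == ad.counter.objective_calls

    def test_se_fd_equivalent_exceeds_per_call(self, styx_problem):
        problem, _ = styx_problem
        ad = ObjectiveAdapter(problem, spec("dns", "ls"), gradient="se")
        ad.residuals_z(ad.z0)
        ad.jacobian_z(ad.z0)
        assert ad.counter.objective_calls == 2  # 1 residual + 1 SE gradient
        assert ad.counter.fd_equivalent_evals == 1 + ad.p + 1
        assert ad.counter.elapsed_seconds > 0


class TestSfStationarity:
    def test_optimal_alpha_matches_closed_form(self, egfhrg_problem):
        """At fixed theta the SF-LS optimum is alpha_j = sum(y~ y)/sum(y^2)."""
        problem, _ = egfhrg_problem
        sp = spec("sf", "ls")
        fv = assemble_free_vector(problem, sp)
        ytilde, mu, _ = _predictions(problem, sp, fv, with_sens=False)  # alpha=1: mu=y
        ds = problem.dataset
        sl = fv.layout["scaling_factors"]
        for j, obs in enumerate(problem.output_map.names):
            idx = [i for i, p in enumerate(ds.points) if p.observable == obs]
            y, yt = mu[idx], ytilde[idx]
            closed = float(yt @ y / (y @ y))

            def ls_of_alpha(a):
                vals = fv.values.copy()
                vals[sl.start + j] = a
                return rf.objective_ls(fv.with_values(vals), problem, sp)

            grid = np.linspace(0.5 * closed, 1.5 * closed, 101)
            a_grid = grid[np.argmin([ls_of_alpha(a) for a in grid])]
            assert a_grid == pytest.approx(closed, rel=2e-2)
            # stationarity to high precision via golden-section refinement
            from scipy.optimize import minimize_scalar
            res = minimize_scalar(ls_of_alpha, bracket=(0.5 * closed, closed, 1.5 * closed),
                                  options={"xtol": 1e-12})
            assert res.x == pytest.approx(closed, abs=1e-6 * max(1, abs(closed)))


class TestPenalty:
    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            rf.ObjectiveSpec("bogus", "ls")

    def test_failed_simulation_yields_finite_penalty(self, styx_problem):
        problem, _ = styx_problem
        sp = spec("dns", "ls")
        fv = assemble_free_vector(problem, sp)
        vals = fv.values.copy()
        vals[:] = np.clip(vals * 1e3, fv.bounds[:, 0], fv.bounds[:, 1])  # extreme corner
        obj = rf.objective_ls(fv.with_values(vals), problem, sp)
        assert np.isfinite(obj)
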