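"""Objective functions for fitting ODE models to relative data.

Two scaling schemes map simulations onto arbitrary-unit data:

* DNS (data-driven normalisation of simulations): the measured data are
  normalised per (observable, replicate) group and the simulation is
  normalised by the *same* rule over the same (condition, time) points, so
  residuals r_i = y~_i - y_i / y_ref need no extra parameters.
* SF (scaling factors): one estimated multiplier alpha_j per observable
  converts simulation to data scale, r_i = y~_i - alpha_j * y_i.

Two objective forms:

* LS: sum of squared residuals.
* LL: negative Gaussian log-likelihood with a two-parameter error model
  sigma_i = s_a + s_b * |mu_i| (absolute plus proportional noise), where
  mu_i is the model prediction on the comparison scale.  s_a and s_b are
  estimated alongside the kinetic parameters.

The free-parameter vector is laid out as [kinetic | scaling factors (SF
only) | s_a, s_b (LL only)]; scaling factors and error parameters are
searched in log space with bounds [1e-6, 1e6].

Evaluation accounting implements both conventions that make gradient-method
comparisons treacherous: ``objective_calls`` counts actual objective
evaluations (a sensitivity-equation gradient is one call), while
``fd_equivalent_evals`` charges p + 1 per gradient regardless of how it was
obtained — the cost a finite-difference gradient would have had.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import NormalizationSpec, reference_value
from .exceptions import ConfigurationError, IntegrationError, NormalizationError
from .models import simulate, simulate_with_sensitivities
from .problem import OdeProblem

__all__ = [
    "ScalingFactorSet",
    "ErrorModel",
    "ObjectiveSpec",
    "FreeParameterVector",
    "EvaluationCounter",
    "assemble_free_vector",
    "residuals",
    "objective_ls",
    "objective_ll",
    "fd_gradient",
    "se_jacobian",
    "ObjectiveAdapter",
    "PENALTY",
]

#: finite penalty returned for infeasible parameter sets (failed integration
#: or non-positive simulated normalisation reference)
PENALTY = 1e10

#: bounds for log-space nuisance parameters (scaling factors, s_a, s_b)
NUISANCE_BOUNDS = (1e-6, 1e6)

#: shift making sqrt(2 ln sigma + C) real for sigma >= 1e-6 (LL-as-residuals)
LL_RESIDUAL_SHIFT = 60.0


@dataclass(frozen=True)
class ScalingFactorSet:
    """One positive multiplier per observable (SF scheme)."""

    alphas: dict[str, float]

    def __post_init__(self):
        for name, a in self.alphas.items():
            if not a > 0:
                raise ConfigurationError(f"scaling factor for {name!r} must be > 0")


@dataclass(frozen=True)
class ErrorModel:
    """Two-parameter measurement-noise model sigma = s_a + s_b * |mu|."""

    s_a: float
    s_b: float

    def __post_init__(self):
        if not self.s_a > 0:
            raise ConfigurationError("s_a must be > 0")
        if self.s_b < 0:
            raise ConfigurationError("s_b must be >= 0")

    def sigma(self, mu) -> np.ndarray:
        return self.s_a + self.s_b * np.abs(np.asarray(mu, dtype=float))


@dataclass(frozen=True)
class ObjectiveSpec:
    """Scaling scheme (dns | sf) crossed with objective form (ls | ll)."""

    scaling: str = "dns"
    form: str = "ls"

    def __post_init__(self):
        if self.scaling not in ("dns", "sf"):
            raise ConfigurationError(f"unknown scaling scheme {self.scaling!r}")
        if self.form not in ("ls", "ll"):
            raise ConfigurationError(f"unknown objective form {self.form!r}")


@dataclass(frozen=True)
class FreeParameterVector:
    """The assembled vector of estimated quantities with layout and bounds."""

    names: tuple[str, ...]
    values: np.ndarray
    bounds: np.ndarray  # (p, 2)
    layout: dict[str, slice]  # segment name -> slice into values

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "bounds", np.asarray(self.bounds, dtype=float))
        if self.values.shape[0] != len(self.names) or self.bounds.shape != (
            len(self.names),
            2,
        ):
            raise ConfigurationError("free-vector fields have inconsistent lengths")
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise ConfigurationError("free-vector value outside its bounds")

    def __len__(self) -> int:
        return self.values.shape[0]

    def segment(self, name: str) -> np.ndarray:
        return self.values[self.layout[name]]

    def with_values(self, values) -> "FreeParameterVector":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class EvaluationCounter:
    """Evaluation and time accounting under both counting conventions."""

    objective_calls: int = 0
    gradient_calls: int = 0
    fd_equivalent_evals: int = 0
    elapsed_seconds: float = 0.0

    def count_objective(self, n: int = 1) -> None:
        self.objective_calls += n
        self.fd_equivalent_evals += n

    def count_se_gradient(self, p: int) -> None:
        """A sensitivity-equation gradient: one actual call, but the
        fd-equivalent reconstruction charges p + 1."""
        self.gradient_calls += 1
        self.objective_calls += 1
        self.fd_equivalent_evals += p + 1

    def count_fd_gradient(self) -> None:
        """An FD gradient; its p + 1 objective calls are counted where they
        happen, this only tallies the gradient itself."""
        self.gradient_calls += 1

    def snapshot(self) -> dict:
        return {
            "objective_calls": self.objective_calls,
            "gradient_calls": self.gradient_calls,
            "fd_equivalent_evals": self.fd_equivalent_evals,
            "elapsed_seconds": self.elapsed_seconds,
        }


def assemble_free_vector(problem: OdeProblem, spec: ObjectiveSpec) -> FreeParameterVector:
    """Lay out the estimated quantities: kinetic, then one scaling factor per
    observable (SF only), then (s_a, s_b) (LL only); ordering follows the
    declaration order in the problem."""
    if problem.p_kinetic == 0:
        raise ConfigurationError("problem declares no free kinetic parameters")
    names: list[str] = list(problem.free_names)
    values = [float(problem.theta_nominal[problem.model.param_names.index(n)]) for n in names]
    bounds = [problem.bounds[n] for n in names]
    layout = {"kinetic": slice(0, len(names))}
    if spec.scaling == "sf":
        start = len(names)
        for obs in problem.output_map.names:
            names.append(f"alpha_{obs}")
            values.append(1.0)
            bounds.append(NUISANCE_BOUNDS)
        layout["scaling_factors"] = slice(start, len(names))
    if spec.form == "ll":
        start = len(names)
        names += ["s_a", "s_b"]
        values += [0.1, 0.1]
        bounds += [NUISANCE_BOUNDS, NUISANCE_BOUNDS]
        layout["error_model"] = slice(start, len(names))
    return FreeParameterVector(
        names=tuple(names),
        values=np.array(values),
        bounds=np.array(bounds),
        layout=layout,
    )


# ---------------------------------------------------------------------------
# prediction assembly


class _PenaltyEvaluation(Exception):
    """Internal marker: this parameter set is infeasible, use the penalty."""


def _simulate_measured(problem: OdeProblem, theta: np.ndarray, with_sens: bool):
    """Simulated observable values (and optionally their kinetic-parameter
    sensitivities) at every measured (condition, observable, time)."""
    sim: dict[tuple, float] = {}
    dsim: dict[tuple, np.ndarray] = {}
    free_index = problem.free_index
    observables = problem.dataset.observables
    for cond in problem.dataset.conditions:
        times = problem.measurement_times(cond)
        condition = problem.condition(cond)
        try:
            if with_sens:
                st = simulate_with_sensitivities(
                    problem.model, theta, condition, times, free_index,
                    rtol=problem.rtol, atol=problem.atol,
                )
                traj, sens = st.trajectory, st.sensitivities
            else:
                traj = simulate(
                    problem.model, theta, condition, times,
                    rtol=problem.rtol, atol=problem.atol,
                )
                sens = None
        except IntegrationError as exc:
            raise _PenaltyEvaluation() from exc
        theta_c, _, _ = problem.model.apply_condition(theta, condition)
        for obs in observables:
            y = problem.output_map.values(obs, traj.states, theta_c)
            for ti, t in enumerate(traj.times):
                key = (cond, obs, float(t))
                sim[key] = float(y[ti])
                if sens is not None:
                    x = traj.states[ti]
                    gx = problem.output_map.grad_state(obs, x, theta_c)
                    gp = problem.output_map.grad_params(obs, x, theta_c)[free_index]
                    dsim[key] = gx @ sens[ti] + gp
    return sim, (dsim if with_sens else None)


def _comparison_dataset(problem: OdeProblem, spec: ObjectiveSpec):
    """Both schemes fit the data on the scale its normalisation directive
    produces (scheme 'none' leaves it raw).  The schemes differ in how the
    *simulation* reaches that scale: DNS re-normalises it by its own
    reference each run, SF multiplies it by an estimated alpha per
    observable."""
    return problem.normalized_dataset()


def _group_sim_reference(values: np.ndarray, keys: list[tuple], spec: NormalizationSpec):
    """Reference of a group of simulated values plus the index set defining
    it (for sensitivity chain rule): ('mean', None) | ('point', pos)."""
    ctx = {}
    for pos, (cond, _obs, t) in enumerate(keys):
        ctx.setdefault((cond, t), pos)
    ref = reference_value(values, spec, ctx)
    if spec.scheme == "average":
        kind = ("mean", None)
    elif spec.scheme == "max":
        kind = ("point", int(np.argmax(values)))
    elif spec.scheme == "reference_point":
        sel = (spec.reference_selector[0], float(spec.reference_selector[1]))
        kind = ("point", ctx[sel])
    else:
        kind = ("none", None)
    return ref, kind


def _predictions(
    problem: OdeProblem,
    spec: ObjectiveSpec,
    free: FreeParameterVector,
    with_sens: bool,
):
    """Per-data-point model predictions mu_i on the comparison scale.

    Returns (ytilde, mu, dmu) where dmu (None unless with_sens) has one row
    per data point and one column per free-vector entry (error-model columns
    are zero: plain predictions do not depend on s_a, s_b).
    """
    ds = _comparison_dataset(problem, spec)
    theta = problem.theta_from_free(free.segment("kinetic"))
    sim, dsim = _simulate_measured(problem, theta, with_sens)
    n = len(ds.points)
    p_total = len(free)
    p_kin = problem.p_kinetic
    ytilde = ds.values()
    mu = np.empty(n)
    dmu = np.zeros((n, p_total)) if with_sens else None

    if spec.scaling == "dns":
        norm = ds.normalization
        for (_obs, _rep), idx in ds.groups().items():
            keys = [
                (ds.points[i].condition, ds.points[i].observable, float(ds.points[i].time))
                for i in idx
            ]
            y = np.array([sim[k] for k in keys])
            try:
                ref, kind = _group_sim_reference(y, keys, norm)
            except NormalizationError as exc:
                raise _PenaltyEvaluation() from exc
            mu[idx] = y / ref
            if with_sens:
                dy = np.stack([dsim[k] for k in keys])  # (m, p_kin)
                if kind[0] == "mean":
                    dref = dy.mean(axis=0)
                elif kind[0] == "point":
                    dref = dy[kind[1]]
                else:
                    dref = np.zeros(p_kin)
                block = (ref * dy - np.outer(y, dref)) / ref**2
                dmu[np.asarray(idx), :p_kin] = block
    else:  # sf
        alphas = free.segment("scaling_factors")
        obs_order = problem.output_map.names
        sl = free.layout["scaling_factors"]
        for i, p in enumerate(ds.points):
            key = (p.condition, p.observable, float(p.time))
            j = obs_order.index(p.observable)
            y = sim[key]
            mu[i] = alphas[j] * y
            if with_sens:
                dmu[i, :p_kin] = alphas[j] * dsim[key]
                dmu[i, sl.start + j] = y
    return ytilde, mu, dmu


# ---------------------------------------------------------------------------
# objectives


def residuals(
    free: FreeParameterVector, problem: OdeProblem, spec: ObjectiveSpec
) -> np.ndarray:
    """r_i = y~_i - mu_i in dataset order.

    An infeasible parameter set (failed integration, non-positive simulated
    reference) yields a constant penalty vector whose sum of squares is
    ``PENALTY`` — finite, so derivative-free optimisers can recover.
    """
    try:
        ytilde, mu, _ = _predictions(problem, spec, free, with_sens=False)
    except _PenaltyEvaluation:
        n = len(_comparison_dataset(problem, spec).points)
        return np.full(n, np.sqrt(PENALTY / n))
    return ytilde - mu


def objective_ls(
    free: FreeParameterVector, problem: OdeProblem, spec: ObjectiveSpec
) -> float:
    """Sum of squared residuals."""
    r = residuals(free, problem, spec)
    return float(r @ r)


def _sigma(free: FreeParameterVector, mu: np.ndarray) -> np.ndarray:
    s_a, s_b = free.segment("error_model")
    return s_a + s_b * np.abs(mu)


def objective_ll(
    free: FreeParameterVector, problem: OdeProblem, spec: ObjectiveSpec
) -> float:
    """Negative Gaussian log-likelihood, additive constant dropped:
    sum_i [ (y~_i - mu_i)^2 / (2 sigma_i^2) + ln sigma_i ],
    sigma_i = s_a + s_b |mu_i|."""
    if spec.form != "ll":
        raise ConfigurationError("objective_ll requires an LL objective spec")
    try:
        ytilde, mu, _ = _predictions(problem, spec, free, with_sens=False)
    except _PenaltyEvaluation:
        return PENALTY
    sig = _sigma(free, mu)
    if np.any(sig <= 0):
        return PENALTY
    r = ytilde - mu
    return float(np.sum(r**2 / (2 * sig**2) + np.log(sig)))


def fd_gradient(objective, x, h: float = 1e-6, counter: EvaluationCounter | None = None):
    """Forward-difference gradient: (f(x + h_k e_k) - f(x)) / h_k with
    h_k = h * max(|x_k|, 1).  Consumes exactly p + 1 objective calls."""
    x = np.asarray(x, dtype=float)
    f0 = objective(x)
    if counter is not None:
        counter.count_objective()
    if not np.isfinite(f0):
        warnings.warn("objective non-finite at expansion point; penalty used")
        f0 = PENALTY
    g = np.empty_like(x)
    for k in range(x.size):
        hk = h * max(abs(x[k]), 1.0)
        xk = x.copy()
        xk[k] += hk
        fk = objective(xk)
        if counter is not None:
            counter.count_objective()
        if not np.isfinite(fk):
            warnings.warn("objective non-finite at FD probe point; penalty used")
            fk = PENALTY
        g[k] = (fk - f0) / hk
    if counter is not None:
        counter.count_fd_gradient()
    return g


def se_jacobian(
    free: FreeParameterVector,
    problem: OdeProblem,
    spec: ObjectiveSpec,
    counter: EvaluationCounter | None = None,
) -> np.ndarray:
    """Residual Jacobian (n_points x p_free_vector) from forward sensitivities.

    State sensitivities are chained through the output map and, for DNS,
    through the normalisation:
    d(y_i/y_ref)/dtheta_k = (y_ref dy_i - y_i dy_ref) / y_ref^2, where
    dy_ref is the same aggregate (mean / max point / selected point) of the
    sensitivities that defined y_ref.  SF columns are -y_i on points of the
    matching observable.  Error-model columns are zero (plain residuals do
    not involve sigma).  Counts as one gradient call / one objective call
    under the per-call convention and p + 1 under the fd-equivalent one.
    """
    try:
        _, _, dmu = _predictions(problem, spec, free, with_sens=True)
    except _PenaltyEvaluation:
        n = len(_comparison_dataset(problem, spec).points)
        dmu = np.zeros((n, len(free)))
    if counter is not None:
        counter.count_se_gradient(len(free))
    return -dmu


# ---------------------------------------------------------------------------
# optimiser-facing adapter


class ObjectiveAdapter:
    """Presents one (problem, spec) objective to the optimisers.

    Works in internal coordinates z = log10(v) of the free vector, which
    enforces positivity and makes box bounds linear; exposes residual and
    Jacobian callables (sensitivity-equation or finite-difference), the
    canonical scalar objective (LS value or negative log-likelihood) and an
    :class:`EvaluationCounter`.

    For LL the least-squares path minimises an extended residual vector
    [ (y~ - mu)/sigma, sqrt(2 ln sigma + C) ] whose sum of squares equals
    2 * NLL + n * C — an affine transform with the same minimiser.
    """

    def __init__(
        self,
        problem: OdeProblem,
        spec: ObjectiveSpec,
        gradient: str = "se",
        fd_step: float = 1e-4,
        counter: EvaluationCounter | None = None,
    ):
        # the FD step default is noise-aware: residuals carry integration
        # error of order rtol, so steps near sqrt(rtol) balance truncation
        # against solver noise; oracle comparisons pass 1e-6 explicitly
        if gradient not in ("se", "fd"):
            raise ConfigurationError("gradient must be 'se' or 'fd'")
        self.problem = problem
        self.spec = spec
        self.gradient = gradient
        self.fd_step = fd_step
        self.counter = counter or EvaluationCounter()
        self.free0 = assemble_free_vector(problem, spec)
        self.n_points = len(_comparison_dataset(problem, spec).points)

    # -- coordinates --------------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.free0)

    @property
    def z0(self) -> np.ndarray:
        return np.log10(self.free0.values)

    @property
    def z_bounds(self) -> np.ndarray:
        return np.log10(self.free0.bounds)

    def free_at(self, z) -> FreeParameterVector:
        return self.free0.with_values(np.clip(
            10.0 ** np.asarray(z, dtype=float),
            self.free0.bounds[:, 0],
            self.free0.bounds[:, 1],
        ))

    # -- residual interface (for Levenberg-Marquardt) -----------------------

    def _plain(self, z):
        free = self.free_at(z)
        try:
            ytilde, mu, _ = _predictions(self.problem, self.spec, free, with_sens=False)
        except _PenaltyEvaluation:
            return None, None, free
        return ytilde, mu, free

    def residuals_z(self, z) -> np.ndarray:
        t0 = time.perf_counter()
        ytilde, mu, free = self._plain(z)
        try:
            if ytilde is None:
                return np.full(self._n_res(), np.sqrt(PENALTY / self._n_res()))
            r = ytilde - mu
            if self.spec.form == "ls":
                return r
            sig = _sigma(free, mu)
            return np.concatenate(
                [r / sig, np.sqrt(2 * np.log(sig) + LL_RESIDUAL_SHIFT)]
            )
        finally:
            self.counter.count_objective()
            self.counter.elapsed_seconds += time.perf_counter() - t0

    def _n_res(self) -> int:
        return self.n_points * (2 if self.spec.form == "ll" else 1)

    def jacobian_z(self, z) -> np.ndarray:
        if self.gradient == "fd":
            return self._fd_jacobian(z)
        return self._se_jacobian(z)

    def _se_jacobian(self, z) -> np.ndarray:
        t0 = time.perf_counter()
        free = self.free_at(z)
        try:
            try:
                ytilde, mu, dmu = _predictions(self.problem, self.spec, free, with_sens=True)
            except _PenaltyEvaluation:
                return np.zeros((self._n_res(), self.p))
            if self.spec.form == "ls":
                jv = -dmu
            else:
                sig = _sigma(free, mu)
                r = ytilde - mu
                dsig = np.zeros_like(dmu)
                s_b = free.segment("error_model")[1]
                dsig[:, :] = s_b * np.sign(mu)[:, None] * dmu
                sl = free.layout["error_model"]
                dsig[:, sl.start] = 1.0
                dsig[:, sl.start + 1] = np.abs(mu)
                j1 = (-dmu * sig[:, None] - r[:, None] * dsig) / sig[:, None] ** 2
                e = np.sqrt(2 * np.log(sig) + LL_RESIDUAL_SHIFT)
                j2 = dsig / (sig * e)[:, None]
                jv = np.vstack([j1, j2])
            # chain rule through z = log10(v): dv/dz = v ln 10
            return jv * (free.values * np.log(10.0))[None, :]
        finally:
            self.counter.count_se_gradient(self.p)
            self.counter.elapsed_seconds += time.perf_counter() - t0

    def _fd_jacobian(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        r0 = self.residuals_z(z)
        cols = np.empty((r0.size, z.size))
        for k in range(z.size):
            hk = self.fd_step * max(abs(z[k]), 1.0)
            zk = z.copy()
            zk[k] += hk
            cols[:, k] = (self.residuals_z(zk) - r0) / hk
        self.counter.count_fd_gradient()
        return cols

    # -- scalar interface (for GLSDC / Powell) ------------------------------

    def cost_from_residuals(self, r: np.ndarray) -> float:
        """Canonical objective from a residual vector (LS value, or NLL
        recovered from the extended LL residuals)."""
        ss = float(r @ r)
        if self.spec.form == "ls":
            return ss
        return (ss - self.n_points * LL_RESIDUAL_SHIFT) / 2.0

    def objective_z(self, z) -> float:
        return self.cost_from_residuals(self.residuals_z(z))
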