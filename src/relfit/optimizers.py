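"""Optimisation algorithms with comparable evaluation/time traces.

Three algorithms, all emitting the same trace records so that convergence
can be compared both by evaluation counts and by wall-clock time:

* ``levmar_fd`` — Levenberg-Marquardt with finite-difference residual
  Jacobians and Latin-hypercube restarts;
* ``levmar_se`` — the same LM core with Jacobians from forward sensitivity
  equations;
* ``glsdc`` — a hybrid genetic local search with diversity control: a
  real-coded genetic phase in which offspring enter the population only if
  sufficiently distant (in box-normalised log-parameter space) from the
  retained elites, alternating with Powell derivative-free refinement of the
  best distinct individuals.  No gradient is ever requested.

All searches run in log10 parameter space; Latin-hypercube starts are
log-uniform with exactly one sample per stratum per dimension.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.optimize import least_squares
from scipy.stats import qmc

from .exceptions import ConfigurationError, InputError
from .objectives import EvaluationCounter, ObjectiveAdapter, ObjectiveSpec
from .problem import OdeProblem

__all__ = [
    "OptimizerConfig",
    "RunTrace",
    "OptimizerResult",
    "EstimateEnsemble",
    "latin_hypercube_sample",
    "levmar_minimize",
    "multistart_levmar",
    "powell_search",
    "glsdc_run",
    "convergence_summary",
]

ALGORITHMS = ("levmar_fd", "levmar_se", "glsdc")


@dataclass
class OptimizerConfig:
    algorithm: str = "levmar_se"
    max_evals: int = 100_000
    max_seconds: float = 3600.0
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_iter: int = 500  # per LM start
    n_starts: int = 8
    population_size: int | None = None  # GLSDC; default min(10 p, 200)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.max_evals <= 0 or self.max_seconds <= 0:
            raise ConfigurationError("budgets must be positive")
        if self.ftol <= 0 or self.xtol <= 0:
            raise ConfigurationError("tolerances must be positive")


class RunTrace:
    """Time-stamped best-so-far records of one optimisation run."""

    def __init__(self):
        self.records: list[dict] = []
        self._best = np.inf

    def record(self, elapsed_seconds: float, objective_calls: int,
               fd_equivalent_evals: int, objective: float) -> None:
        self._best = min(self._best, objective)
        self.records.append(
            {
                "elapsed_seconds": float(elapsed_seconds),
                "objective_calls": int(objective_calls),
                "fd_equivalent_evals": int(fd_equivalent_evals),
                "best_objective_so_far": float(self._best),
            }
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def best(self) -> float:
        return self._best

    def best_at_time(self, t: float) -> float:
        """Best objective at or before time t; the first record if t precedes
        it, the final value if the trace ends earlier."""
        if not self.records:
            raise InputError("empty trace")
        best = self.records[0]["best_objective_so_far"]
        for rec in self.records:
            if rec["elapsed_seconds"] > t:
                break
            best = rec["best_objective_so_far"]
        return best

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class OptimizerResult:
    best_x: np.ndarray
    best_objective: float
    trace: RunTrace
    termination_reason: str
    counter: EvaluationCounter
    n_iterations: int = 0


@dataclass
class EstimateEnsemble:
    """n_runs x p matrix of estimates with per-run objectives and metadata."""

    estimates: np.ndarray
    objectives: np.ndarray
    parameter_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)
    traces: list[RunTrace] = field(default_factory=list)

    def __post_init__(self):
        self.estimates = np.atleast_2d(np.asarray(self.estimates, dtype=float))
        self.objectives = np.asarray(self.objectives, dtype=float)
        if self.estimates.shape[1] != len(self.parameter_names):
            raise InputError("estimate columns must match parameter names")
        if self.estimates.shape[0] != self.objectives.shape[0]:
            raise InputError("one objective value per run required")

    @property
    def n_runs(self) -> int:
        return self.estimates.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.estimates, columns=list(self.parameter_names))
        df.insert(0, "objective", self.objectives)
        df.insert(0, "run", np.arange(self.n_runs))
        return df


# ---------------------------------------------------------------------------
# sampling


def latin_hypercube_sample(bounds, n: int, seed: int) -> np.ndarray:
    """n log-uniform Latin-hypercube points inside per-parameter (lo, hi).

    Each dimension is split into n equal log-width strata holding exactly one
    sample.  Bounds must be strictly positive (log scaling).
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if np.any(bounds[:, 0] <= 0) or np.any(bounds[:, 1] <= bounds[:, 0]):
        raise ConfigurationError("log-scaled LHS needs 0 < lo < hi per dimension")
    lo, hi = np.log10(bounds[:, 0]), np.log10(bounds[:, 1])
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=int(seed))
    u = sampler.random(n)
    return 10.0 ** (lo + u * (hi - lo))


# ---------------------------------------------------------------------------
# Levenberg-Marquardt


def levmar_minimize(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], np.ndarray],
    x0,
    config: OptimizerConfig,
    bounds=None,
    counter: EvaluationCounter | None = None,
    trace: RunTrace | None = None,
    t_start: float | None = None,
    cost_of: Callable[[np.ndarray], float] | None = None,
) -> OptimizerResult:
    """Damped least-squares (Levenberg-Marquardt family) descent on a
    residual vector.

    The trust-region subproblems are delegated to scipy's bounded
    trust-region-reflective least-squares solver, which is the modern form
    of LM damping and handles the box bounds of the log-parameter search
    space without ad-hoc projection.  Everything the comparison needs —
    evaluation counting under both conventions, wall-clock tracing, budget
    enforcement — happens in the residual/Jacobian wrappers, so the solver
    sees exactly one objective evaluation per residual call and one gradient
    per Jacobian call.  Terminates on relative objective change (ftol), step
    norm (xtol), gradient stationarity (reported as ftol), iteration cap or
    budget.
    """
    x0 = np.asarray(x0, dtype=float).copy()
    counter = counter if counter is not None else EvaluationCounter()
    trace = trace if trace is not None else RunTrace()
    t_start = time.perf_counter() if t_start is None else t_start
    cost_of = cost_of or (lambda r: float(r @ r))
    if bounds is not None:
        bounds = np.asarray(bounds, dtype=float)
        x0 = np.clip(x0, bounds[:, 0], bounds[:, 1])
        lb, ub = bounds[:, 0], bounds[:, 1]
    else:
        lb, ub = -np.inf, np.inf

    best = {"x": x0.copy(), "cost": np.inf}

    class _BudgetExceeded(Exception):
        pass

    def over_budget() -> bool:
        return (
            counter.objective_calls >= config.max_evals
            or time.perf_counter() - t_start >= config.max_seconds
        )

    def fun(x):
        if over_budget():
            raise _BudgetExceeded()
        r = residual_fn(x)
        c = cost_of(r)
        if np.isfinite(c) and c < best["cost"]:
            best["cost"] = c
            best["x"] = np.asarray(x, dtype=float).copy()
        trace.record(time.perf_counter() - t_start, counter.objective_calls,
                     counter.fd_equivalent_evals, c)
        return r

    def jac(x):
        if over_budget():
            raise _BudgetExceeded()
        return jacobian_fn(x)

    status_map = {0: "max_iter", 1: "ftol", 2: "ftol", 3: "xtol", 4: "xtol"}
    n_iter = 0
    try:
        res = least_squares(
            fun,
            x0,
            jac=jac,
            bounds=(lb, ub),
            method="trf",
            x_scale="jac",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=1e-14,
            max_nfev=config.max_iter,
        )
        reason = status_map.get(res.status, "stalled")
        n_iter = int(res.njev if res.njev is not None else res.nfev)
    except _BudgetExceeded:
        reason = "budget"
    if not np.isfinite(best["cost"]):
        # nothing evaluated successfully: report the (penalised) start
        r0 = residual_fn(x0)
        best["cost"], best["x"] = cost_of(r0), x0
    return OptimizerResult(
        best_x=best["x"],
        best_objective=best["cost"],
        trace=trace,
        termination_reason=reason,
        counter=counter,
        n_iterations=n_iter,
    )


def multistart_levmar(
    problem: OdeProblem,
    spec: ObjectiveSpec,
    config: OptimizerConfig,
) -> tuple[EstimateEnsemble, RunTrace]:
    """One LM run per Latin-hypercube start until the global budget runs out.

    Returns the ensemble of completed runs plus a global trace recording the
    best objective over all starts against shared wall clock / counters.
    """
    gradient = "se" if config.algorithm == "levmar_se" else "fd"
    adapter = ObjectiveAdapter(problem, spec, gradient=gradient)
    starts = latin_hypercube_sample(adapter.free0.bounds, config.n_starts, config.seed)
    t_start = time.perf_counter()
    global_trace = RunTrace()
    rows, objs, traces = [], [], []
    for k in range(config.n_starts):
        if (
            rows
            and (
                adapter.counter.objective_calls >= config.max_evals
                or time.perf_counter() - t_start >= config.max_seconds
            )
        ):
            break
        res = levmar_minimize(
            adapter.residuals_z,
            adapter.jacobian_z,
            np.log10(starts[k]),
            config,
            bounds=adapter.z_bounds,
            counter=adapter.counter,
            trace=global_trace,
            t_start=t_start,
            cost_of=adapter.cost_from_residuals,
        )
        free = adapter.free_at(res.best_x)
        rows.append(free.values)
        objs.append(res.best_objective)
        traces.append(res.trace)
    order_best = int(np.argmin(objs))
    ensemble = EstimateEnsemble(
        estimates=np.array(rows),
        objectives=np.array(objs),
        parameter_names=adapter.free0.names,
        metadata={
            "algorithm": config.algorithm,
            "scaling": spec.scaling,
            "objective": spec.form,
            "seed": config.seed,
            "best_run": order_best,
            "counter": adapter.counter.snapshot(),
        },
        traces=[global_trace],
    )
    return ensemble, global_trace


# ---------------------------------------------------------------------------
# Powell and GLSDC


def powell_search(
    objective_fn: Callable[[np.ndarray], float],
    x0,
    tol: float = 1e-10,
    bounds=None,
    maxfev: int | None = None,
    direc: np.ndarray | None = None,
    return_direc: bool = False,
):
    """Derivative-free conjugate-direction descent (Powell's method).

    Returns (x, f(x)) with f(x) <= f(x0); never requests a gradient.  An
    initial direction set ``direc`` may be supplied (carrying the conjugate
    set over between restarts lets repeated calls follow curved valleys);
    with ``return_direc`` the final set is returned as a third element.
    Box bounds are enforced through a quadratic penalty outside the box
    rather than scipy's bounded line search, which is considerably less
    precise near the optimum.
    """
    x0 = np.asarray(x0, dtype=float)
    if bounds is not None:
        b = np.asarray(bounds, dtype=float)
        lo, hi = b[:, 0], b[:, 1]
        x0 = np.clip(x0, lo, hi)

        def fn(x):
            over = np.maximum(0.0, x - hi) + np.maximum(0.0, lo - x)
            return objective_fn(np.clip(x, lo, hi)) + 1e4 * float(over @ over)
    else:
        fn = objective_fn
    f0 = float(fn(x0))
    opts = {"xtol": tol, "ftol": tol}
    if maxfev is not None:
        opts["maxfev"] = int(maxfev)
    if direc is not None:
        direc = np.asarray(direc, dtype=float)
        # a degenerate conjugate set would leave directions unexplored
        if np.linalg.matrix_rank(direc) == direc.shape[0]:
            opts["direc"] = direc
    res = optimize.minimize(fn, x0, method="Powell", options=opts)
    if np.isfinite(res.fun) and res.fun < f0:
        x_best, f_best = np.asarray(res.x, dtype=float), float(res.fun)
        if bounds is not None:
            x_best = np.clip(x_best, lo, hi)
    else:
        x_best, f_best = x0, f0
    if return_direc:
        return x_best, f_best, np.asarray(res.direc, dtype=float)
    return x_best, f_best


def _diverse_subset(pop, fitness, delta, widths, max_keep):
    """Scan individuals in fitness order, keeping those whose box-normalised
    distance to everything already kept exceeds delta; lower index wins ties."""
    order = np.lexsort((np.arange(len(fitness)), fitness))
    kept: list[int] = []
    for i in order:
        cand = pop[i] / widths
        if all(np.linalg.norm(cand - pop[j] / widths) > delta for j in kept):
            kept.append(int(i))
        if len(kept) >= max_keep:
            break
    return kept


def glsdc_run(
    objective_fn: Callable[[np.ndarray], float],
    bounds,
    config: OptimizerConfig,
    trace: RunTrace | None = None,
    counter: EvaluationCounter | None = None,
) -> OptimizerResult:
    """Genetic local search with distance-based diversity control.

    Alternates genetic generations (rank selection among a diversity-filtered
    elite set, BLX-alpha crossover, per-coordinate mutation at rate 1/p) with
    Powell refinement of the top distinct individuals.  Offspring landing
    within the diversity distance delta (box-normalised space) of a retained
    elite are discarded, which keeps the population spread over distinct
    basins.  ``bounds`` are in the search coordinates (log-parameter space).
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    p = bounds.shape[0]
    widths = bounds[:, 1] - bounds[:, 0]
    pop_size = config.population_size or min(10 * p, 200)
    if pop_size < 4:
        raise ConfigurationError("population_size must be >= 4")
    delta = 0.1
    n_local = 3
    gens_per_cycle = 5
    rng = np.random.default_rng(config.seed)
    counter = counter if counter is not None else EvaluationCounter()
    trace = trace if trace is not None else RunTrace()
    t_start = time.perf_counter()
    best_x, best_f = None, np.inf

    def f(x):
        nonlocal best_x, best_f
        t_call = time.perf_counter()
        val = float(objective_fn(x))
        counter.elapsed_seconds += time.perf_counter() - t_call
        counter.count_objective()
        if val < best_f:
            best_f, best_x = val, np.asarray(x, dtype=float).copy()
        trace.record(time.perf_counter() - t_start, counter.objective_calls,
                     counter.fd_equivalent_evals, val)
        return val

    def out_of_budget():
        return (
            counter.objective_calls >= config.max_evals
            or time.perf_counter() - t_start >= config.max_seconds
        )

    # log-uniform initial population via LHS in the box
    sampler = qmc.LatinHypercube(d=p, seed=int(config.seed))
    pop = bounds[:, 0] + sampler.random(pop_size) * widths
    fit = np.array([f(x) for x in pop])

    reason = "budget"
    incumbent_direc = None  # conjugate set carried across local phases
    incumbent_x = None
    while not out_of_budget():
        for _ in range(gens_per_cycle):
            if out_of_budget():
                break
            elites = _diverse_subset(pop, fit, delta, widths, max(2, pop_size // 2))
            new_pop = [pop[i] for i in elites]
            new_fit = [fit[i] for i in elites]
            elite_norm = [pop[i] / widths for i in elites]
            while len(new_pop) < pop_size and not out_of_budget():
                pair = rng.choice(elites, size=2, replace=True)
                a, b = pop[pair[0]], pop[pair[1]]
                lo = np.minimum(a, b)
                hi = np.maximum(a, b)
                d = hi - lo
                child = rng.uniform(lo - 0.5 * d, hi + 0.5 * d)
                mut = rng.random(p) < (1.0 / p)
                child = np.where(mut, child + rng.normal(0.0, 0.1 * widths), child)
                child = np.clip(child, bounds[:, 0], bounds[:, 1])
                dist = [np.linalg.norm(child / widths - e) for e in elite_norm]
                if dist and min(dist) <= delta:
                    # too close to a retained elite: replace by a fresh sample
                    child = rng.uniform(bounds[:, 0], bounds[:, 1])
                new_pop.append(child)
                new_fit.append(f(child))
            pop = np.array(new_pop)
            fit = np.array(new_fit)
        if out_of_budget():
            break
        # local phase: Powell on the top distinct individuals; the incumbent
        # best keeps its conjugate direction set between cycles, which lets
        # repeated restarts track curved valleys instead of stalling
        targets = _diverse_subset(pop, fit, delta, widths, n_local)
        for rank, i in enumerate(targets):
            if out_of_budget():
                break
            remaining = config.max_evals - counter.objective_calls
            if remaining <= p:
                break
            is_best = rank == 0
            direc = None
            if is_best and incumbent_x is not None and np.allclose(
                pop[i], incumbent_x, atol=1e-12
            ):
                direc = incumbent_direc
            budget_i = (300 * p) if is_best else (60 * p)
            x_loc, f_loc, direc_out = powell_search(
                f, pop[i], tol=config.ftol, bounds=bounds,
                maxfev=min(budget_i, remaining), direc=direc, return_direc=True,
            )
            if f_loc < fit[i]:
                pop[i] = x_loc
                fit[i] = f_loc
            if is_best:
                incumbent_x, incumbent_direc = pop[i].copy(), direc_out
        if best_f <= config.ftol:
            reason = "ftol"
            break
    return OptimizerResult(
        best_x=best_x,
        best_objective=best_f,
        trace=trace,
        termination_reason=reason,
        counter=counter,
        n_iterations=len(trace),
    )


def glsdc_fit(
    problem: OdeProblem, spec: ObjectiveSpec, config: OptimizerConfig
) -> tuple[EstimateEnsemble, RunTrace]:
    """GLSDC on a problem/objective, returning a one-run ensemble + trace."""
    adapter = ObjectiveAdapter(problem, spec, gradient="fd")
    trace = RunTrace()
    res = glsdc_run(
        lambda z: adapter.objective_z(z),
        adapter.z_bounds,
        config,
        trace=trace,
        counter=EvaluationCounter(),  # glsdc counts its own calls
    )
    free = adapter.free_at(res.best_x)
    ensemble = EstimateEnsemble(
        estimates=free.values[None, :],
        objectives=np.array([res.best_objective]),
        parameter_names=adapter.free0.names,
        metadata={
            "algorithm": "glsdc",
            "scaling": spec.scaling,
            "objective": spec.form,
            "seed": config.seed,
            "counter": res.counter.snapshot(),
        },
        traces=[trace],
    )
    return ensemble, trace


# ---------------------------------------------------------------------------
# summaries


def convergence_summary(traces: Sequence[RunTrace], cutoffs: Sequence[float]) -> pd.DataFrame:
    """Median / 25th / 75th percentile of per-trace best objectives at each
    time cutoff.  Traces shorter than a cutoff contribute their final value;
    a cutoff before a trace's first record uses the first recorded value."""
    traces = list(traces)
    if not traces:
        raise InputError("no traces given")
    rows = []
    for t in cutoffs:
        vals = np.array([tr.best_at_time(float(t)) for tr in traces])
        rows.append(
            {
                "cutoff_seconds": float(t),
                "q25": float(np.percentile(vals, 25)),
                "median": float(np.percentile(vals, 50)),
                "q75": float(np.percentile(vals, 75)),
                "n_traces": len(traces),
            }
        )
    return pd.DataFrame(rows)
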