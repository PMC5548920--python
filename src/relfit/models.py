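"""ODE models of signalling networks: simulation and forward sensitivities.

A model is the right-hand side dx/dt = f(x, theta) together with named states
and parameters, an initial state that may depend on parameters, and output
functions y = g(x) mapping states to observables.  Experimental conditions
(stimulus doses, knock-downs) are expressed as overrides of parameter values
or initial states; they are applied to copies, the model itself is immutable.

Sensitivities dx/dtheta_k are obtained by integrating the augmented system of
dimension n_states * (p + 1): the original states plus one block of state
derivatives per free parameter.  The sensitivity right-hand side
dS/dt = (df/dx) S + df/dtheta is built from symbolic Jacobians derived from
the declared rhs expressions at model-build time, never from internal finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import warnings

import numpy as np
import sympy
from scipy.integrate import odeint

from .exceptions import (
    ConfigurationError,
    InputError,
    IntegrationError,
    ModelDefinitionError,
)
from .expressions import make_symbols, parse_expression

__all__ = [
    "Condition",
    "Trajectory",
    "SensitivityTrajectory",
    "OutputMap",
    "OdeModel",
    "simulate",
    "simulate_with_sensitivities",
    "observe",
]

#: default stiff-solver tolerances (relative, absolute); configurable per call
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class Condition:
    """An experimental condition as overrides of parameters or initial states.

    ``overrides`` maps a declared parameter name (e.g. a stimulus dose) or a
    declared state name (its initial value, e.g. a knocked-down concentration)
    to the value it takes in this condition.
    """

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Trajectory:
    """ODE solution sampled at requested output times."""

    times: np.ndarray  # shape (n_times,), ascending
    states: np.ndarray  # shape (n_times, n_states)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if states.shape[0] != times.shape[0]:
            raise InputError("trajectory rows must correspond one-to-one to times")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)


@dataclass(frozen=True)
class SensitivityTrajectory:
    """States plus forward sensitivities d x / d theta_k for free parameters."""

    trajectory: Trajectory
    sensitivities: np.ndarray  # shape (n_times, n_states, p_free)
    free_index: tuple[int, ...]


class OutputMap:
    """Named output functions y = g(x, theta) over model states.

    Built from arithmetic expressions so that gradients with respect to both
    states and parameters are available for sensitivity-based Jacobians.
    """

    def __init__(self, model: "OdeModel", expressions: Mapping[str, str]):
        self._names = list(expressions)
        self._model = model
        syms = dict(model._state_symbols)
        syms.update(model._param_symbols)
        args = model._lambdify_args
        self._fns: dict[str, Callable] = {}
        self._grad_x: dict[str, Callable] = {}
        self._grad_p: dict[str, Callable] = {}
        xs = [model._state_symbols[s] for s in model.state_names]
        ps = [model._param_symbols[s] for s in model.param_names]
        for name, text in expressions.items():
            expr = parse_expression(text, syms)
            self._fns[name] = sympy.lambdify(args, expr, "numpy")
            self._grad_x[name] = sympy.lambdify(
                args, [sympy.diff(expr, s) for s in xs], "numpy"
            )
            self._grad_p[name] = sympy.lambdify(
                args, [sympy.diff(expr, p) for p in ps], "numpy"
            )

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._fns

    def value(self, name: str, x: np.ndarray, theta: np.ndarray) -> float:
        if name not in self._fns:
            raise ConfigurationError(f"unknown observable {name!r}")
        return float(self._fns[name](0.0, *np.asarray(x, float), *np.asarray(theta, float)))

    def values(self, name: str, states: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Apply g row-wise over a state matrix (vectorised over time)."""
        if name not in self._fns:
            raise ConfigurationError(f"unknown observable {name!r}")
        states = np.atleast_2d(np.asarray(states, dtype=float))
        theta = np.asarray(theta, float)
        out = self._fns[name](0.0, *states.T, *theta)
        return np.broadcast_to(np.asarray(out, dtype=float), (states.shape[0],)).copy()

    def grad_state(self, name: str, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return np.asarray(self._grad_x[name](0.0, *x, *theta), dtype=float)

    def grad_params(self, name: str, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return np.asarray(self._grad_p[name](0.0, *x, *theta), dtype=float)


class OdeModel:
    """dx/dt = f(x, theta) with named states/parameters and symbolic Jacobians.

    Construct with :meth:`from_expressions`; the declared rhs is parsed and
    differentiated symbolically so the augmented sensitivity system is exact.
    """

    def __init__(
        self,
        state_names: Sequence[str],
        param_names: Sequence[str],
        rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray],
        initial_state: Callable[[np.ndarray], np.ndarray],
        jac_state: Callable | None = None,
        jac_params: Callable | None = None,
        initial_jac: Callable | None = None,
        _symbols: tuple | None = None,
    ):
        if len(set(state_names) | set(param_names)) != len(state_names) + len(param_names):
            raise ConfigurationError("state and parameter names must be distinct")
        self.state_names = list(state_names)
        self.param_names = list(param_names)
        self.rhs = rhs
        self._initial_state = initial_state
        self.jac_state = jac_state
        self.jac_params = jac_params
        self.initial_jac = initial_jac
        if _symbols is not None:
            self._state_symbols, self._param_symbols, self._lambdify_args = _symbols
        else:
            ss = make_symbols(self.state_names)
            pp = make_symbols(self.param_names)
            t = sympy.Symbol("t", real=True)
            self._state_symbols, self._param_symbols = ss, pp
            self._lambdify_args = (
                [t] + [ss[s] for s in self.state_names] + [pp[p] for p in self.param_names]
            )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_expressions(
        cls,
        state_names: Sequence[str],
        param_names: Sequence[str],
        rhs_exprs: Mapping[str, str],
        initial_exprs: Mapping[str, object],
    ) -> "OdeModel":
        """Build a model from arithmetic expressions.

        ``rhs_exprs`` maps each state name to d(state)/dt as an expression in
        states, parameters and ``t``.  ``initial_exprs`` maps each state to a
        number or an expression in parameters only.
        """
        state_names = [str(s) for s in state_names]
        param_names = [str(p) for p in param_names]
        ss = make_symbols(state_names)
        pp = make_symbols(param_names)
        t = sympy.Symbol("t", real=True)
        all_syms = {"t": t, **ss, **pp}
        missing = [s for s in state_names if s not in rhs_exprs]
        if missing:
            raise ConfigurationError(f"rhs missing for state(s): {missing}")
        exprs = [parse_expression(str(rhs_exprs[s]), all_syms) for s in state_names]
        init_exprs = []
        for s in state_names:
            if s not in initial_exprs:
                raise ConfigurationError(f"initial value missing for state {s!r}")
            init_exprs.append(parse_expression(str(initial_exprs[s]), dict(pp)))

        xs = [ss[s] for s in state_names]
        psyms = [pp[p] for p in param_names]
        args = [t] + xs + psyms
        f_mat = sympy.Matrix(exprs)
        jx = f_mat.jacobian(xs)
        jp = f_mat.jacobian(psyms)
        x0_mat = sympy.Matrix(init_exprs)
        x0_jac = x0_mat.jacobian(psyms)

        f_lam = sympy.lambdify(args, exprs, "numpy")
        jx_lam = sympy.lambdify(args, jx.tolist(), "numpy")
        jp_lam = sympy.lambdify(args, jp.tolist(), "numpy")
        x0_lam = sympy.lambdify(psyms, init_exprs, "numpy")
        x0j_lam = sympy.lambdify(psyms, x0_jac.tolist(), "numpy")

        def rhs(time, x, theta):
            return np.asarray(f_lam(time, *x, *theta), dtype=float)

        def jac_state(time, x, theta):
            return np.asarray(jx_lam(time, *x, *theta), dtype=float)

        def jac_params(time, x, theta):
            return np.asarray(jp_lam(time, *x, *theta), dtype=float)

        def initial_state(theta):
            return np.asarray(x0_lam(*theta), dtype=float)

        def initial_jac(theta):
            return np.asarray(x0j_lam(*theta), dtype=float)

        return cls(
            state_names,
            param_names,
            rhs,
            initial_state,
            jac_state=jac_state,
            jac_params=jac_params,
            initial_jac=initial_jac,
            _symbols=(ss, pp, args),
        )

    # -- helpers ------------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def initial_state(self, theta: np.ndarray) -> np.ndarray:
        x0 = np.asarray(self._initial_state(np.asarray(theta, float)), dtype=float)
        if x0.shape != (self.n_states,):
            raise ModelDefinitionError("initial_state returned wrong length")
        return x0

    def apply_condition(
        self, theta: np.ndarray, condition: Condition
    ) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """Return (theta', x0', overridden state indices) under a condition.

        The base theta and model are untouched; overrides act on copies.
        """
        theta = np.array(theta, dtype=float, copy=True)
        if theta.shape != (self.n_params,):
            raise InputError(
                f"theta has length {theta.size}, model declares {self.n_params} parameters"
            )
        state_over: dict[int, float] = {}
        for key, val in condition.overrides.items():
            if key in self.param_names:
                theta[self.param_names.index(key)] = float(val)
            elif key in self.state_names:
                state_over[self.state_names.index(key)] = float(val)
            else:
                raise ConfigurationError(
                    f"condition {condition.name!r} overrides unknown identifier {key!r}"
                )
        x0 = self.initial_state(theta)
        for idx, val in state_over.items():
            x0[idx] = val
        return theta, x0, sorted(state_over)


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise InputError("times must be a non-empty 1-D vector")
    if np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly ascending")
    if times[0] < 0:
        raise InputError("times must be non-negative")
    return times


def _integrate(fun, x0, times, rtol, atol, jac=None):
    """LSODA via the low-overhead odeint interface; returns (n_times, n) or
    None on solver failure / non-finite states."""
    x0 = np.asarray(x0, dtype=float)
    if times[-1] == 0.0:
        return np.tile(x0, (times.size, 1))
    prepend = times[0] > 0.0
    grid = np.concatenate([[0.0], times]) if prepend else times
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lsoda chatter on hard steps
        out, info = odeint(
            fun,
            x0,
            grid,
            Dfun=jac,
            rtol=rtol,
            atol=atol,
            tfirst=True,
            full_output=True,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(out)):
        return None
    return out[1:] if prepend else out


def simulate(
    model: OdeModel,
    theta: np.ndarray,
    condition: Condition,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the model under a condition, sampling exactly at ``times``.

    Uses a stiff-capable solver (LSODA) with the analytic state Jacobian when
    the model provides one.  Integration starts at t = 0 with the condition's
    overrides applied to copies of theta and the initial state.
    """
    times = _check_times(times)
    if rtol <= 0 or atol <= 0:
        raise InputError("solver tolerances must be positive")
    theta_c, x0, _ = model.apply_condition(theta, condition)

    def fun(t, x):
        return model.rhs(t, x, theta_c)

    jac = None
    if model.jac_state is not None:
        jac = lambda t, x: model.jac_state(t, x, theta_c)  # noqa: E731
    states = _integrate(fun, x0, times, rtol, atol, jac=jac)
    if states is None:
        raise IntegrationError(
            f"ODE integration failed under condition {condition.name!r}",
            theta=theta_c,
            condition=condition,
        )
    return Trajectory(times=times, states=states)


def simulate_with_sensitivities(
    model: OdeModel,
    theta: np.ndarray,
    condition: Condition,
    times,
    free_index: Sequence[int],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SensitivityTrajectory:
    """Integrate the augmented state + sensitivity system.

    The augmented system has dimension n_states * (p + 1) for p free
    parameters: the original states plus dS/dt = (df/dx) S + df/dtheta_free,
    with S(0) = d x0 / d theta_free (zero rows for condition-overridden
    initial states).  The leading block reproduces :func:`simulate` within
    solver tolerance.
    """
    times = _check_times(times)
    free_index = list(free_index)
    if not free_index:
        raise InputError("free_index must be non-empty")
    if len(set(free_index)) != len(free_index):
        raise InputError("free_index contains duplicates")
    if any(k < 0 or k >= model.n_params for k in free_index):
        raise InputError("free_index position out of range")
    if model.jac_state is None or model.jac_params is None:
        raise ModelDefinitionError(
            "model lacks partial derivatives (jac_state/jac_params) needed for sensitivities"
        )
    theta_c, x0, over_states = model.apply_condition(theta, condition)
    n, p = model.n_states, len(free_index)

    if model.initial_jac is not None:
        s0 = np.asarray(model.initial_jac(theta_c), dtype=float)[:, free_index]
    else:
        s0 = np.zeros((n, p))
    # an overridden initial state is a condition constant, not a function of theta
    for idx in over_states:
        s0[idx, :] = 0.0

    def aug(t, z):
        x = z[:n]
        s = z[n:].reshape(n, p)
        dx = model.rhs(t, x, theta_c)
        jx = model.jac_state(t, x, theta_c)
        jp = model.jac_params(t, x, theta_c)[:, free_index]
        ds = jx @ s + jp
        return np.concatenate([dx, ds.ravel()])

    z0 = np.concatenate([x0, s0.ravel()])
    z = _integrate(aug, z0, times, rtol, atol)
    if z is None:
        raise IntegrationError(
            f"sensitivity integration failed under condition {condition.name!r}",
            theta=theta_c,
            condition=condition,
        )
    states = z[:, :n]
    sens = z[:, n:].reshape(times.size, n, p)
    return SensitivityTrajectory(
        trajectory=Trajectory(times=times, states=states),
        sensitivities=sens,
        free_index=tuple(free_index),
    )


def observe(
    trajectory: Trajectory,
    output_map: OutputMap,
    observable: str,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the output function g row-wise; one value per output time."""
    if observable not in output_map:
        raise ConfigurationError(f"unknown observable {observable!r}")
    if theta is None:
        theta = np.zeros(len(output_map._model.param_names))
    return output_map.values(observable, trajectory.states, theta)
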