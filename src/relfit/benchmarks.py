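"""Synthetic ground-truth benchmark problems.

Real calibration studies of MAPK/ERK-type signalling models cannot ship with
a desk-scale package, so this module generates miniature stand-ins with the
same experimental design: a phosphorylation cascade observed through a small
number of observables, two stimulus conditions, arbitrary-unit replicate
gains and average normalisation.  Every problem carries its generating
ground truth, which makes round-trip tests (objective exactly zero at the
true parameters of noiseless data, parameter recovery, error-model
recovery) possible.

The cascade: tier i holds an active fraction a_i of a unit pool, activated
by the upstream active form (tier 1 by the stimulus S under negative
feedback from the last tier) with Michaelis-Menten kinetics and deactivated
by a saturable phosphatase term:

    da_i/dt = (kbas_i + kact_i u_i) (T_i - a_i)/(km_i + T_i - a_i)
              - kd_i a_i/(kmd_i + a_i),
    u_1 = S / (1 + kfb a_n),   u_i = a_{i-1}  (i > 1),

with T_i = 1 except tier 1, whose pool size T1 is a parameter so that a
knock-down condition can scale it.  Observables are sums of active forms
over contiguous tier groups.

Presets mirror the published problem shapes (observables x free kinetic
parameters): ``styx-like`` 1x10 with 38 data points, ``egfhrg-small`` 8x10
and ``egfhrg-large`` 8x74 with 112 data points, each in two conditions with
normalisation by average.

A separate generator produces manifold-structured estimate clouds (a known
k-dimensional non-identifiable subspace embedded in log-parameter space)
for exercising the PCA identifiability pipeline against a known degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataPoint, Dataset, NormalizationSpec
from .exceptions import ConfigurationError, InputError
from .models import Condition, OdeModel, OutputMap, simulate
from .optimizers import EstimateEnsemble
from .problem import OdeProblem

__all__ = [
    "BenchmarkSpec",
    "GroundTruth",
    "make_cascade_problem",
    "generate_data",
    "make_manifold_cloud",
    "make_preset",
    "PRESETS",
]

#: stimulus doses of the two standard conditions
DOSES = {"high": 1.0, "low": 0.2}
#: tier-1 pool size under the optional knock-down condition
KNOCKDOWN_SCALE = 0.3
#: solver tolerances shared by benchmark data generation and fitting
BENCH_RTOL, BENCH_ATOL = 1e-7, 1e-9


@dataclass(frozen=True)
class BenchmarkSpec:
    """Shape and noise of a synthetic cascade estimation problem."""

    n_tiers: int = 3
    n_observables: int = 1
    p_free: int = 10
    n_conditions: int = 2
    n_replicates: int = 1
    n_times: int = 19
    t_end: float = 10.0
    noise: tuple[float, float] = (0.02, 0.1)  # (s_a, s_b) in simulation units
    replicate_gain_range: tuple[float, float] = (10.0, 3000.0)
    #: "doses" (high/low stimulus) or "control_knockdown" (full vs scaled
    #: tier-1 pool, the design of single-observable knock-down experiments)
    condition_set: str = "doses"
    #: negative transcriptional-style feedback from the last tier onto tier-1
    #: activation; multimodal landscapes come mostly from this loop
    feedback: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_tiers < 1 or self.n_observables < 1:
            raise ConfigurationError("need at least one tier and one observable")
        if self.n_observables > self.n_tiers:
            raise ConfigurationError("more observables than observable states")
        if self.n_conditions not in (2, 3):
            raise ConfigurationError("supported condition counts: 2 (doses) or 3 (+knock-down)")
        if self.replicate_gain_range[0] <= 0:
            raise ConfigurationError("replicate gains must be positive")
        if self.noise[0] < 0 or self.noise[1] < 0:
            raise ConfigurationError("noise components must be non-negative")
        if self.condition_set not in ("doses", "control_knockdown"):
            raise ConfigurationError(f"unknown condition_set {self.condition_set!r}")


@dataclass(frozen=True)
class GroundTruth:
    theta_true: np.ndarray
    param_names: tuple[str, ...]
    seed: int
    gains: dict = field(default_factory=dict)  # (observable, replicate) -> gain

    def value(self, name: str) -> float:
        return float(self.theta_true[self.param_names.index(name)])


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named substream: all benchmark randomness flows from one seed."""
    return np.random.default_rng([int(seed), int(stream)])


_STREAM_TRUTH, _STREAM_GAINS, _STREAM_NOISE, _STREAM_EMBED = 0, 1, 2, 3


def _cascade_expressions(n_tiers: int, feedback: bool) -> tuple[list[str], list[str], dict, dict]:
    states = [f"a{i}" for i in range(1, n_tiers + 1)]
    params: list[str] = []
    for i in range(1, n_tiers + 1):
        params += [f"kact{i}", f"km{i}", f"kd{i}", f"kmd{i}", f"kbas{i}"]
    if feedback:
        params += ["kfb"]
    params += ["T1", "S"]
    rhs = {}
    for i in range(1, n_tiers + 1):
        total = "T1" if i == 1 else "1"
        if i == 1:
            up = f"S/(1 + kfb*a{n_tiers})" if feedback else "S"
        else:
            up = f"a{i - 1}"
        rhs[f"a{i}"] = (
            f"(kbas{i} + kact{i}*({up}))*({total} - a{i})/(km{i} + {total} - a{i})"
            f" - kd{i}*a{i}/(kmd{i} + a{i})"
        )
    initial = {s: 0.0 for s in states}
    return states, params, rhs, initial


def _free_priority(n_tiers: int, feedback: bool) -> list[str]:
    """Which parameters are freed first as p_free grows: rate constants,
    the feedback strength (if present), then the Michaelis constants of
    activation and deactivation, then basal rates."""
    order = [f"kact{i}" for i in range(1, n_tiers + 1)]
    order += [f"kd{i}" for i in range(1, n_tiers + 1)]
    if feedback:
        order += ["kfb"]
    order += [f"km{i}" for i in range(1, n_tiers + 1)]
    order += [f"kmd{i}" for i in range(1, n_tiers + 1)]
    order += [f"kbas{i}" for i in range(1, n_tiers + 1)]
    return order


def _draw_truth(spec: BenchmarkSpec, param_names: list[str]) -> np.ndarray:
    rng = _rng(spec.seed, _STREAM_TRUTH)
    vals = {}
    for i in range(1, spec.n_tiers + 1):
        vals[f"kact{i}"] = rng.uniform(1.0, 4.0)
        vals[f"km{i}"] = rng.uniform(0.2, 0.8)
        vals[f"kd{i}"] = rng.uniform(0.4, 1.5)
        vals[f"kmd{i}"] = rng.uniform(0.3, 0.8)
        vals[f"kbas{i}"] = 0.01
    if spec.feedback:
        vals["kfb"] = rng.uniform(1.0, 3.0)
    vals["T1"] = 1.0
    vals["S"] = DOSES["high"]
    return np.array([vals[n] for n in param_names])


def make_cascade_problem(spec: BenchmarkSpec) -> tuple[OdeProblem, GroundTruth]:
    """Build a seeded cascade problem with known ground truth.

    The returned problem's dataset is generated at theta_true with the
    spec's replicate gains and noise; its nominal parameter values equal the
    truth (fixed parameters are fixed at truth, free ones are searched in a
    +-3-decade box around it).
    """
    states, params, rhs, initial = _cascade_expressions(spec.n_tiers, spec.feedback)
    free_order = _free_priority(spec.n_tiers, spec.feedback)
    if spec.p_free > len(free_order):
        raise ConfigurationError(
            f"p_free={spec.p_free} exceeds the {len(free_order)} tunable kinetic parameters"
        )
    free_names = free_order[: spec.p_free]
    theta_true = _draw_truth(spec, params)
    model = OdeModel.from_expressions(states, params, rhs, initial)

    if spec.condition_set == "control_knockdown":
        conditions = [
            Condition("control", {"S": DOSES["high"], "T1": 1.0}),
            Condition("knockdown", {"S": DOSES["high"], "T1": KNOCKDOWN_SCALE}),
        ]
        if spec.n_conditions == 3:
            conditions.append(Condition("low", {"S": DOSES["low"]}))
    else:
        conditions = [
            Condition("high", {"S": DOSES["high"]}),
            Condition("low", {"S": DOSES["low"]}),
        ]
        if spec.n_conditions == 3:
            conditions.append(
                Condition("knockdown", {"S": DOSES["high"], "T1": KNOCKDOWN_SCALE})
            )

    # contiguous tier groups summed into observables
    edges = np.linspace(0, spec.n_tiers, spec.n_observables + 1).astype(int)
    obs_exprs = {}
    for j in range(spec.n_observables):
        members = states[edges[j]: edges[j + 1]]
        obs_exprs[f"obs{j + 1}"] = " + ".join(members)
    output_map = OutputMap(model, obs_exprs)

    bounds = {}
    for i, name in enumerate(params):
        v = theta_true[i]
        ref = v if v > 0 else 1.0
        bounds[name] = (ref * 1e-3, ref * 1e3)

    gains = _draw_gains(spec, list(obs_exprs))
    truth = GroundTruth(
        theta_true=theta_true, param_names=tuple(params), seed=spec.seed, gains=gains
    )
    dataset = _make_dataset(model, output_map, conditions, spec, truth)
    problem = OdeProblem(
        name=f"cascade-{spec.n_observables}-{spec.p_free}",
        model=model,
        conditions=conditions,
        output_map=output_map,
        dataset=dataset,
        free_names=free_names,
        bounds=bounds,
        theta_nominal=theta_true.copy(),
        # benchmark problems trade a little solver accuracy for speed; the
        # library default (1e-8/1e-10) stays for user-defined problems
        rtol=BENCH_RTOL,
        atol=BENCH_ATOL,
        expressions={"rhs": rhs, "initial": initial, "observables": obs_exprs},
    )
    return problem, truth


def _draw_gains(spec: BenchmarkSpec, observables: list[str]) -> dict:
    rng = _rng(spec.seed, _STREAM_GAINS)
    lo, hi = spec.replicate_gain_range
    gains = {}
    for obs in observables:
        for r in range(1, spec.n_replicates + 1):
            gains[(obs, f"r{r}")] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return gains


def _time_grid(spec: BenchmarkSpec) -> np.ndarray:
    return np.linspace(0.0, spec.t_end, spec.n_times)


def _make_dataset(model, output_map, conditions, spec: BenchmarkSpec, truth: GroundTruth) -> Dataset:
    rng = _rng(spec.seed, _STREAM_NOISE)
    s_a, s_b = spec.noise
    times = _time_grid(spec)
    points = []
    for cond in conditions:
        traj = simulate(model, truth.theta_true, cond, times, rtol=BENCH_RTOL, atol=BENCH_ATOL)
        theta_c, _, _ = model.apply_condition(truth.theta_true, cond)
        for obs in output_map.names:
            y = output_map.values(obs, traj.states, theta_c)
            for r in range(1, spec.n_replicates + 1):
                rep = f"r{r}"
                gain = truth.gains[(obs, rep)]
                eps = rng.standard_normal(y.size)
                noisy = y + (s_a + s_b * np.abs(y)) * eps
                for t, v in zip(times, gain * noisy):
                    points.append(
                        DataPoint(
                            condition=cond.name,
                            observable=obs,
                            time=float(t),
                            replicate=rep,
                            value=float(v),
                        )
                    )
    return Dataset(points=tuple(points), normalization=NormalizationSpec(scheme="average"))


def generate_data(problem: OdeProblem, truth: GroundTruth, spec: BenchmarkSpec) -> Dataset:
    """Fresh arbitrary-unit dataset at theta_true:
    y_hat = gain_(obs, rep) * (y + (s_a + s_b |y|) * N(0, 1)); noiseless when
    s_a = s_b = 0.  Gains are the truth's per-(observable, replicate) gains."""
    return _make_dataset(problem.model, problem.output_map, problem.conditions, spec, truth)


def with_dataset(problem: OdeProblem, dataset: Dataset) -> OdeProblem:
    """The same problem bound to another dataset."""
    return OdeProblem(
        name=problem.name,
        model=problem.model,
        conditions=problem.conditions,
        output_map=problem.output_map,
        dataset=dataset,
        free_names=list(problem.free_names),
        bounds=dict(problem.bounds),
        theta_nominal=problem.theta_nominal.copy(),
        rtol=problem.rtol,
        atol=problem.atol,
        expressions=problem.expressions,
    )


# ---------------------------------------------------------------------------
# manifold-structured estimate clouds


def make_manifold_cloud(
    p: int, k: int, n: int, spread: float, noise_sd: float, seed: int
) -> EstimateEnsemble:
    """Estimates spread over a known k-dimensional subspace of log2 space.

    k latent coordinates (zero-mean, per-direction log2 standard deviation
    spread/sqrt(12), the spread of a uniform of that width) are embedded via
    a random orthonormal map; isotropic Gaussian noise of sd ``noise_sd``
    fills the orthogonal complement; 2**(matrix) gives positive estimates.
    The PCA degree of such a cloud is k whenever spread/sqrt(12) > 1 sigma
    threshold and noise_sd**2 < 1.
    """
    if not 0 <= k <= p:
        raise InputError("need 0 <= k <= p")
    if spread <= 0:
        raise InputError("spread must be positive")
    if n < 2:
        raise InputError("need at least two runs")
    rng = _rng(seed, _STREAM_EMBED)
    q, r = np.linalg.qr(rng.standard_normal((p, p)))
    q = q * np.sign(np.diag(r))  # deterministic orientation
    m = np.zeros((n, p))
    if k > 0:
        if n < k + 1:
            raise InputError("need n > k runs to span k latent directions")
        draw = rng.uniform(-spread / 2, spread / 2, size=(n, k))
        draw -= draw.mean(axis=0)
        # exactly orthogonal mean-zero latent columns with sample sd equal to
        # that of a uniform of width `spread`, so the latent covariance is
        # (spread^2/12) I exactly and the embedded spectrum is flat
        q_lat, r_lat = np.linalg.qr(draw)
        q_lat = q_lat * np.sign(np.diag(r_lat))
        latent = q_lat * (spread / np.sqrt(12.0)) * np.sqrt(n - 1)
        m += latent @ q[:, :k].T
    if k < p and noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, p - k))
        m += noise @ q[:, k:].T
    estimates = 2.0 ** m
    return EstimateEnsemble(
        estimates=estimates,
        objectives=np.zeros(n),
        parameter_names=tuple(f"k{i + 1}" for i in range(p)),
        metadata={"kind": "manifold_cloud", "k": k, "spread": spread,
                  "noise_sd": noise_sd, "seed": seed, "embedding": q},
    )


# ---------------------------------------------------------------------------
# presets


PRESETS = {
    # observables x free kinetic parameters, data points as published
    "styx-like": BenchmarkSpec(
        n_tiers=3, n_observables=1, p_free=10, n_conditions=2,
        n_replicates=1, n_times=19, condition_set="control_knockdown",
        feedback=False,
    ),
    "egfhrg-small": BenchmarkSpec(
        n_tiers=8, n_observables=8, p_free=10, n_conditions=2,
        n_replicates=1, n_times=7,
    ),
    "egfhrg-large": BenchmarkSpec(
        n_tiers=15, n_observables=8, p_free=74, n_conditions=2,
        n_replicates=1, n_times=7,
    ),
}


def make_preset(
    name: str, seed: int = 0, noise: tuple[float, float] | None = None
) -> tuple[OdeProblem, GroundTruth]:
    """Instantiate a named preset with a seed; ``noise=(0, 0)`` gives the
    noiseless variant used for round-trip recovery checks."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choices: {sorted(PRESETS)}")
    base = PRESETS[name]
    spec = BenchmarkSpec(
        n_tiers=base.n_tiers,
        n_observables=base.n_observables,
        p_free=base.p_free,
        n_conditions=base.n_conditions,
        n_replicates=base.n_replicates,
        n_times=base.n_times,
        t_end=base.t_end,
        noise=base.noise if noise is None else tuple(noise),
        replicate_gain_range=base.replicate_gain_range,
        condition_set=base.condition_set,
        feedback=base.feedback,
        seed=seed,
    )
    return make_cascade_problem(spec)
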