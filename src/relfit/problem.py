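"""The estimation problem: model, conditions, observables, data and bounds.

An :class:`OdeProblem` is the immutable bundle handed to objectives and
optimisers: the ODE model, the experimental conditions, the output map, the
measurement dataset with its normalisation directive, and the free/fixed
split of the kinetic parameters with per-parameter box bounds.

Problems are serialisable to a small YAML dialect (states, parameters with
free flags and bounds, rhs expressions, initial values, condition override
maps, observable expressions, a data CSV path and the normalisation rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data import Dataset, NormalizationSpec, normalize_data, read_dataset
from .exceptions import ConfigurationError
from .models import Condition, OdeModel, OutputMap

__all__ = ["OdeProblem", "load_problem", "save_problem"]

#: default kinetic search box: +-3 decades around the nominal value
DEFAULT_DECADES = 3.0


@dataclass
class OdeProblem:
    name: str
    model: OdeModel
    conditions: list[Condition]
    output_map: OutputMap
    dataset: Dataset
    free_names: list[str]
    bounds: dict[str, tuple[float, float]]
    theta_nominal: np.ndarray
    rtol: float = 1e-8
    atol: float = 1e-10
    #: optional expression sources ({'rhs':…, 'initial':…, 'observables':…})
    #: kept so a built problem can be serialised back to YAML
    expressions: dict | None = None

    _normalized_cache: Dataset | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.theta_nominal = np.asarray(self.theta_nominal, dtype=float)
        if self.theta_nominal.shape != (self.model.n_params,):
            raise ConfigurationError("theta_nominal length mismatch")
        unknown = [n for n in self.free_names if n not in self.model.param_names]
        if unknown:
            raise ConfigurationError(f"free parameter(s) not declared: {unknown}")
        for name in self.free_names:
            lo, hi = self.bounds.get(name, (None, None))
            if lo is None or hi is None or not (0 < lo < hi):
                raise ConfigurationError(
                    f"free parameter {name!r} needs positive bounds lo < hi"
                )
        cond_names = [c.name for c in self.conditions]
        if len(set(cond_names)) != len(cond_names):
            raise ConfigurationError("duplicate condition names")
        for obs in self.dataset.observables:
            if obs not in self.output_map:
                raise ConfigurationError(f"dataset observable {obs!r} has no output function")
        for cond in self.dataset.conditions:
            if cond not in cond_names:
                raise ConfigurationError(f"dataset condition {cond!r} is not declared")

    # -- derived views ------------------------------------------------------

    @property
    def p_kinetic(self) -> int:
        return len(self.free_names)

    @property
    def n_observables(self) -> int:
        return len(self.output_map.names)

    @property
    def free_index(self) -> list[int]:
        return [self.model.param_names.index(n) for n in self.free_names]

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise ConfigurationError(f"unknown condition {name!r}")

    def measurement_times(self, condition: str) -> np.ndarray:
        """Sorted unique measurement times of one condition (union over
        observables and replicates); residuals never interpolate."""
        times = sorted({float(p.time) for p in self.dataset.points if p.condition == condition})
        return np.asarray(times, dtype=float)

    def normalized_dataset(self) -> Dataset:
        """The dataset after its own normalisation directive (cached)."""
        if self._normalized_cache is None:
            if self.dataset.normalized or self.dataset.normalization.scheme == "none":
                self._normalized_cache = self.dataset
            else:
                self._normalized_cache = normalize_data(self.dataset)
        return self._normalized_cache

    def theta_from_free(self, free_kinetic: Sequence[float]) -> np.ndarray:
        theta = self.theta_nominal.copy()
        theta[self.free_index] = np.asarray(free_kinetic, dtype=float)
        return theta


def _norm_spec_from_config(cfg: Mapping) -> NormalizationSpec:
    scheme = str(cfg.get("scheme", "average"))
    selector = None
    if scheme == "reference_point":
        selector = (str(cfg["reference_condition"]), float(cfg["reference_time"]))
    return NormalizationSpec(scheme=scheme, reference_selector=selector)


def load_problem(path, dataset: Dataset | None = None) -> OdeProblem:
    """Load a problem from a YAML config; `data:` paths resolve relative to it."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("states", "parameters", "rhs", "initial", "conditions", "observables"):
        if key not in cfg:
            raise ConfigurationError(f"problem config missing section {key!r}")

    states = [str(s) for s in cfg["states"]]
    params = cfg["parameters"]
    param_names = [str(p["name"]) for p in params]
    values = np.array([float(p["value"]) for p in params])
    free_names = [str(p["name"]) for p in params if p.get("free", False)]
    bounds: dict[str, tuple[float, float]] = {}
    for p in params:
        name, val = str(p["name"]), float(p["value"])
        lo = float(p["lower"]) if "lower" in p else val * 10.0 ** (-DEFAULT_DECADES)
        hi = float(p["upper"]) if "upper" in p else val * 10.0 ** (DEFAULT_DECADES)
        bounds[name] = (lo, hi)

    model = OdeModel.from_expressions(states, param_names, cfg["rhs"], cfg["initial"])
    conditions = [
        Condition(name=str(c["name"]), overrides=dict(c.get("overrides", {})))
        for c in cfg["conditions"]
    ]
    output_map = OutputMap(model, {str(k): str(v) for k, v in cfg["observables"].items()})

    norm = _norm_spec_from_config(cfg.get("normalization", {}))
    if dataset is None:
        if "data" in cfg and cfg["data"]:
            dataset = read_dataset(path.parent / cfg["data"], norm)
        else:
            raise ConfigurationError("no dataset given and config declares no data file")
    solver = cfg.get("solver", {})
    return OdeProblem(
        name=str(cfg.get("name", path.stem)),
        model=model,
        conditions=conditions,
        output_map=output_map,
        dataset=dataset,
        free_names=free_names,
        bounds=bounds,
        theta_nominal=values,
        rtol=float(solver.get("rtol", 1e-8)),
        atol=float(solver.get("atol", 1e-10)),
    )


def save_problem(
    problem: OdeProblem,
    path,
    rhs_exprs: Mapping[str, str] | None = None,
    initial_exprs: Mapping[str, object] | None = None,
    observable_exprs: Mapping[str, str] | None = None,
    data_filename: str | None = "data.csv",
) -> None:
    """Write the YAML config (and the data CSV next to it, if requested).

    Expression sources default to ``problem.expressions``; a built model
    itself keeps only compiled callables.
    """
    path = Path(path)
    src = problem.expressions or {}
    rhs_exprs = rhs_exprs if rhs_exprs is not None else src.get("rhs")
    initial_exprs = initial_exprs if initial_exprs is not None else src.get("initial")
    observable_exprs = (
        observable_exprs if observable_exprs is not None else src.get("observables")
    )
    if rhs_exprs is None or initial_exprs is None or observable_exprs is None:
        raise ConfigurationError(
            "expression sources unavailable; pass rhs/initial/observable expressions"
        )
    spec = problem.dataset.normalization
    norm_cfg: dict = {"scheme": spec.scheme}
    if spec.scheme == "reference_point":
        norm_cfg["reference_condition"] = spec.reference_selector[0]
        norm_cfg["reference_time"] = float(spec.reference_selector[1])
    cfg = {
        "name": problem.name,
        "states": list(problem.model.state_names),
        "parameters": [
            {
                "name": n,
                "value": float(problem.theta_nominal[i]),
                "free": n in problem.free_names,
                "lower": float(problem.bounds[n][0]),
                "upper": float(problem.bounds[n][1]),
            }
            for i, n in enumerate(problem.model.param_names)
        ],
        "rhs": {k: str(v) for k, v in rhs_exprs.items()},
        "initial": {k: (v if isinstance(v, (int, float)) else str(v)) for k, v in initial_exprs.items()},
        "conditions": [
            {"name": c.name, "overrides": {k: float(v) for k, v in c.overrides.items()}}
            for c in problem.conditions
        ],
        "observables": {k: str(v) for k, v in observable_exprs.items()},
        "normalization": norm_cfg,
        "solver": {"rtol": problem.rtol, "atol": problem.atol},
    }
    if data_filename:
        cfg["data"] = data_filename
        problem.dataset.to_frame().to_csv(path.parent / data_filename, index=False)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
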