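"""Arbitrary-unit measurement data and the shared normalisation contract.

Quantitative immunoblot-style data come in arbitrary units that are only
comparable within one replicate.  The standard remedy is to divide every
value by a reference — the average, the maximum, or a designated reference
point of that observable in that replicate.  Data-driven normalisation of
simulations (DNS) applies the *same* rule to simulated observables, computed
over exactly the same (condition, time) points, so that normalised data and
normalised simulation live on a common scale without extra fit parameters.

The normalisation group is (observable, replicate), pooling all conditions
and times of that replicate; the grouping key is configurable in principle
but this pooled convention is the package default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, NormalizationError

__all__ = [
    "DataPoint",
    "NormalizationSpec",
    "Dataset",
    "read_dataset",
    "reference_value",
    "normalize_data",
    "normalize_simulation_like_data",
]

SCHEMES = ("average", "max", "reference_point", "none")

REQUIRED_COLUMNS = ["condition", "observable", "time", "replicate", "value"]


@dataclass(frozen=True)
class DataPoint:
    """One measurement: an arbitrary-unit value at (condition, observable, time, replicate)."""

    condition: str
    observable: str
    time: float
    replicate: str
    value: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise InputError(f"non-finite value for {self.key()}")
        if self.time < 0:
            raise InputError(f"negative time for {self.key()}")

    def key(self) -> tuple:
        return (self.condition, self.observable, self.time, self.replicate)


@dataclass(frozen=True)
class NormalizationSpec:
    """Which reference divides each (observable, replicate) group.

    scheme: 'average' (arithmetic mean of the group), 'max', 'reference_point'
    (the value at a designated (condition, time)), or 'none' (reference 1).
    """

    scheme: str = "average"
    reference_selector: tuple[str, float] | None = None

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise InputError(f"unknown normalisation scheme {self.scheme!r}")
        if self.scheme == "reference_point" and self.reference_selector is None:
            raise InputError("reference_point scheme requires a (condition, time) selector")


@dataclass(frozen=True)
class Dataset:
    """A collection of data points plus the normalisation directive."""

    points: tuple[DataPoint, ...]
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        seen = set()
        for p in self.points:
            k = p.key()
            if k in seen:
                raise InputError(f"duplicate data point key {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def observables(self) -> list[str]:
        out = []
        for p in self.points:
            if p.observable not in out:
                out.append(p.observable)
        return out

    @property
    def conditions(self) -> list[str]:
        out = []
        for p in self.points:
            if p.condition not in out:
                out.append(p.condition)
        return out

    def groups(self) -> dict[tuple[str, str], list[int]]:
        """Indices of points per normalisation group (observable, replicate)."""
        out: dict[tuple[str, str], list[int]] = {}
        for i, p in enumerate(self.points):
            out.setdefault((p.observable, p.replicate), []).append(i)
        return out

    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": p.condition,
                    "observable": p.observable,
                    "time": p.time,
                    "replicate": p.replicate,
                    "value": p.value,
                }
                for p in self.points
            ]
        )


def read_dataset(path, spec: NormalizationSpec | None = None) -> Dataset:
    """Read a CSV with columns condition,observable,time,replicate,value.

    Returns an un-normalised Dataset; row order is preserved.  Missing
    columns, unparsable values and duplicate keys raise InputError naming
    the offending row or key.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"dataset file is missing column(s): {missing}")
    points = []
    for i, row in df.iterrows():
        try:
            t = float(row["time"])
            v = float(row["value"])
        except (TypeError, ValueError) as exc:
            raise InputError(f"row {i}: unparsable numeric field ({exc})") from exc
        points.append(
            DataPoint(
                condition=str(row["condition"]),
                observable=str(row["observable"]),
                time=t,
                replicate=str(row["replicate"]),
                value=v,
            )
        )
    return Dataset(points=tuple(points), normalization=spec or NormalizationSpec())


def reference_value(
    values: Sequence[float],
    spec: NormalizationSpec,
    group_context: Mapping[tuple, int] | None = None,
) -> float:
    """The reference dividing a normalisation group.

    ``group_context`` maps (condition, time) -> position in ``values`` and is
    required for the reference_point scheme.  A reference must be strictly
    positive; anything else raises NormalizationError.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise NormalizationError("empty normalisation group")
    if spec.scheme == "none":
        return 1.0
    if spec.scheme == "average":
        ref = float(values.mean())
    elif spec.scheme == "max":
        ref = float(values.max())
    else:  # reference_point
        if group_context is None:
            raise NormalizationError("reference_point scheme needs a group context")
        sel = (spec.reference_selector[0], float(spec.reference_selector[1]))
        if sel not in group_context:
            raise NormalizationError(f"reference point {sel} not present in group")
        ref = float(values[group_context[sel]])
    if ref <= 0:
        raise NormalizationError(f"normalisation reference is {ref}; must be > 0")
    return ref


def _group_context(ds: Dataset, idx: list[int]) -> dict[tuple, int]:
    """(condition, time) -> position within the group's value vector.

    If a group contains several points at the same (condition, time) (it can
    not, by the duplicate-key rule, within one replicate) the first wins.
    """
    ctx: dict[tuple, int] = {}
    for pos, i in enumerate(idx):
        p = ds.points[i]
        ctx.setdefault((p.condition, float(p.time)), pos)
    return ctx


def normalize_data(ds: Dataset) -> Dataset:
    """Divide every value by its group's reference; returns a new Dataset.

    Groups are (observable, replicate) pooled across conditions and times.
    After 'average' normalisation each group has mean exactly 1.
    """
    if ds.normalized:
        raise InputError("dataset is already normalised")
    new_values = np.array([p.value for p in ds.points], dtype=float)
    for (obs, rep), idx in ds.groups().items():
        vals = new_values[idx]
        ref = reference_value(vals, ds.normalization, _group_context(ds, idx))
        new_values[idx] = vals / ref
    points = tuple(
        replace(p, value=float(v)) for p, v in zip(ds.points, new_values)
    )
    return Dataset(points=points, normalization=ds.normalization, normalized=True)


def normalize_simulation_like_data(
    sim_values: Mapping[tuple[str, str, float], float], ds: Dataset
) -> np.ndarray:
    """Normalise simulated observables with the data's own rule (DNS).

    ``sim_values`` maps (condition, observable, time) to the simulated value.
    For every (observable, replicate) group the simulated reference is the
    same aggregate (mean/max/selected point) over the simulated values at
    exactly the (condition, time) set that defined the data reference for
    that group.  Returns one normalised simulated value per data point, in
    dataset order.

    A non-positive simulated reference signals an infeasible parameter set
    and raises NormalizationError; objective code converts this into a large
    finite penalty rather than a crash.
    """
    out = np.empty(len(ds.points), dtype=float)
    for (obs, rep), idx in ds.groups().items():
        sims = []
        for i in idx:
            p = ds.points[i]
            key = (p.condition, p.observable, float(p.time))
            if key not in sim_values:
                raise InputError(f"simulation missing value for data point {key}")
            sims.append(float(sim_values[key]))
        sims = np.asarray(sims, dtype=float)
        ref = reference_value(sims, ds.normalization, _group_context(ds, idx))
        out[idx] = sims / ref
    return out
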