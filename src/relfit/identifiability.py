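"""Practical (a posteriori) identifiability of estimate ensembles via PCA.

Independent optimisation runs that fit the data equally well but disagree on
parameter values reveal directions in parameter space that the data do not
constrain.  To quantify this, per-parameter estimates are log2-normalised to
their minimum across runs, theta_norm = log2(theta_ij / min_j theta_ij), so
a value of 1 means a two-fold change relative to the smallest estimate.  PCA
of the normalised (runs x parameters) matrix then orders directions by
variance; the degree of practical non-identifiability is the number of
principal components with variance strictly greater than 1 (i.e. more than a
two-fold spread along that direction).

The analysis is scoped to the free kinetic parameters: scaling-factor and
error-model estimates are nuisance quantities and are dropped by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import InputError
from .optimizers import EstimateEnsemble

__all__ = [
    "IdentifiabilityReport",
    "log_normalize_estimates",
    "pca_variances",
    "degree_of_nonidentifiability",
    "analyze_ensemble",
    "identifiable_parameters",
]

#: a principal direction is unidentifiable if its variance exceeds this
VARIANCE_THRESHOLD = 1.0


@dataclass(frozen=True)
class IdentifiabilityReport:
    pc_variances: np.ndarray  # descending
    pc_loadings: np.ndarray  # (p, n_components), columns are PCs
    degree: int
    normalisation_baseline: np.ndarray  # per-parameter reference values
    parameter_names: tuple[str, ...]
    n_runs: int

    def summary(self) -> str:
        return (
            f"degree of practical non-identifiability = {self.degree} "
            f"({self.n_runs} runs, {len(self.parameter_names)} parameters)"
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        var = pd.DataFrame(
            {
                "component": np.arange(1, self.pc_variances.size + 1),
                "variance": self.pc_variances,
                "unidentifiable": self.pc_variances > VARIANCE_THRESHOLD,
            }
        )
        load = pd.DataFrame(
            self.pc_loadings,
            index=list(self.parameter_names),
            columns=[f"PC{i + 1}" for i in range(self.pc_loadings.shape[1])],
        )
        return var, load


def _kinetic_columns(ens: EstimateEnsemble) -> list[int]:
    """Free-vector columns that are kinetic parameters (drop alpha_*, s_a, s_b)."""
    cols = []
    for i, name in enumerate(ens.parameter_names):
        if name in ("s_a", "s_b") or name.startswith("alpha_"):
            continue
        cols.append(i)
    return cols


def log_normalize_estimates(
    ens: EstimateEnsemble,
    kinetic_only: bool = True,
    baseline: str = "min",
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """log2(theta_ij / baseline_i) with runs in rows, parameters in columns.

    ``baseline='min'`` divides by the per-parameter minimum across runs (the
    minimum of each column maps exactly to 0); ``baseline='best'`` divides by
    the values of the run with the lowest objective.  Returns
    (matrix, baseline values, parameter names).
    """
    cols = _kinetic_columns(ens) if kinetic_only else list(range(len(ens.parameter_names)))
    mat = ens.estimates[:, cols]
    names = tuple(ens.parameter_names[i] for i in cols)
    bad = np.argwhere(mat <= 0)
    if bad.size:
        r, c = bad[0]
        raise InputError(
            f"non-positive estimate for parameter {names[c]!r} in run {int(r)}; "
            "log normalisation needs positive estimates"
        )
    if baseline == "min":
        ref = mat.min(axis=0)
    elif baseline == "best":
        ref = mat[int(np.argmin(ens.objectives))]
    else:
        raise InputError(f"unknown baseline {baseline!r}")
    return np.log2(mat / ref), ref, names


def pca_variances(norm_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending PC variances and loadings of a (runs x parameters) matrix.

    Columns are centred but not rescaled (the log2 normalisation is the
    scaling step); variances are the eigenvalues of the sample covariance
    and sum to the total column variance.
    """
    norm_matrix = np.atleast_2d(np.asarray(norm_matrix, dtype=float))
    n, p = norm_matrix.shape
    if n < 2:
        raise InputError("PCA needs at least 2 runs")
    pca = PCA(n_components=min(n - 1, p), svd_solver="full")
    pca.fit(norm_matrix)
    return pca.explained_variance_.copy(), pca.components_.T.copy()


def degree_of_nonidentifiability(variances) -> int:
    """Number of principal directions with variance strictly > 1."""
    variances = np.asarray(variances, dtype=float)
    return int(np.sum(variances > VARIANCE_THRESHOLD))


def identifiable_parameters(
    jacobian: np.ndarray,
    names,
    residual_norm: float = 1e-4,
    fold: float = 1.01,
) -> list[str]:
    """Parameters pinned down by the data at a given fit quality.

    Takes the residual Jacobian in log10-parameter coordinates (rows =
    residuals, columns = parameters) evaluated at an optimum.  In the linear
    approximation, any parameter displacement dz with ||J dz|| <= r_norm fits
    the data essentially as well; a parameter is practically identifiable at
    tolerance ``fold`` if its worst-case displacement over that set stays
    below log10(fold).  With J = U S V', that worst case for parameter i is
    r_norm * sqrt(sum_k V_ik^2 / s_k^2); directions with near-zero singular
    values make every parameter loading on them unidentifiable.

    The default r_norm = 1e-4 corresponds to a sum-of-squares objective of
    1e-8; fold = 1.01 is a one-percent tolerance.
    """
    jacobian = np.asarray(jacobian, dtype=float)
    _, s, vt = np.linalg.svd(jacobian, full_matrices=False)
    tiny = max(jacobian.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    inv2 = np.where(s > tiny, 1.0 / np.maximum(s, tiny) ** 2, np.inf)
    amp = np.sqrt((vt.T**2 * inv2[None, :]).sum(axis=1))
    bound = residual_norm * amp
    return [str(n) for n, b in zip(names, bound) if b < np.log10(fold)]


def analyze_ensemble(
    ens: EstimateEnsemble, kinetic_only: bool = True, baseline: str = "min"
) -> IdentifiabilityReport:
    """Full pipeline: log-normalise, PCA, threshold count."""
    mat, ref, names = log_normalize_estimates(ens, kinetic_only=kinetic_only, baseline=baseline)
    variances, loadings = pca_variances(mat)
    return IdentifiabilityReport(
        pc_variances=variances,
        pc_loadings=loadings,
        degree=degree_of_nonidentifiability(variances),
        normalisation_baseline=ref,
        parameter_names=names,
        n_runs=ens.n_runs,
    )
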