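"""Structural path model and the maximum-likelihood discrepancy function.

The model expresses the vector of regional principal components v as a set of
simultaneous linear regressions

    v = K v + u

where K is a p x p matrix of path coefficients with zero diagonal and u a
vector of residual series with diagonal covariance R = diag(r_1..r_p).
Solving for v gives the model-implied correlation matrix

    C1(theta) = (I - K)^{-1} R (I - K)^{-T}

Convention: ``K[i, j]`` is the path j -> i, so row i of v = Kv + u regresses
region i on its parents. All serialized edges are labelled source -> target
to keep the orientation unambiguous.

The fit of C1 against the observed correlation matrix C2 is measured by the
ML discrepancy

    F(C1, C2) = log|C1| + tr(C2 C1^{-1}) - log|C2| - p

which is nonnegative for positive-definite pairs and zero iff C1 = C2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import (
    DefinitenessError,
    DimensionError,
    DomainError,
    SingularModelError,
)

__all__ = [
    "PathModel",
    "DiscrepancyValue",
    "theta_to_K",
    "K_to_theta",
    "implied_correlation",
    "unit_diagonal_residuals",
    "ml_discrepancy",
    "count_possible_paths",
    "count_candidate_models",
    "check_positive_definite",
    "read_edge_list",
    "write_edge_list",
    "read_correlation_csv",
    "write_correlation_csv",
]

#: relative eigenvalue floor for positive-definiteness checks
PD_RTOL = 1e-10


@dataclass(frozen=True)
class PathModel:
    """A p x p path-coefficient matrix with structural masks.

    ``allowed_mask`` marks anatomically permitted directed paths;
    ``free_mask`` (a subset) marks the currently unconstrained coefficients.
    K is nonzero only on free entries, and theta packs the free entries in
    row-major order of the mask.
    """

    K: np.ndarray
    allowed_mask: np.ndarray
    free_mask: np.ndarray
    region_labels: tuple[str, ...] = field(default=None)

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        allowed = np.asarray(self.allowed_mask, dtype=bool)
        free = np.asarray(self.free_mask, dtype=bool)
        p = K.shape[0]
        if K.shape != (p, p) or allowed.shape != (p, p) or free.shape != (p, p):
            raise DimensionError("K and masks must all be square with equal shape")
        if np.any(np.diag(K)) or np.any(np.diag(allowed)) or np.any(np.diag(free)):
            raise DimensionError("diagonal of K and both masks must be zero (no self-loops)")
        if np.any(free & ~allowed):
            raise DimensionError("free_mask must be a subset of allowed_mask")
        if np.any(K[~free] != 0):
            raise DimensionError("K must be zero outside free_mask")
        labels = self.region_labels
        if labels is None:
            labels = tuple(f"R{i + 1}" for i in range(p))
        else:
            labels = tuple(str(x) for x in labels)
            if len(labels) != p:
                raise DimensionError("region_labels length must equal p")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "allowed_mask", allowed)
        object.__setattr__(self, "free_mask", free)
        object.__setattr__(self, "region_labels", labels)

    @property
    def p(self) -> int:
        return self.K.shape[0]

    @property
    def q(self) -> int:
        return int(self.free_mask.sum())

    @property
    def theta(self) -> np.ndarray:
        return K_to_theta(self.K, self.free_mask)

    def with_theta(self, theta: np.ndarray) -> "PathModel":
        return replace(self, K=theta_to_K(theta, self.free_mask))

    def free_edges(self) -> list[tuple[int, int]]:
        """Free paths as (source, target) index pairs, row-major in the mask."""
        return [(j, i) for i, j in zip(*np.nonzero(self.free_mask))]

    @classmethod
    def null(cls, allowed_mask: np.ndarray, region_labels=None) -> "PathModel":
        allowed = np.asarray(allowed_mask, dtype=bool)
        return cls(
            K=np.zeros(allowed.shape),
            allowed_mask=allowed,
            free_mask=np.zeros_like(allowed),
            region_labels=region_labels,
        )


@dataclass(frozen=True)
class DiscrepancyValue:
    """ML discrepancy with its diagnostic decomposition."""

    F: float
    log_det_C1: float
    trace_term: float
    log_det_C2: float

    def __float__(self) -> float:
        return self.F


def theta_to_K(theta: np.ndarray, free_mask: np.ndarray) -> np.ndarray:
    """Scatter the free-coefficient vector into a full K matrix (row-major)."""
    free_mask = np.asarray(free_mask, dtype=bool)
    theta = np.asarray(theta, dtype=float)
    q = int(free_mask.sum())
    if theta.shape != (q,):
        raise DimensionError(f"theta has length {theta.size}, free_mask has {q} entries")
    K = np.zeros(free_mask.shape)
    K[free_mask] = theta
    return K


def K_to_theta(K: np.ndarray, free_mask: np.ndarray) -> np.ndarray:
    """Gather the free entries of K into a vector (row-major; exact inverse of
    :func:`theta_to_K`)."""
    return np.asarray(K, dtype=float)[np.asarray(free_mask, dtype=bool)].copy()


def _as_variance_vector(residuals, p: int) -> np.ndarray:
    from .timeseries import ResidualModel

    r = residuals.variances if isinstance(residuals, ResidualModel) else np.asarray(
        residuals, dtype=float)
    if r.shape != (p,):
        raise DimensionError(f"residual vector has shape {r.shape}, expected ({p},)")
    if np.any(r < 0):
        raise DomainError("residual variances must be nonnegative")
    return r


def implied_correlation(model: PathModel, residuals) -> np.ndarray:
    """Model-implied correlation matrix C1 = (I-K)^{-1} R (I-K)^{-T}.

    ``residuals`` may be a :class:`~semconn.timeseries.ResidualModel` or a
    plain nonnegative vector. Raises :class:`SingularModelError` when I - K is
    singular.
    """
    p = model.p
    r = _as_variance_vector(residuals, p)
    A = np.eye(p) - model.K
    try:
        B = linalg.solve(A, np.eye(p))
    except linalg.LinAlgError as exc:  # pragma: no cover - scipy raises generic
        raise SingularModelError("I - K is singular") from exc
    if not np.all(np.isfinite(B)) or np.linalg.cond(A) > 1e12:
        raise SingularModelError(
            f"I - K is singular or near-singular (cond={np.linalg.cond(A):.3g})"
        )
    C1 = B @ np.diag(r) @ B.T
    return 0.5 * (C1 + C1.T)  # enforce exact symmetry


def unit_diagonal_residuals(K: np.ndarray) -> np.ndarray:
    """Residual variances making diag(C1) = 1.

    With B = (I-K)^{-1}, diag(C1) = (B∘B) r; solving the linear system gives
    the unique residual vector under which the implied matrix is a genuine
    correlation matrix — the closure used when fitting standardized series.
    Entries may come out nonpositive for incoherent K; callers treat that as
    infeasible.
    """
    p = K.shape[0]
    A = np.eye(p) - K
    B = np.linalg.solve(A, np.eye(p))
    return np.linalg.solve(B * B, np.ones(p))


def check_positive_definite(C: np.ndarray, name: str = "matrix", rtol: float = PD_RTOL) -> np.ndarray:
    """Validate symmetry and positive definiteness; return eigenvalues."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionError(f"{name} must be square, got shape {C.shape}")
    if not np.allclose(C, C.T, atol=1e-8):
        raise DefinitenessError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(C)
    if w[0] <= rtol * max(w[-1], 0.0) or w[-1] <= 0:
        raise DefinitenessError(
            f"{name} is not positive definite (eigenvalues in [{w[0]:.3g}, {w[-1]:.3g}])"
        )
    return w


def _logdet_pd(C: np.ndarray, name: str) -> tuple[float, np.ndarray]:
    """log-determinant via Cholesky; raises DefinitenessError on failure."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise DefinitenessError(f"{name} is not positive definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(L)))), L


def ml_discrepancy(C1: np.ndarray, C2: np.ndarray) -> DiscrepancyValue:
    """ML discrepancy F = log|C1| + tr(C2 C1^{-1}) - log|C2| - p.

    Both matrices must be symmetric positive definite of the same order.
    Determinants are computed through Cholesky factors, never by
    exponentiating a determinant, so the value is stable at larger p.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    if C1.shape != C2.shape:
        raise DimensionError(f"shape mismatch: C1 {C1.shape} vs C2 {C2.shape}")
    p = C1.shape[0]
    check_positive_definite(C1, "C1")
    check_positive_definite(C2, "C2")
    log_det_C1, L1 = _logdet_pd(C1, "C1")
    log_det_C2, _ = _logdet_pd(C2, "C2")
    # tr(C2 C1^{-1}) via triangular solves against the Cholesky factor of C1
    X = linalg.solve_triangular(L1, C2, lower=True)
    Y = linalg.solve_triangular(L1, X.T, lower=True)
    trace_term = float(np.trace(Y))
    F = log_det_C1 + trace_term - log_det_C2 - p
    return DiscrepancyValue(F=float(F), log_det_C1=log_det_C1,
                            trace_term=trace_term, log_det_C2=log_det_C2)


def count_possible_paths(p: int) -> int:
    """Number of directed non-self paths among p regions: p(p-1)."""
    if p < 1:
        raise DomainError(f"p must be >= 1, got {p}")
    return p * (p - 1)


def count_candidate_models(n_paths: int, n_select: int) -> int:
    """Exact binomial coefficient C(n_paths, n_select) as a Python integer."""
    if n_paths < 0 or n_select < 0 or n_select > n_paths:
        raise DomainError(
            f"need 0 <= n_select <= n_paths, got n_select={n_select}, n_paths={n_paths}"
        )
    return math.comb(n_paths, n_select)


def diag_deviation(C1: np.ndarray) -> float:
    """Diagnostic: max |diag(C1) - 1| (the implied matrix of an arbitrary
    theta need not have unit diagonal)."""
    return float(np.max(np.abs(np.diag(C1) - 1.0)))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_edge_list(model: PathModel, path) -> None:
    """Serialize a path model as an edge list CSV.

    Columns: source_region, target_region, coefficient, status with status in
    {free, allowed, fixed-zero}; one row per ordered region pair.
    """
    rows = []
    labels = model.region_labels
    for i in range(model.p):
        for j in range(model.p):
            if i == j:
                continue
            # (j -> i) lives at K[i, j]
            if model.free_mask[i, j]:
                status = "free"
            elif model.allowed_mask[i, j]:
                status = "allowed"
            else:
                status = "fixed-zero"
            rows.append({
                "source_region": labels[j],
                "target_region": labels[i],
                "coefficient": model.K[i, j],
                "status": status,
            })
    pd.DataFrame(rows).sort_values(
        ["source_region", "target_region"]).to_csv(path, index=False)


def read_edge_list(path) -> PathModel:
    """Load a path model from the edge-list CSV format."""
    df = pd.read_csv(path)
    required = {"source_region", "target_region", "coefficient", "status"}
    missing = required - set(df.columns)
    if missing:
        raise DimensionError(f"edge list missing columns: {sorted(missing)}")
    labels = sorted(set(df["source_region"].astype(str)) | set(df["target_region"].astype(str)))
    idx = {lab: k for k, lab in enumerate(labels)}
    p = len(labels)
    K = np.zeros((p, p))
    allowed = np.zeros((p, p), dtype=bool)
    free = np.zeros((p, p), dtype=bool)
    for _, row in df.iterrows():
        j, i = idx[str(row["source_region"])], idx[str(row["target_region"])]
        status = str(row["status"])
        if status == "free":
            free[i, j] = allowed[i, j] = True
            K[i, j] = float(row["coefficient"])
        elif status == "allowed":
            allowed[i, j] = True
        elif status != "fixed-zero":
            raise DomainError(f"unknown edge status {status!r}")
    return PathModel(K=K, allowed_mask=allowed, free_mask=free,
                     region_labels=tuple(labels))


def model_to_json(model: PathModel) -> str:
    return json.dumps({
        "region_labels": list(model.region_labels),
        "K": model.K.tolist(),
        "allowed_mask": model.allowed_mask.astype(int).tolist(),
        "free_mask": model.free_mask.astype(int).tolist(),
    }, indent=2)


def model_from_json(text: str) -> PathModel:
    d = json.loads(text)
    return PathModel(
        K=np.array(d["K"], dtype=float),
        allowed_mask=np.array(d["allowed_mask"], dtype=bool),
        free_mask=np.array(d["free_mask"], dtype=bool),
        region_labels=tuple(d["region_labels"]),
    )


def write_correlation_csv(C: np.ndarray, labels, path) -> None:
    pd.DataFrame(C, index=list(labels), columns=list(labels)).to_csv(path)


def read_correlation_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
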