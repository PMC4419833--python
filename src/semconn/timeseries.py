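"""Regional time-series preparation.

Each region of interest (ROI) is observed as an ``m x n`` matrix of subjects
by timepoints. The rows are standardized to zero mean and unit variance, and
the dominant stimulus-locked temporal component — the *eigentimeseries*, the
first right singular vector of the matrix — is extracted by SVD:

    R_i = U_i L_i V_i^T

The fraction of variance the first component explains, lambda_1^2 / sum_j
lambda_j^2, determines the region's residual variance

    r_i = 1 - lambda_1^2 / sum_j lambda_j^2

which enters the structural model as the diagonal of the residual covariance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DimensionError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalTimeSeries",
    "EigenDecomposition",
    "ResidualModel",
    "standardize",
    "eigentimeseries",
    "residual_variance",
    "build_pc_matrix",
    "read_region_csv",
    "read_long_table",
    "write_pc_outputs",
]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """Standardized subjects-by-timepoints matrix for one region."""

    region_id: str
    data: np.ndarray  # m x n, rows standardized

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EigenDecomposition:
    """SVD summary of one region's standardized matrix."""

    singular_values: np.ndarray  # nonincreasing, length m
    eigentimeseries: np.ndarray  # length n, unit norm, sign-fixed
    explained_fraction: float  # lambda_1^2 / sum lambda_j^2
    u: np.ndarray = field(repr=False, default=None)  # m x k left vectors
    vt: np.ndarray = field(repr=False, default=None)  # k x n right vectors


@dataclass(frozen=True)
class ResidualModel:
    """Diagonal residual variances r_1..r_p, each in [0, 1]."""

    variances: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "variances", v)
        if v.ndim != 1:
            raise DimensionError("residual variances must be a 1-d vector")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise DomainError(f"residual variances must lie in [0, 1], got {v}")

    @property
    def p(self) -> int:
        return self.variances.size


def standardize(raw: np.ndarray, region_id: str = "region", ddof: int = 1) -> RegionalTimeSeries:
    """Standardize each subject row to zero mean and unit variance.

    Parameters
    ----------
    raw : (m, n) array
        One subject per row, one timepoint per column.
    region_id : str
        Label carried through to outputs.
    ddof : int
        Delta degrees of freedom for the variance denominator. The default 1
        (unbiased, ``n - 1``) is conventional for sample time series; pass 0
        for the population normalization.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    m, n = raw.shape
    if n < 2:
        raise DimensionError(f"need at least 2 timepoints, got n={n}")
    sd = raw.std(axis=1, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(
            f"region {region_id!r}: constant row(s) {bad.tolist()} cannot be standardized"
        )
    data = (raw - raw.mean(axis=1, keepdims=True)) / sd[:, None]
    return RegionalTimeSeries(region_id=region_id, data=data)


def _fix_sign(v: np.ndarray) -> int:
    """Deterministic sign convention: the element of largest absolute value is
    positive; ties broken by the earliest index."""
    idx = int(np.argmax(np.abs(v)))
    return -1 if v[idx] < 0 else 1


def eigentimeseries(ts: RegionalTimeSeries) -> EigenDecomposition:
    """Extract the first principal component (eigentimeseries) of a region.

    Returns the full thin SVD so the reconstruction ``U L V^T`` can be
    checked, with the sign of the first right singular vector fixed by a
    deterministic data-driven rule.
    """
    data = ts.data
    if not np.any(data):
        raise DegenerateInputError(f"region {ts.region_id!r}: all-zero matrix")
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    if s.size > 1 and np.isclose(s[0], s[1], rtol=1e-10, atol=0.0):
        logger.warning(
            "region %r: leading singular values tied (%.6g ~ %.6g); "
            "the first principal subspace is ambiguous",
            ts.region_id, s[0], s[1],
        )
    sign = _fix_sign(vt[0])
    u = u.copy()
    vt = vt.copy()
    vt[0] *= sign
    u[:, 0] *= sign
    total = float(np.sum(s**2))
    return EigenDecomposition(
        singular_values=s,
        eigentimeseries=vt[0].copy(),
        explained_fraction=float(s[0] ** 2 / total),
        u=u,
        vt=vt,
    )


def residual_variance(eig: EigenDecomposition) -> float:
    """Residual variance r = 1 - lambda_1^2 / sum_j lambda_j^2."""
    s = np.asarray(eig.singular_values, dtype=float)
    total = float(np.sum(s**2))
    if total == 0:
        raise DegenerateInputError("all singular values are zero")
    return float(1.0 - s[0] ** 2 / total)


def build_pc_matrix(
    regions: Sequence[RegionalTimeSeries],
) -> tuple[np.ndarray, ResidualModel, list[EigenDecomposition]]:
    """Stack each region's eigentimeseries into a p x n matrix.

    Returns the matrix (row i is region i's first principal component), the
    residual model with r_i per the eigenvalue-spectrum formula, and the
    per-region decompositions for diagnostics.
    """
    if len(regions) < 2:
        raise DimensionError(f"need at least 2 regions, got {len(regions)}")
    ns = {ts.n for ts in regions}
    if len(ns) != 1:
        raise DimensionError(f"regions disagree on timepoint count: {sorted(ns)}")
    eigs = [eigentimeseries(ts) for ts in regions]
    pcs = np.vstack([e.eigentimeseries for e in eigs])
    resid = ResidualModel(np.array([residual_variance(e) for e in eigs]))
    return pcs, resid, eigs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_region_csv(path, region_id: str | None = None, sep: str | None = None,
                    ddof: int = 1) -> RegionalTimeSeries:
    """Read one region's subjects x timepoints matrix from a delimited file.

    The delimiter is sniffed (comma/tab/whitespace) unless ``sep`` is given;
    a header row is detected by attempting a fully numeric parse first.
    """
    path = Path(path)
    if region_id is None:
        region_id = path.stem
    kwargs = dict(sep=sep, engine="python") if sep else dict(
        sep=None, engine="python")
    try:
        df = pd.read_csv(path, header=None, **kwargs)
        raw = df.to_numpy(dtype=float)
    except (ValueError, TypeError):
        try:
            df = pd.read_csv(path, header=0, **kwargs)
            raw = df.to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise DegenerateInputError(
                f"{path}: could not parse a numeric matrix ({exc})") from exc
    return standardize(raw, region_id=region_id, ddof=ddof)


def read_long_table(path, sep: str | None = None, ddof: int = 1) -> list[RegionalTimeSeries]:
    """Read a long-format table with columns region, subject, timepoint, value."""
    kwargs = dict(sep=sep, engine="python") if sep else dict(sep=None, engine="python")
    df = pd.read_csv(path, **kwargs)
    required = {"region", "subject", "timepoint", "value"}
    missing = required - set(df.columns)
    if missing:
        raise DimensionError(f"long table missing columns: {sorted(missing)}")
    out = []
    for region, grp in df.groupby("region", sort=True):
        wide = grp.pivot(index="subject", columns="timepoint", values="value")
        if wide.isna().any().any():
            raise DimensionError(f"region {region!r}: incomplete subject/timepoint grid")
        out.append(standardize(wide.to_numpy(dtype=float), region_id=str(region), ddof=ddof))
    return out


def write_pc_outputs(out_dir, regions: Sequence[RegionalTimeSeries],
                     pcs: np.ndarray, resid: ResidualModel,
                     eigs: Sequence[EigenDecomposition]) -> None:
    """Write the eigentimeseries matrix and residual variances as CSV plus a
    JSON sidecar with each region's singular-value spectrum."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = [ts.region_id for ts in regions]
    pd.DataFrame(pcs, index=labels).to_csv(out_dir / "eigentimeseries.csv")
    pd.DataFrame({"region": labels, "residual_variance": resid.variances}).to_csv(
        out_dir / "residual_variances.csv", index=False
    )
    sidecar = {
        ts.region_id: {
            "singular_values": e.singular_values.tolist(),
            "explained_fraction": e.explained_fraction,
        }
        for ts, e in zip(regions, eigs)
    }
    (out_dir / "spectra.json").write_text(json.dumps(sidecar, indent=2))
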