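"""Model/results facade for effective-connectivity SEM.

:class:`EffectiveConnectivitySEM` is built from data (regional time series or
a correlation matrix); its :meth:`~EffectiveConnectivitySEM.fit` minimizes
the ML discrepancy for a fixed structure and returns :class:`SEMResults`,
while :meth:`~EffectiveConnectivitySEM.search` decides which paths to free
and returns :class:`StructureSearchResults`. Both results objects expose the
estimates, the discrepancy decomposition, diagnostics and a summary table.

Example
-------
>>> import numpy as np
>>> from semconn import EffectiveConnectivitySEM
>>> C2 = np.array([[1.0, 0.6], [0.6, 1.0]])
>>> mask = np.array([[False, False], [True, False]])  # path R1 -> R2
>>> model = EffectiveConnectivitySEM(C2, allowed_mask=mask)
>>> res = model.fit(free_mask=mask)
>>> round(res.params["R1->R2"], 3)
0.6
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import search as _search
from .exceptions import DimensionError
from .optimize import GAConfig, SEMProblem, hpgsa_minimize, minimize_local
from .sem import (
    DiscrepancyValue,
    PathModel,
    check_positive_definite,
    diag_deviation,
    implied_correlation,
    ml_discrepancy,
    unit_diagonal_residuals,
)
from .timeseries import RegionalTimeSeries, ResidualModel, build_pc_matrix

__all__ = ["EffectiveConnectivitySEM", "SEMResults", "StructureSearchResults"]


def _edge_labels(model: PathModel) -> list[str]:
    return [f"{model.region_labels[s]}->{model.region_labels[t]}"
            for s, t in _search._edges_rowmajor(model.free_mask)]


class EffectiveConnectivitySEM:
    """Structural equation model for directed interregional connectivity.

    Parameters
    ----------
    C2 : (p, p) array
        Observed correlation matrix of the regional principal components.
    allowed_mask : (p, p) bool array, optional
        Anatomically permitted directed paths (``mask[t, s]`` is s -> t);
        defaults to every non-self pair.
    residuals : vector, ResidualModel or "unit_diagonal"
        Residual-variance rule used in the implied matrix. The default
        ``"unit_diagonal"`` derives, at each coefficient vector, the
        residuals under which the implied matrix has unit diagonal — the
        natural closure for a correlation-matrix fit. Pass the PCA-spectrum
        residuals (``pca_residuals`` after ``from_timeseries``) for the
        fixed-R variant.
    region_labels : sequence of str, optional
    """

    def __init__(self, C2, allowed_mask=None, residuals="unit_diagonal",
                 region_labels=None):
        self.C2 = np.asarray(C2, dtype=float)
        check_positive_definite(self.C2, "C2")
        self.p = self.C2.shape[0]
        if allowed_mask is None:
            allowed_mask = ~np.eye(self.p, dtype=bool)
        self.allowed_mask = np.asarray(allowed_mask, dtype=bool)
        if self.allowed_mask.shape != (self.p, self.p):
            raise DimensionError("allowed_mask does not match the order of C2")
        self.residuals = residuals
        self.region_labels = tuple(region_labels) if region_labels is not None \
            else tuple(f"R{i + 1}" for i in range(self.p))
        self.pca_residuals: ResidualModel | None = None
        self.nobs: int | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_timeseries(cls, regions: Sequence[RegionalTimeSeries],
                        allowed_mask=None, residuals="unit_diagonal"):
        """Build the model from standardized regional time series.

        Extracts each region's eigentimeseries, forms their observed
        correlation matrix, and records the PCA-spectrum residual variances
        for the fixed-R fitting variant.
        """
        pcs, resid, _ = build_pc_matrix(regions)
        C2 = np.corrcoef(pcs)
        model = cls(C2, allowed_mask=allowed_mask, residuals=residuals,
                    region_labels=[ts.region_id for ts in regions])
        model.pca_residuals = resid
        model.nobs = regions[0].n
        return model

    @classmethod
    def from_dataframe(cls, corr: pd.DataFrame, allowed_mask=None,
                       residuals="unit_diagonal"):
        """Build the model from a labelled square correlation DataFrame."""
        return cls(corr.to_numpy(dtype=float), allowed_mask=allowed_mask,
                   residuals=residuals, region_labels=[str(c) for c in corr.columns])

    # -- fitting -----------------------------------------------------------
    def fit(self, free_mask=None, method: str = "powell", theta_init=None,
            config: GAConfig | None = None) -> "SEMResults":
        """Minimize F over the coefficients of a fixed structure.

        method : "powell" (local, the classic baseline) or "hpgsa" (the
        hybrid genetic/simulated-annealing global search).
        """
        free_mask = self.allowed_mask if free_mask is None \
            else np.asarray(free_mask, dtype=bool)
        problem = SEMProblem(free_mask, self.residuals, self.C2)
        if method == "powell":
            t0 = np.zeros(problem.q) if theta_init is None else np.asarray(theta_init, float)
            run = minimize_local(problem.objective, t0)
        elif method == "hpgsa":
            run = hpgsa_minimize(problem, config or GAConfig(
                population_size=128, max_generations=60, n_islands=2))
        else:
            raise DimensionError(f"unknown method {method!r}")
        path_model = PathModel(
            K=np.zeros((self.p, self.p)), allowed_mask=self.allowed_mask,
            free_mask=free_mask, region_labels=self.region_labels,
        ).with_theta(run.theta_best)
        return SEMResults(model=self, path_model=path_model, opt_result=run)

    def search(self, strategy: str = "stepwise", q: int | None = None,
               stop: _search.StopRule | None = None, optimizer="powell",
               config: GAConfig | None = None) -> "StructureSearchResults":
        """Decide which paths are free.

        strategy : "stepwise" (Lagrange-multiplier forward selection),
        "exhaustive" (enumerate all q-subsets; exact, small instances only)
        or "ga" (genetic/simulated-annealing subset search; needs ``q``).
        """
        if strategy == "stepwise":
            trace = _search.stepwise_search(
                self.C2, self.residuals, self.allowed_mask, stop=stop,
                optimizer=optimizer, region_labels=self.region_labels,
                ga_config=config)
            return StructureSearchResults(model=self, path_model=trace.model, trace=trace)
        if q is None:
            raise DimensionError(f"strategy {strategy!r} requires q")
        if strategy == "exhaustive":
            cand = _search.exhaustive_structure_search(
                self.C2, self.residuals, self.allowed_mask, q,
                region_labels=self.region_labels)
        elif strategy == "ga":
            cand = _search.ga_structure_search(
                self.C2, self.residuals, self.allowed_mask, q,
                config=config, region_labels=self.region_labels)
        else:
            raise DimensionError(f"unknown strategy {strategy!r}")
        return StructureSearchResults(model=self, path_model=cand.model, candidate=cand)

    # -- internals shared with results ------------------------------------
    def _implied(self, path_model: PathModel) -> np.ndarray:
        if isinstance(self.residuals, str):
            r = unit_diagonal_residuals(path_model.K)
        else:
            r = self.residuals
        return implied_correlation(path_model, r)


@dataclass(frozen=True)
class SEMResults:
    """Fitted coefficients for a fixed structure, with diagnostics."""

    model: EffectiveConnectivitySEM
    path_model: PathModel
    opt_result: object

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.path_model.theta, index=_edge_labels(self.path_model),
                         name="coefficient")

    @property
    def implied(self) -> np.ndarray:
        return self.model._implied(self.path_model)

    @property
    def discrepancy(self) -> DiscrepancyValue:
        return ml_discrepancy(self.implied, self.model.C2)

    @property
    def fvalue(self) -> float:
        return float(self.opt_result.F_best)

    @property
    def diag_deviation(self) -> float:
        return diag_deviation(self.implied)

    def summary(self) -> str:
        d = self.discrepancy
        lines = [
            "Effective-connectivity SEM results",
            "=" * 46,
            f"regions:             {self.path_model.p}",
            f"free paths (q):      {self.path_model.q}",
            f"ML discrepancy F:    {d.F:.6g}",
            f"  log|C1|:           {d.log_det_C1:.6g}",
            f"  tr(C2 C1^-1):      {d.trace_term:.6g}",
            f"  log|C2|:           {d.log_det_C2:.6g}",
            f"max |diag(C1)-1|:    {self.diag_deviation:.3g}",
            f"function evals:      {self.opt_result.n_evaluations}",
            "-" * 46,
            "path                coefficient",
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<20s}{value: .4f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class StructureSearchResults:
    """Outcome of a structure search (stepwise trace or subset candidate)."""

    model: EffectiveConnectivitySEM
    path_model: PathModel
    trace: _search.SearchTrace | None = None
    candidate: _search.StructureCandidate | None = None

    @property
    def fvalue(self) -> float:
        if self.trace is not None:
            return self.trace.F_final
        return float(self.candidate.F_min)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.path_model.theta, index=_edge_labels(self.path_model),
                         name="coefficient")

    def trace_frame(self) -> pd.DataFrame:
        """Stepwise trace as one row per iteration (empty for subset search)."""
        if self.trace is None:
            return pd.DataFrame()
        labels = self.path_model.region_labels
        return pd.DataFrame([
            {
                "step": rec.index,
                "freed_source": labels[rec.freed_path[0]],
                "freed_target": labels[rec.freed_path[1]],
                "lm_score": rec.lm_scores[rec.freed_path],
                "F": rec.F,
                "fit_index": rec.fit_index,
            }
            for rec in self.trace.steps
        ])

    def summary(self) -> str:
        lines = [
            "Effective-connectivity structure search",
            "=" * 46,
            f"regions:          {self.path_model.p}",
            f"free paths (q):   {self.path_model.q}",
            f"minimized F:      {self.fvalue:.6g}",
        ]
        if self.trace is not None:
            lines.append(f"stopped:          {self.trace.stopped_reason}")
            lines.append(f"null-model F:     {self.trace.F_null:.6g}")
        if self.candidate is not None and self.candidate.n_enumerated:
            lines.append(f"structures tried: {self.candidate.n_enumerated}")
        lines += ["-" * 46, "path                coefficient"]
        for name, value in self.params.items():
            lines.append(f"{name:<20s}{value: .4f}")
        return "\n".join(lines)
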