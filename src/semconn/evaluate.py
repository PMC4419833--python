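"""Comparison machinery: trial grading, repeat-failure probability, and
side-by-side connectivity-map tables.

A candidate optimizer's run is graded *Improved* when its minimized F is
strictly below the reference value and *Worsened* otherwise (ties count as
Worsened). Because independent restarts fail independently, the probability
that k repeats all come out Worsened is p_worse**k — e.g. a per-run worse
rate of 0.44 over 10 repeats leaves 0.44**10 ≈ 0.027%, i.e. 99.973%
confidence that at least one repeat improves on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .exceptions import DomainError, LabelingError
from .sem import PathModel

__all__ = [
    "TrialRecord",
    "EdgeStatus",
    "EdgeComparison",
    "grade_trials",
    "repeat_worse_probability",
    "format_percent",
    "compare_maps",
    "comparison_table",
]


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    F_candidate: float
    F_reference: float
    grade: str  # Improved | Worsened


class EdgeStatus(str, Enum):
    NONE = "none"
    A_TO_B = "a_to_b"
    B_TO_A = "b_to_a"
    BIDIRECTIONAL = "bidirectional"


@dataclass(frozen=True)
class EdgeComparison:
    pair: tuple[str, str]  # unordered, lexicographic
    status_a: EdgeStatus
    status_b: EdgeStatus
    sign_a: str  # e.g. "+/-" for bidirectional, "+", "-", ""
    sign_b: str
    agreement: bool


def grade_trials(F_candidates, F_reference: float) -> tuple[list[TrialRecord], float]:
    """Grade each candidate F against a fixed reference F.

    Improved iff F_candidate < F_reference (strict); ties are Worsened.
    Returns the per-trial records and the improved fraction.
    """
    F_candidates = list(F_candidates)
    if not F_candidates:
        raise DomainError("no trials to grade")
    if not np.all(np.isfinite(F_candidates)) or not np.isfinite(F_reference):
        raise DomainError("all F values must be finite")
    records = [
        TrialRecord(
            trial=i + 1,
            F_candidate=float(f),
            F_reference=float(F_reference),
            grade="Improved" if f < F_reference else "Worsened",
        )
        for i, f in enumerate(F_candidates)
    ]
    frac = sum(r.grade == "Improved" for r in records) / len(records)
    return records, frac


def repeat_worse_probability(p_worse: float, k: int) -> float:
    """Probability that k independent repeats all come out Worsened."""
    if not 0.0 <= p_worse <= 1.0:
        raise DomainError(f"p_worse must be in [0, 1], got {p_worse}")
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    return float(p_worse**k)


def format_percent(probability: float, sig: int = 2) -> str:
    """Render a probability as a percentage with ``sig`` significant figures
    (e.g. 0.44**10 -> '0.027%'; its complement -> '99.973%')."""
    from math import floor, log10

    pct = 100.0 * probability
    if pct == 0:
        return "0%"
    if pct >= 99:
        # keep the informative digits of the complement (99.973%, not 1e2%)
        comp = 100.0 - pct
        decimals = (sig - 1 - floor(log10(comp)) if comp > 0 else 0)
        return f"{pct:.{max(decimals, 0)}f}%"
    decimals = sig - 1 - floor(log10(abs(pct)))
    return f"{pct:.{max(decimals, 0)}f}%"


def _sign_tag(*coeffs: float) -> str:
    return "/".join("+" if c > 0 else "-" for c in coeffs)


def _classify(model: PathModel, a: int, b: int, tol: float) -> tuple[EdgeStatus, str]:
    ab = model.K[b, a]  # a -> b
    ba = model.K[a, b]  # b -> a
    has_ab, has_ba = abs(ab) > tol, abs(ba) > tol
    if has_ab and has_ba:
        return EdgeStatus.BIDIRECTIONAL, _sign_tag(ab, ba)
    if has_ab:
        return EdgeStatus.A_TO_B, _sign_tag(ab)
    if has_ba:
        return EdgeStatus.B_TO_A, _sign_tag(ba)
    return EdgeStatus.NONE, ""


def compare_maps(
    model_a: PathModel,
    model_b: PathModel,
    edge_tolerance: float = 1e-6,
) -> list[EdgeComparison]:
    """Classify every unordered region pair in two connectivity maps.

    One row per pair, ordered lexicographically by the pair labels; a
    coefficient counts as a connection when |coef| > edge_tolerance. The sign
    of each present coefficient is carried as a +/- tag.
    """
    if model_a.p != model_b.p or model_a.region_labels != model_b.region_labels:
        raise LabelingError(
            f"models disagree on regions: {model_a.region_labels} vs {model_b.region_labels}"
        )
    labels = model_a.region_labels
    rows = []
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            a, b = order[ai], order[bi]
            status_a, sign_a = _classify(model_a, a, b, edge_tolerance)
            status_b, sign_b = _classify(model_b, a, b, edge_tolerance)
            rows.append(EdgeComparison(
                pair=(labels[a], labels[b]),
                status_a=status_a,
                status_b=status_b,
                sign_a=sign_a,
                sign_b=sign_b,
                agreement=status_a == status_b,
            ))
    return rows


_ARROWS = {
    EdgeStatus.NONE: "No connection",
    EdgeStatus.A_TO_B: "ROI 1 -> ROI 2",
    EdgeStatus.B_TO_A: "ROI 1 <- ROI 2",
    EdgeStatus.BIDIRECTIONAL: "ROI 1 <-> ROI 2",
}


def comparison_table(rows: list[EdgeComparison], name_a: str = "model_a",
                     name_b: str = "model_b") -> pd.DataFrame:
    """Render edge comparisons as a pair-per-row table (No., ROI1, ROI2,
    one column per model, agreement)."""
    return pd.DataFrame([
        {
            "No.": i + 1,
            "ROI1": r.pair[0],
            "ROI2": r.pair[1],
            name_a: _ARROWS[r.status_a] + (f" ({r.sign_a})" if r.sign_a else ""),
            name_b: _ARROWS[r.status_b] + (f" ({r.sign_b})" if r.sign_b else ""),
            "agreement": r.agreement,
        }
        for i, r in enumerate(rows)
    ])
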