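"""Structure search: deciding which paths are free.

Three strategies are provided.

* :func:`stepwise_search` — the automated stepwise procedure: start from the
  null model (all coefficients constrained to zero), compute a Lagrange-
  multiplier (modification-index) score for every constrained-but-allowed
  path, free the highest-scoring path, re-minimize F, and repeat until the
  fit is acceptable, the free-path budget (default 12) is reached, or no
  candidates remain.
* :func:`exhaustive_structure_search` — enumerate every q-subset of the
  allowed paths with a nested local minimization; exact, used as the oracle
  at desk scale (the full problem would enumerate C(30, 12) = 86,493,225
  structures).
* :func:`ga_structure_search` — a genetic/simulated-annealing search over
  fixed-cardinality subsets and their coefficients jointly, for instances
  where enumeration is infeasible.

Tie-breaking is lexicographic on (source index, target index) everywhere, so
all searches are deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .exceptions import DimensionError, DomainError
from .optimize import GAConfig, SEMProblem, hpgsa_minimize, minimize_local, sa_accept, PENALTY_BASE
from .sem import PathModel, count_candidate_models

logger = logging.getLogger(__name__)

__all__ = [
    "StepRecord",
    "SearchTrace",
    "StructureCandidate",
    "StopRule",
    "lagrange_scores",
    "stepwise_search",
    "exhaustive_structure_search",
    "ga_structure_search",
]

Edge = tuple[int, int]  # (source, target)


@dataclass(frozen=True)
class StopRule:
    """Stopping rule for the stepwise search.

    Stops when minimized F drops below ``fit_tolerance`` (the trace records
    raw F so any parsimony-adjusted index can be recomputed downstream) or
    when ``max_free_paths`` coefficients are free.
    """

    max_free_paths: int = 12
    fit_tolerance: float = 0.05


@dataclass(frozen=True)
class StepRecord:
    index: int
    freed_path: Edge
    lm_scores: dict[Edge, float]
    theta: np.ndarray
    F: float
    fit_index: float


@dataclass(frozen=True)
class SearchTrace:
    steps: tuple[StepRecord, ...]
    stopped_reason: str  # max_paths | fit_threshold | no_candidates
    model: PathModel
    F_null: float

    @property
    def F_final(self) -> float:
        return self.steps[-1].F if self.steps else self.F_null


@dataclass(frozen=True)
class StructureCandidate:
    free_set: tuple[Edge, ...]
    F_min: float
    theta_at_min: np.ndarray  # aligned with free_set order
    model: PathModel
    n_enumerated: int = 0

    @property
    def q(self) -> int:
        return len(self.free_set)


def _allowed_edges(allowed_mask: np.ndarray) -> list[Edge]:
    """Allowed paths as (source, target), sorted lexicographically."""
    targets, sources = np.nonzero(np.asarray(allowed_mask, dtype=bool))
    return sorted((int(s), int(t)) for t, s in zip(targets, sources))


def _mask_from_edges(edges: Sequence[Edge], p: int) -> np.ndarray:
    mask = np.zeros((p, p), dtype=bool)
    for s, t in edges:
        mask[t, s] = True
    return mask


def _theta_rowmajor(edges: Sequence[Edge], coeffs: Sequence[float], p: int) -> np.ndarray:
    """Pack edge coefficients into the row-major order of the free mask."""
    K = np.zeros((p, p))
    for (s, t), c in zip(edges, coeffs):
        K[t, s] = c
    return K[_mask_from_edges(edges, p)]


def _edges_rowmajor(mask: np.ndarray) -> list[Edge]:
    """Edges of a mask in its row-major (target, source) scan order."""
    return [(int(s), int(t)) for t, s in zip(*np.nonzero(mask))]


def lagrange_scores(
    model: PathModel,
    residuals,
    C2: np.ndarray,
    step: float = 1e-4,
) -> dict[Edge, float]:
    """Modification-index score for every allowed-but-constrained path.

    For each candidate coefficient the score is g^2 / (2h), with g and h the
    first and second partial derivatives of F with respect to that
    coefficient at zero, estimated by central differences while the free
    coefficients stay at their current values. A flat or concave direction
    (h <= 0) gets g^2 / (2|h| + eps) with a warning. Already-free paths are
    absent from the table.
    """
    p = model.p
    theta0 = model.theta
    scores: dict[Edge, float] = {}
    for s, t in _allowed_edges(model.allowed_mask):
        if model.free_mask[t, s]:
            continue
        trial_mask = model.free_mask.copy()
        trial_mask[t, s] = True
        prob = SEMProblem(trial_mask, residuals, C2)
        # position of the new coefficient within the row-major packing
        pos = int(np.cumsum(trial_mask.ravel())[t * p + s] - 1)
        base = np.insert(theta0, pos, 0.0)
        f0 = prob.objective(base)
        plus = base.copy()
        plus[pos] = step
        minus = base.copy()
        minus[pos] = -step
        fp, fm = prob.objective(plus), prob.objective(minus)
        g = (fp - fm) / (2.0 * step)
        h = (fp - 2.0 * f0 + fm) / step**2
        if h <= 0:
            warnings.warn(
                f"flat or concave direction for path {s}->{t} (h={h:.3g}); "
                "using |h| in the modification index",
                RuntimeWarning,
                stacklevel=2,
            )
            h = abs(h) + 1e-12
        scores[(s, t)] = float(g**2 / (2.0 * h))
    return scores


def _minimize(problem: SEMProblem, theta_init: np.ndarray, optimizer, ga_config) :
    if callable(optimizer):
        return optimizer(problem, theta_init)
    if optimizer == "powell":
        return minimize_local(problem.objective, theta_init)
    if optimizer == "hpgsa":
        cfg = ga_config or GAConfig(population_size=64, max_generations=60, n_islands=2)
        run = hpgsa_minimize(problem, cfg)
        # warm-started local refinement keeps the trace monotone
        local = minimize_local(problem.objective, theta_init)
        return run if run.F_best <= local.F_best else local
    raise DomainError(f"unknown optimizer {optimizer!r}")


def stepwise_search(
    C2: np.ndarray,
    residuals,
    allowed_mask: np.ndarray,
    stop: StopRule | None = None,
    optimizer: str | Callable = "powell",
    region_labels=None,
    ga_config: GAConfig | None = None,
) -> SearchTrace:
    """Stepwise Lagrange-multiplier model search from the null model.

    Each iteration frees the constrained allowed path with the largest
    modification index (ties broken lexicographically on (source, target)),
    then re-minimizes F warm-started at the previous optimum with the new
    coefficient at zero — so minimized F is nonincreasing across steps.
    """
    stop = stop or StopRule()
    allowed_mask = np.asarray(allowed_mask, dtype=bool)
    if not allowed_mask.any():
        raise DomainError("allowed_mask is empty: no paths to consider")
    p = allowed_mask.shape[0]
    model = PathModel.null(allowed_mask, region_labels=region_labels)
    F_null = float(SEMProblem(model.free_mask, residuals, C2).objective(np.zeros(0)))
    steps: list[StepRecord] = []
    F_current = F_null
    if F_current < stop.fit_tolerance:
        return SearchTrace(steps=(), stopped_reason="fit_threshold", model=model, F_null=F_null)
    while True:
        scores = lagrange_scores(model, residuals, C2)
        if not scores:
            return SearchTrace(tuple(steps), "no_candidates", model, F_null)
        # max score; ties lexicographic on (source, target)
        best_edge = min(scores, key=lambda e: (-scores[e], e))
        new_free = model.free_mask.copy()
        s, t = best_edge
        new_free[t, s] = True
        prob = SEMProblem(new_free, residuals, C2)
        pos = int(np.cumsum(new_free.ravel())[t * p + s] - 1)
        theta_init = np.insert(model.theta, pos, 0.0)
        run = _minimize(prob, theta_init, optimizer, ga_config)
        model = PathModel(
            K=np.zeros((p, p)), allowed_mask=allowed_mask,
            free_mask=new_free, region_labels=region_labels,
        ).with_theta(run.theta_best)
        F_current = float(run.F_best)
        steps.append(StepRecord(
            index=len(steps) + 1,
            freed_path=best_edge,
            lm_scores=scores,
            theta=np.asarray(run.theta_best, dtype=float),
            F=F_current,
            fit_index=F_current,
        ))
        if F_current < stop.fit_tolerance:
            return SearchTrace(tuple(steps), "fit_threshold", model, F_null)
        if model.q >= stop.max_free_paths:
            return SearchTrace(tuple(steps), "max_paths", model, F_null)


def _candidate_from_subset(
    subset: tuple[Edge, ...],
    theta_init: np.ndarray,
    residuals,
    C2: np.ndarray,
    allowed_mask: np.ndarray,
    region_labels,
) -> StructureCandidate:
    p = C2.shape[0]
    mask = _mask_from_edges(subset, p)
    prob = SEMProblem(mask, residuals, C2)
    run = minimize_local(prob.objective, theta_init) if len(subset) else None
    F = float(run.F_best) if run else float(prob.objective(np.zeros(0)))
    theta_rm = run.theta_best if run else np.zeros(0)
    model = PathModel(
        K=np.zeros((p, p)), allowed_mask=np.asarray(allowed_mask, dtype=bool),
        free_mask=mask, region_labels=region_labels,
    ).with_theta(theta_rm)
    # report coefficients in the subset's (source, target) order
    order = _edges_rowmajor(mask)
    coef = {e: c for e, c in zip(order, theta_rm)}
    subset_sorted = tuple(sorted(subset))
    return StructureCandidate(
        free_set=subset_sorted,
        F_min=F,
        theta_at_min=np.array([coef.get(e, 0.0) for e in subset_sorted]),
        model=model,
    )


def exhaustive_structure_search(
    C2: np.ndarray,
    residuals,
    allowed_mask: np.ndarray,
    q: int,
    cap: int = 100_000,
    region_labels=None,
) -> StructureCandidate:
    """Enumerate every q-subset of the allowed paths, minimizing F in each.

    Exact but exponential: refuses when the candidate count exceeds ``cap``.
    Ties in minimized F are broken lexicographically on the sorted edge set.
    """
    edges = _allowed_edges(allowed_mask)
    if q > len(edges):
        raise DomainError(f"q={q} exceeds the {len(edges)} allowed paths")
    n_cand = count_candidate_models(len(edges), q)
    if n_cand > cap:
        raise DomainError(
            f"{n_cand} candidate structures exceed the enumeration cap {cap}"
        )
    best: StructureCandidate | None = None
    for subset in combinations(edges, q):
        cand = _candidate_from_subset(
            subset, np.zeros(q), residuals, C2, allowed_mask, region_labels)
        if best is None or cand.F_min < best.F_min - 1e-12 or (
            abs(cand.F_min - best.F_min) <= 1e-12 and cand.free_set < best.free_set
        ):
            best = cand
    return replace(best, n_enumerated=n_cand)


def ga_structure_search(
    C2: np.ndarray,
    residuals,
    allowed_mask: np.ndarray,
    q: int,
    config: GAConfig | None = None,
    region_labels=None,
    polish_top: int = 3,
) -> StructureCandidate:
    """Joint genetic/simulated-annealing search over structures and
    coefficients.

    The chromosome is a fixed-cardinality subset of the allowed paths plus a
    real coefficient per member. Subset crossover keeps the parents'
    intersection and fills the remaining slots uniformly from the symmetric
    difference; subset mutation swaps one member for one non-member — both
    preserve |free_set| = q by construction. Offspring are accepted against
    their parent by the simulated-annealing rule. The best ``polish_top``
    distinct structures found are refined by Powell minimization before the
    winner is returned; seed-deterministic throughout.
    """
    config = config or GAConfig(population_size=128, max_generations=50)
    edges = _allowed_edges(allowed_mask)
    n_edges = len(edges)
    if q > n_edges:
        raise DomainError(f"q={q} exceeds the {n_edges} allowed paths")
    p = C2.shape[0]
    if q == 0:
        return _candidate_from_subset((), np.zeros(0), residuals, C2,
                                      allowed_mask, region_labels)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.coefficient_bounds
    sigma = 0.1 * (hi - lo)
    pop_size = config.population_size

    prob_cache: dict[tuple[int, ...], SEMProblem] = {}

    def fitness(subset: tuple[int, ...], coeffs: np.ndarray) -> float:
        prob = prob_cache.get(subset)
        if prob is None:
            prob = SEMProblem(_mask_from_edges([edges[i] for i in subset], p), residuals, C2)
            prob_cache[subset] = prob
        theta = _theta_rowmajor([edges[i] for i in subset], coeffs, p)
        return prob.objective(theta)

    subsets = [tuple(sorted(rng.choice(n_edges, size=q, replace=False))) for _ in range(pop_size)]
    coeffs = [rng.uniform(-1.0, 1.0, size=q) for _ in range(pop_size)]
    fits = np.array([fitness(s, c) for s, c in zip(subsets, coeffs)])

    best_seen: dict[tuple[int, ...], tuple[float, np.ndarray]] = {}

    def note(subset, coeff, f):
        cur = best_seen.get(subset)
        if cur is None or f < cur[0]:
            best_seen[subset] = (f, coeff.copy())

    for s, c, f in zip(subsets, coeffs, fits):
        note(s, c, f)

    g_best = float(fits.min())
    stall = 0
    for gen in range(config.max_generations):
        T = config.sa_initial_temperature * config.sa_cooling_factor**gen
        elite = int(np.argmin(fits))
        elite_state = (subsets[elite], coeffs[elite].copy(), float(fits[elite]))
        for slot in range(pop_size):
            i, j = rng.integers(0, pop_size, size=2)
            p1 = int(i if fits[i] <= fits[j] else j)
            i, j = rng.integers(0, pop_size, size=2)
            p2 = int(i if fits[i] <= fits[j] else j)
            c1 = dict(zip(subsets[p1], coeffs[p1]))
            c2 = dict(zip(subsets[p2], coeffs[p2]))
            if rng.random() < config.crossover_rate:
                inter = sorted(set(subsets[p1]) & set(subsets[p2]))
                sym = sorted(set(subsets[p1]) ^ set(subsets[p2]))
                fill = rng.choice(len(sym), size=q - len(inter), replace=False) if sym else []
                child_subset = tuple(sorted(inter + [sym[k] for k in fill]))
                child_coeffs = np.array([
                    0.5 * (c1[e] + c2[e]) if e in c1 and e in c2 else c1.get(e, c2.get(e))
                    for e in child_subset
                ])
            else:
                child_subset = subsets[p1]
                child_coeffs = coeffs[p1].copy()
            if rng.random() < config.mutation_rate and len(child_subset) < n_edges:
                outside = sorted(set(range(n_edges)) - set(child_subset))
                drop = int(rng.integers(0, q))
                add = int(outside[int(rng.integers(0, len(outside)))])
                members = list(child_subset)
                vals = dict(zip(members, child_coeffs))
                del vals[members[drop]]
                vals[add] = float(rng.uniform(-1.0, 1.0))
                child_subset = tuple(sorted(vals))
                child_coeffs = np.array([vals[e] for e in child_subset])
            mutate = rng.random(q) < config.mutation_rate
            child_coeffs = np.clip(
                np.where(mutate, child_coeffs + rng.normal(0.0, sigma, size=q), child_coeffs),
                lo, hi)
            f_child = fitness(child_subset, child_coeffs)
            note(child_subset, child_coeffs, f_child)
            if sa_accept(f_child - fits[slot], T, rng.random()):
                subsets[slot] = child_subset
                coeffs[slot] = child_coeffs
                fits[slot] = f_child
        if fits.min() > elite_state[2]:
            worst = int(np.argmax(fits))
            subsets[worst], coeffs[worst], fits[worst] = elite_state
        if fits.min() < g_best - config.stall_tolerance:
            g_best = float(fits.min())
            stall = 0
        else:
            stall += 1
            if stall >= config.stall_generations:
                break

    # polish the best distinct structures with nested local minimization
    ranked = sorted(best_seen.items(), key=lambda kv: (kv[1][0], kv[0]))
    best_cand: StructureCandidate | None = None
    for subset, (f, coeff) in ranked[:max(1, polish_top)]:
        edge_subset = tuple(edges[i] for i in subset)
        theta_init = _theta_rowmajor(edge_subset, coeff, p)
        cand = _candidate_from_subset(edge_subset, theta_init, residuals, C2,
                                      allowed_mask, region_labels)
        if best_cand is None or cand.F_min < best_cand.F_min - 1e-12 or (
            abs(cand.F_min - best_cand.F_min) <= 1e-12 and cand.free_set < best_cand.free_set
        ):
            best_cand = cand
    return best_cand
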