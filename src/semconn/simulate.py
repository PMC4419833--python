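"""Synthetic ground-truth networks and multi-subject regional time series.

The generator emulates the statistical structure the path model assumes: a
stimulus-locked latent residual series u(t), drawn i.i.d. across timepoints,
drives the latent regional signal through the network,

    v(t) = (I - K)^{-1} u(t)

Each subject observes the same latent signal plus independent Gaussian
observation noise, so the pooled subjects x timepoints matrix of a region has
a dominant shared component recoverable by SVD — the situation the
eigentimeseries extraction is designed for. A ``subject_mode="independent"``
option instead draws a fresh latent realization per subject (no shared
component), useful for stress-testing the pooling step.

By default the residual standard deviations are rescaled so the latent
signal has unit variance in every region (the implied matrix is then a true
correlation matrix), matching the standardized regime of real regional data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DimensionError, DomainError, GenerationError, SingularModelError
from .sem import PathModel, count_possible_paths
from .timeseries import RegionalTimeSeries, standardize

__all__ = [
    "SyntheticScenario",
    "generate_network",
    "simulate_timeseries",
    "make_benchmark_suite",
    "unit_variance_residual_sd",
    "anatomical_mask",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """A ground-truth path model plus sampling dimensions and noise levels."""

    truth: PathModel
    residual_sd: np.ndarray
    m: int = 5
    n: int = 500
    observation_noise_sd: float = 0.3
    subject_mode: str = "shared"  # shared | independent
    ar_coefficient: float = 0.0  # optional AR(1) residual structure
    seed: int = 0

    def __post_init__(self):
        sd = np.asarray(self.residual_sd, dtype=float)
        object.__setattr__(self, "residual_sd", sd)
        p = self.truth.p
        if sd.shape != (p,):
            raise DimensionError(f"residual_sd shape {sd.shape}, expected ({p},)")
        if np.any(sd <= 0) or self.observation_noise_sd < 0:
            raise DomainError("residual sds must be positive, noise sd nonnegative")
        if self.n < p:
            raise DimensionError(f"need n >= p, got n={self.n}, p={p}")
        rho = np.max(np.abs(np.linalg.eigvals(self.truth.K)))
        if rho >= 1:
            raise SingularModelError(f"spectral radius of K is {rho:.3f} >= 1")
        if self.subject_mode not in ("shared", "independent"):
            raise DomainError(f"unknown subject_mode {self.subject_mode!r}")
        if not -1 < self.ar_coefficient < 1:
            raise DomainError("ar_coefficient must lie in (-1, 1)")

    @property
    def implied_covariance(self) -> np.ndarray:
        """Analytic latent covariance (I-K)^{-1} diag(sd^2) (I-K)^{-T}."""
        p = self.truth.p
        B = np.linalg.solve(np.eye(p) - self.truth.K, np.eye(p))
        S = (B * self.residual_sd**2) @ B.T
        return 0.5 * (S + S.T)


def unit_variance_residual_sd(K: np.ndarray) -> np.ndarray:
    """Residual sds under which every latent signal has unit variance.

    Solves (B∘B) sd^2 = 1 with B = (I-K)^{-1}; raises when the network
    admits no positive solution (signal variance from parents already
    exceeds one somewhere).
    """
    p = K.shape[0]
    B = np.linalg.solve(np.eye(p) - K, np.eye(p))
    var = np.linalg.solve(B * B, np.ones(p))
    if np.any(var <= 0):
        raise GenerationError("no positive residual variances give unit latent variance")
    return np.sqrt(var)


def anatomical_mask(truth: PathModel) -> np.ndarray:
    """Allowed-path mask emulating anatomical constraints around a truth.

    Directions are not identifiable from correlation data alone (Markov-
    equivalent reorientations fit identically), so real analyses orient the
    model space with an anatomical edge list. This helper builds that list
    for a synthetic truth: every true path is allowed, both directions are
    allowed for region pairs the truth does not connect, and the reversal of
    a true path is excluded.
    """
    p = truth.p
    allowed = ~np.eye(p, dtype=bool)
    reversed_true = truth.free_mask.T & ~truth.free_mask
    return allowed & ~reversed_true


def generate_network(
    p: int,
    q: int,
    coeff_low: float = 0.3,
    coeff_high: float = 0.7,
    seed: int = 0,
    max_resamples: int = 1000,
    region_labels=None,
    allow_reciprocal: bool = False,
) -> PathModel:
    """Random ground-truth network: q distinct directed non-self paths with
    coefficients drawn uniformly from ±[coeff_low, coeff_high], resampled
    until the spectral radius of K is below 1 and the network supports a
    unit-variance standardization.

    By default each unordered region pair carries at most one directed path:
    a reciprocal pair with near-cancelling coefficients can be
    observationally equivalent to no connection at all, which makes a poor
    ground truth for recovery benchmarks. Pass ``allow_reciprocal=True`` to
    sample from all ordered pairs (note p(p-1)/2 is then the feasible q
    limit no longer).
    """
    if not 0 < coeff_low <= coeff_high:
        raise DomainError("need 0 < coeff_low <= coeff_high")
    n_paths = count_possible_paths(p) if allow_reciprocal else p * (p - 1) // 2
    if q > n_paths:
        raise DomainError(f"q={q} exceeds the {n_paths} available paths for p={p}")
    rng = np.random.default_rng(seed)
    if allow_reciprocal:
        pairs = [(s, t) for t in range(p) for s in range(p) if s != t]
    else:
        pairs = [(s, t) for s in range(p) for t in range(s + 1, p)]
    allowed = np.ones((p, p), dtype=bool)
    np.fill_diagonal(allowed, False)
    for _ in range(max_resamples):
        idx = rng.choice(len(pairs), size=q, replace=False)
        K = np.zeros((p, p))
        mask = np.zeros((p, p), dtype=bool)
        for k in idx:
            s, t = pairs[k]
            if not allow_reciprocal and rng.random() < 0.5:
                s, t = t, s
            mag = rng.uniform(coeff_low, coeff_high)
            K[t, s] = mag * (1 if rng.random() < 0.5 else -1)
            mask[t, s] = True
        if np.max(np.abs(np.linalg.eigvals(K))) >= 1:
            continue
        try:
            unit_variance_residual_sd(K)
        except GenerationError:
            continue
        return PathModel(K=K, allowed_mask=allowed, free_mask=mask,
                         region_labels=region_labels)
    raise GenerationError(
        f"could not draw a stable {q}-path network on {p} nodes in {max_resamples} tries"
    )


def simulate_timeseries(
    scenario: SyntheticScenario,
) -> tuple[list[RegionalTimeSeries], np.ndarray]:
    """Simulate standardized multi-subject regional time series.

    Returns one :class:`RegionalTimeSeries` per region plus the analytic
    latent correlation matrix for oracle checks. The latent residual u(t) is
    i.i.d. normal across timepoints (optionally AR(1) when
    ``ar_coefficient`` is nonzero); subjects observe the shared latent signal
    with independent observation noise unless ``subject_mode="independent"``.
    """
    rng = np.random.default_rng(scenario.seed)
    p, m, n = scenario.truth.p, scenario.m, scenario.n
    A = np.eye(p) - scenario.truth.K
    n_latents = 1 if scenario.subject_mode == "shared" else m

    def draw_latent():
        e = rng.normal(size=(p, n)) * scenario.residual_sd[:, None]
        if scenario.ar_coefficient:
            # stationary AR(1) with the same marginal sd as the white case
            phi = scenario.ar_coefficient
            c = np.sqrt(1 - phi**2)
            u = np.empty_like(e)
            u[:, 0] = e[:, 0]
            for t in range(1, n):
                u[:, t] = phi * u[:, t - 1] + c * e[:, t]
        else:
            u = e
        return np.linalg.solve(A, u)

    latents = [draw_latent() for _ in range(n_latents)]
    regions = []
    raw = np.empty((p, m, n))
    for subj in range(m):
        v = latents[0] if scenario.subject_mode == "shared" else latents[subj]
        noise = rng.normal(size=(p, n)) * scenario.observation_noise_sd
        raw[:, subj, :] = v + noise
    for i in range(p):
        regions.append(standardize(raw[i], region_id=scenario.truth.region_labels[i]))
    S = scenario.implied_covariance
    d = np.sqrt(np.diag(S))
    true_corr = S / np.outer(d, d)
    return regions, true_corr


def make_benchmark_suite(
    out_dir,
    sizes: dict[int, int] | None = None,
    seeds=range(5),
    n: int = 500,
    m: int = 5,
) -> list[Path]:
    """Write a suite of synthetic scenarios to disk.

    ``sizes`` maps region count p to true path count q; the default spans
    p in {2, 3, 4, 6}. Each scenario directory holds truth_edges.csv, one
    region_<i>.csv (m x n) per region, and scenario.json with all parameters
    and the seed; regeneration with the same seeds is byte-identical.
    """
    from .sem import write_edge_list

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sizes is None:
        sizes = {2: 1, 3: 2, 4: 3, 6: 6}
    written = []
    for p, q in sorted(sizes.items()):
        for seed in seeds:
            truth = generate_network(p, q, seed=seed * 1000 + p)
            sd = unit_variance_residual_sd(truth.K)
            scenario = SyntheticScenario(
                truth=truth, residual_sd=sd, m=m, n=n, seed=seed * 1000 + p + 1)
            regions, true_corr = simulate_timeseries(scenario)
            d = out_dir / f"p{p}_q{q}_seed{seed}"
            d.mkdir(parents=True, exist_ok=True)
            write_edge_list(truth, d / "truth_edges.csv")
            for ts in regions:
                pd.DataFrame(ts.data).to_csv(d / f"region_{ts.region_id}.csv",
                                             index=False, header=False)
            (d / "scenario.json").write_text(json.dumps({
                "p": p, "q": q, "m": m, "n": n,
                "seed": scenario.seed,
                "network_seed": seed * 1000 + p,
                "residual_sd": sd.tolist(),
                "observation_noise_sd": scenario.observation_noise_sd,
                "subject_mode": scenario.subject_mode,
                "true_correlation": true_corr.tolist(),
            }, indent=2))
            written.append(d)
    return written
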