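import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_pd(rng: np.random.Generator, p: int, unit_diagonal: bool = True) -> np.ndarray:
    """Random symmetric positive-definite matrix (optionally a correlation)."""
    A = rng.normal(size=(p, p + 3))
    C = A @ A.T / (p + 3)
    if unit_diagonal:
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return 0.5 * (C + C.T)


@pytest.fixture
def two_node_problem():
    """Observed correlation rho=0.6 with one free path R1 -> R2.

    With residual variances (1, 1 - rho^2) the implied matrix at theta = rho
    equals the observed matrix exactly, so the minimizer is theta = 0.6 with
    F = 0.
    """
    from semconn import SEMProblem

    C2 = np.array([[1.0, 0.6], [0.6, 1.0]])
    free = np.array([[False, False], [True, False]])
    return SEMProblem(free, np.array([1.0, 1 - 0.6**2]), C2)


@pytest.fixture
def chain3():
    """Analytic 3-region chain R1 -> R2 -> R3 with known coefficients."""
    from semconn import PathModel
    from semconn.simulate import unit_variance_residual_sd

    p = 3
    K = np.zeros((p, p))
    K[1, 0] = 0.7  # R1 -> R2
    K[2, 1] = 0.5  # R2 -> R3
    mask = K != 0
    allowed = ~np.eye(p, dtype=bool)
    truth = PathModel(K=K, allowed_mask=allowed, free_mask=mask)
    sd = unit_variance_residual_sd(K)
    B = np.linalg.solve(np.eye(p) - K, np.eye(p))
    C2 = (B * sd**2) @ B.T
    return truth, sd, 0.5 * (C2 + C2.T)
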