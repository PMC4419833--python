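import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from semconn import (
    PathModel,
    count_candidate_models,
    count_possible_paths,
    implied_correlation,
    ml_discrepancy,
)
from semconn.exceptions import (
    DefinitenessError,
    DimensionError,
    DomainError,
    SingularModelError,
)
from semconn.sem import (
    K_to_theta,
    model_from_json,
    model_to_json,
    read_edge_list,
    theta_to_K,
    unit_diagonal_residuals,
    write_edge_list,
)

from conftest import random_pd


class TestThetaPacking:
    def test_empty_mask_gives_zero_matrix(self):
        K = theta_to_K(np.zeros(0), np.zeros((3, 3), dtype=bool))
        assert (K == 0).all()

    def test_single_entry(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[2, 1] = True
        K = theta_to_K(np.array([0.5]), mask)
        assert K[2, 1] == 0.5
        assert np.count_nonzero(K) == 1

    @given(st.integers(0, 2**32 - 1))
    def test_roundtrip_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 6))
        mask = rng.random((p, p)) < 0.5
        np.fill_diagonal(mask, False)
        theta = rng.normal(size=int(mask.sum()))
        assert (K_to_theta(theta_to_K(theta, mask), mask) == theta).all()

    def test_length_mismatch_rejected(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 0] = True
        with pytest.raises(DimensionError):
            theta_to_K(np.array([1.0, 2.0]), mask)


class TestImpliedCorrelation:
    def test_null_model_gives_diagonal_residuals(self):
        r = np.array([0.3, 0.7, 1.0])
        model = PathModel.null(~np.eye(3, dtype=bool))
        np.testing.assert_allclose(implied_correlation(model, r), np.diag(r))

    def test_two_node_closed_form(self):
        """Single path with coefficient a and residuals (1, 1-a^2) implies
        the correlation matrix [[1, a], [a, 1]]."""
        a = 0.6
        mask = np.array([[False, False], [True, False]])
        model = PathModel(K=theta_to_K([a], mask), allowed_mask=mask, free_mask=mask)
        C1 = implied_correlation(model, np.array([1.0, 1 - a**2]))
        np.testing.assert_allclose(C1, [[1, a], [a, 1]], atol=1e-12)

    def test_large_spectral_radius_but_invertible(self):
        mask = np.array([[False, False], [True, False]])
        model = PathModel(K=theta_to_K([3.0], mask), allowed_mask=mask, free_mask=mask)
        C1 = implied_correlation(model, np.array([1.0, 1.0]))
        assert np.all(np.isfinite(C1))
        np.testing.assert_allclose(C1, C1.T, atol=1e-10)

    def test_singular_model_rejected(self):
        mask = ~np.eye(2, dtype=bool)
        model = PathModel(K=theta_to_K([1.0, 1.0], mask), allowed_mask=mask,
                          free_mask=mask)  # (I-K) has rank 1
        with pytest.raises(SingularModelError):
            implied_correlation(model, np.array([1.0, 1.0]))

    def test_agrees_with_simulation_covariance(self):
        """The analytic implied matrix matches the empirical covariance of
        exact simulation v = (I-K)^{-1} u within Monte-Carlo error."""
        rng = np.random.default_rng(9)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 0] = mask[2, 1] = True
        model = PathModel(K=theta_to_K([0.7, 0.5], mask),
                          allowed_mask=~np.eye(3, dtype=bool), free_mask=mask)
        r = np.array([1.0, 0.51, 0.6])
        n = 200_000
        u = rng.normal(size=(3, n)) * np.sqrt(r)[:, None]
        v = np.linalg.solve(np.eye(3) - model.K, u)
        emp = v @ v.T / n
        np.testing.assert_allclose(emp, implied_correlation(model, r), atol=0.02)

    def test_unit_diagonal_residuals_closure(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 0] = mask[2, 1] = True
        model = PathModel(K=theta_to_K([0.7, 0.5], mask),
                          allowed_mask=~np.eye(3, dtype=bool), free_mask=mask)
        r = unit_diagonal_residuals(model.K)
        C1 = implied_correlation(model, r)
        np.testing.assert_allclose(np.diag(C1), 1.0, atol=1e-10)


class TestMLDiscrepancy:
    def test_exact_fit_is_zero(self):
        C = random_pd(np.random.default_rng(0), 4)
        assert abs(ml_discrepancy(C, C).F) < 1e-10

    def test_two_node_closed_form(self):
        """F(I, [[1, .5], [.5, 1]]) = -ln(det C2) = -ln 0.75."""
        C2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        d = ml_discrepancy(np.eye(2), C2)
        assert np.isclose(d.F, -math.log(0.75))
        assert np.isclose(d.log_det_C1, 0.0)
        assert np.isclose(d.trace_term, 2.0)

    def test_spectral_identity_oracle(self):
        """F equals sum(lam - ln lam) - p over the eigenvalues of C1^{-1} C2."""
        rng = np.random.default_rng(1)
        for _ in range(25):
            p = int(rng.integers(2, 7))
            C1, C2 = random_pd(rng, p), random_pd(rng, p)
            lam = np.linalg.eigvals(np.linalg.solve(C1, C2)).real
            expected = float(np.sum(lam - np.log(lam)) - p)
            assert abs(ml_discrepancy(C1, C2).F - expected) < 1e-8

    def test_nonnegative_over_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = int(rng.integers(2, 6))
            F = ml_discrepancy(random_pd(rng, p), random_pd(rng, p)).F
            assert F >= -1e-10

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        C1, C2 = random_pd(rng, 4), random_pd(rng, 4)
        base = ml_discrepancy(C1, C2).F
        for perm in permutations(range(4)):
            P = np.eye(4)[list(perm)]
            assert np.isclose(ml_discrepancy(P @ C1 @ P.T, P @ C2 @ P.T).F, base)

    def test_non_pd_input_named(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(DefinitenessError, match="C1"):
            ml_discrepancy(bad, np.eye(2))
        with pytest.raises(DefinitenessError, match="C2"):
            ml_discrepancy(np.eye(2), bad)


class TestCounts:
    def test_possible_paths(self):
        assert count_possible_paths(6) == 30
        assert count_possible_paths(1) == 0
        # brute-force enumeration of ordered pairs at p=4
        assert count_possible_paths(4) == len(
            [(i, j) for i in range(4) for j in range(4) if i != j])

    def test_candidate_models(self):
        assert count_candidate_models(30, 12) == 86_493_225
        assert count_candidate_models(17, 0) == 1
        assert count_candidate_models(6, 3) == len(list(combinations(range(6), 3)))

    def test_symmetry_and_pascal(self):
        for n in range(1, 12):
            for k in range(n + 1):
                assert count_candidate_models(n, k) == count_candidate_models(n, n - k)
            for k in range(1, n):
                assert count_candidate_models(n, k) == (
                    count_candidate_models(n - 1, k - 1) + count_candidate_models(n - 1, k))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            count_possible_paths(0)
        with pytest.raises(DomainError):
            count_candidate_models(5, 6)


class TestSerialization:
    def _model(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 0] = mask[2, 1] = True
        allowed = ~np.eye(3, dtype=bool)
        return PathModel(K=theta_to_K([0.7, -0.5], mask), allowed_mask=allowed,
                         free_mask=mask, region_labels=("A", "B", "C"))

    def test_edge_list_roundtrip(self, tmp_path):
        model = self._model()
        path = tmp_path / "edges.csv"
        write_edge_list(model, path)
        back = read_edge_list(path)
        assert back.region_labels == model.region_labels
        np.testing.assert_allclose(back.K, model.K)
        assert (back.free_mask == model.free_mask).all()
        assert (back.allowed_mask == model.allowed_mask).all()

    def test_json_roundtrip(self):
        model = self._model()
        back = model_from_json(model_to_json(model))
        np.testing.assert_allclose(back.K, model.K)
        assert back.region_labels == model.region_labels

    def test_invariant_enforcement(self):
        with pytest.raises(DimensionError):
            PathModel(K=np.eye(2), allowed_mask=~np.eye(2, dtype=bool),
                      free_mask=~np.eye(2, dtype=bool))  # nonzero diagonal
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 0] = True
        with pytest.raises(DimensionError):
            PathModel(K=np.zeros((2, 2)), allowed_mask=np.zeros((2, 2), dtype=bool),
                      free_mask=mask)  # free not subset of allowed
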