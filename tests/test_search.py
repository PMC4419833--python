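import numpy as np
import pytest

from semconn import (
    GAConfig,
    PathModel,
    StopRule,
    exhaustive_structure_search,
    ga_structure_search,
    generate_network,
    simulate_timeseries,
    stepwise_search,
)
from semconn.exceptions import DomainError
from semconn.search import lagrange_scores
from semconn.sem import count_candidate_models, theta_to_K
from semconn.simulate import SyntheticScenario, anatomical_mask, unit_variance_residual_sd


def analytic_c2(K, sd):
    p = K.shape[0]
    B = np.linalg.solve(np.eye(p) - K, np.eye(p))
    C = (B * sd**2) @ B.T
    return 0.5 * (C + C.T)


class TestLagrangeScores:
    def test_true_path_dominates_at_null(self):
        """With the true residuals, the generating path's modification index
        strictly exceeds every other allowed path's (including its own
        reversal)."""
        p = 3
        K = np.zeros((p, p))
        K[1, 0] = 0.7
        sd = unit_variance_residual_sd(K)
        C2 = analytic_c2(K, sd)
        null = PathModel.null(~np.eye(p, dtype=bool))
        scores = lagrange_scores(null, sd**2, C2)
        best = max(scores, key=scores.get)
        assert best == (0, 1)
        assert all(scores[(0, 1)] > v + 1e-6 for e, v in scores.items() if e != (0, 1))

    def test_identity_correlation_gives_zero_scores(self):
        null = PathModel.null(~np.eye(3, dtype=bool))
        scores = lagrange_scores(null, np.ones(3), np.eye(3))
        assert all(abs(v) < 1e-6 for v in scores.values())

    def test_free_paths_absent_from_table(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 0] = True
        model = PathModel(K=theta_to_K([0.5], mask),
                          allowed_mask=~np.eye(3, dtype=bool), free_mask=mask)
        scores = lagrange_scores(model, "unit_diagonal", np.eye(3))
        assert (0, 1) not in scores
        assert len(scores) == 5

    def test_scores_nonnegative(self):
        rng = np.random.default_rng(0)
        from conftest import random_pd

        null = PathModel.null(~np.eye(4, dtype=bool))
        scores = lagrange_scores(null, "unit_diagonal", random_pd(rng, 4))
        assert all(v >= 0 for v in scores.values())


class TestStepwise:
    def test_recovers_generating_paths_first(self):
        """On noiseless data from a 2-path truth the first two freed paths
        are the generating ones."""
        truth = generate_network(3, 2, 0.6, 0.6, seed=21)
        sd = unit_variance_residual_sd(truth.K)
        C2 = analytic_c2(truth.K, sd)
        trace = stepwise_search(C2, "unit_diagonal", anatomical_mask(truth))
        freed = {s.freed_path for s in trace.steps[:2]}
        assert freed == set(truth.free_edges())
        assert trace.stopped_reason == "fit_threshold"

    def test_identity_correlation_stops_immediately(self):
        trace = stepwise_search(np.eye(3), "unit_diagonal", ~np.eye(3, dtype=bool))
        assert trace.steps == ()
        assert trace.stopped_reason == "fit_threshold"

    def test_max_paths_bound_respected(self):
        from conftest import random_pd

        C2 = random_pd(np.random.default_rng(1), 6)
        trace = stepwise_search(C2, "unit_diagonal", ~np.eye(6, dtype=bool),
                                stop=StopRule(max_free_paths=12, fit_tolerance=0.0))
        assert len(trace.steps) <= 12
        assert trace.stopped_reason in ("max_paths", "no_candidates")

    def test_monotone_f_and_q_increments(self):
        from conftest import random_pd

        C2 = random_pd(np.random.default_rng(2), 4)
        trace = stepwise_search(C2, "unit_diagonal", ~np.eye(4, dtype=bool),
                                stop=StopRule(max_free_paths=5, fit_tolerance=1e-9))
        fs = [trace.F_null] + [s.F for s in trace.steps]
        assert all(b <= a + 1e-10 for a, b in zip(fs, fs[1:]))
        for i, s in enumerate(trace.steps):
            assert s.theta.size == i + 1

    def test_freed_path_had_maximal_lm(self):
        from conftest import random_pd

        C2 = random_pd(np.random.default_rng(3), 4)
        trace = stepwise_search(C2, "unit_diagonal", ~np.eye(4, dtype=bool),
                                stop=StopRule(max_free_paths=3, fit_tolerance=1e-9))
        for s in trace.steps:
            assert s.lm_scores[s.freed_path] >= max(s.lm_scores.values()) - 1e-12

    def test_ground_truth_recovery_rate(self):
        """Over 20 seeded instances (p=4, q=3, strong coefficients), at least
        90% of generating paths appear among the first q freed paths."""
        hits = total = 0
        for seed in range(20):
            truth = generate_network(4, 3, 0.4, 0.7, seed=100 + seed)
            sd = unit_variance_residual_sd(truth.K)
            scen = SyntheticScenario(truth=truth, residual_sd=sd, m=5, n=500,
                                     observation_noise_sd=0.2, seed=200 + seed)
            regions, _ = simulate_timeseries(scen)
            from semconn import EffectiveConnectivitySEM

            model = EffectiveConnectivitySEM.from_timeseries(regions)
            trace = stepwise_search(model.C2, "unit_diagonal", anatomical_mask(truth),
                                    stop=StopRule(max_free_paths=3, fit_tolerance=0.0))
            freed = {s.freed_path for s in trace.steps}
            true_edges = set(truth.free_edges())
            hits += len(freed & true_edges)
            total += len(true_edges)
        assert hits / total >= 0.9


class TestExhaustive:
    def test_finds_generating_structure(self):
        truth = generate_network(3, 2, 0.6, 0.6, seed=31)
        sd = unit_variance_residual_sd(truth.K)
        C2 = analytic_c2(truth.K, sd)
        best = exhaustive_structure_search(C2, "unit_diagonal", anatomical_mask(truth), 2)
        assert set(best.free_set) == set(truth.free_edges())
        assert best.F_min < 1e-8

    def test_null_structure(self):
        best = exhaustive_structure_search(np.eye(3), np.ones(3),
                                           ~np.eye(3, dtype=bool), 0)
        assert best.free_set == ()
        assert abs(best.F_min) < 1e-12

    def test_enumeration_count(self):
        from conftest import random_pd

        C2 = random_pd(np.random.default_rng(4), 3)
        best = exhaustive_structure_search(C2, "unit_diagonal",
                                           ~np.eye(3, dtype=bool), 2)
        assert best.n_enumerated == count_candidate_models(6, 2)

    def test_cap_refusal_names_count(self):
        with pytest.raises(DomainError, match="86493225|86,493,225"):
            exhaustive_structure_search(np.eye(6), np.ones(6),
                                        ~np.eye(6, dtype=bool), 12, cap=100)


class TestGaStructure:
    def test_matches_exhaustive_oracle(self):
        """On every small fixture instance the GA attains the exhaustive
        optimum within 1e-4."""
        for seed in range(3):
            truth = generate_network(3, 2, 0.5, 0.7, seed=40 + seed)
            sd = unit_variance_residual_sd(truth.K)
            scen = SyntheticScenario(truth=truth, residual_sd=sd, m=5, n=400,
                                     seed=50 + seed)
            _, true_corr = simulate_timeseries(scen)
            allowed = anatomical_mask(truth)
            exact = exhaustive_structure_search(true_corr, "unit_diagonal", allowed, 2)
            ga = ga_structure_search(true_corr, "unit_diagonal", allowed, 2,
                                     config=GAConfig(population_size=64,
                                                     max_generations=30, seed=seed))
            assert ga.F_min <= exact.F_min + 1e-4

    def test_seed_determinism(self, chain3):
        truth, sd, C2 = chain3
        cfg = GAConfig(population_size=32, max_generations=15, seed=9)
        a = ga_structure_search(C2, "unit_diagonal", truth.allowed_mask, 2, config=cfg)
        b = ga_structure_search(C2, "unit_diagonal", truth.allowed_mask, 2, config=cfg)
        assert a.free_set == b.free_set
        assert a.F_min == b.F_min
        assert (a.theta_at_min == b.theta_at_min).all()

    def test_q_above_allowed_rejected(self):
        with pytest.raises(DomainError):
            ga_structure_search(np.eye(3), np.ones(3), ~np.eye(3, dtype=bool), 7)

    def test_chromosome_cardinality_preserved(self, chain3):
        truth, sd, C2 = chain3
        cand = ga_structure_search(C2, "unit_diagonal", truth.allowed_mask, 3,
                                   config=GAConfig(population_size=32,
                                                   max_generations=10, seed=2))
        assert cand.q == 3
        assert len(set(cand.free_set)) == 3
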