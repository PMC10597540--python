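import numpy as np
import pandas as pd
import pytest

from episub import (
    DistanceSpec,
    LinkageSpec,
    SimParams,
    agglomerate,
    cluster_outcome_association,
    compute_distance,
    find_optimal_clusters,
    preprocess_pipeline,
    select_best_approach,
    simulate_cohort,
    split_and_test,
)
from episub.hierarchy import ClusterAssignment
from episub.subtypes import AssociationResult, SubtypeCall, _design_matrix

from conftest import make_metadata
from oracles import irls_logistic


def balanced_assignment(n: int, n_in: int) -> ClusterAssignment:
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return ClusterAssignment(
        labels={s: (1 if i < n_in else 2) for i, s in enumerate(ids)}, k=2
    )


class TestClusterOutcomeAssociation:
    def test_exchangeable_groups_give_null_coefficient(self):
        # recurrence 50% both inside and outside; covariates random
        n = 200
        outcome = ([1] * 50 + [0] * 50) * 2
        meta = make_metadata(n, outcome=outcome, rng_seed=1)
        res = cluster_outcome_association(balanced_assignment(n, 100), meta, 1)
        assert abs(res.coef) < 0.5
        assert res.wald_p > 0.9

    def test_membership_identical_to_outcome_flags_separation(self):
        n = 30
        outcome = [1] * 15 + [0] * 15
        meta = make_metadata(n, outcome=outcome, rng_seed=2)
        res = cluster_outcome_association(balanced_assignment(n, 15), meta, 1)
        assert res.separation_flag
        assert not res.converged

    def test_recovers_known_log_odds_and_matches_irls_oracle(self):
        # planted log-odds 1.5 for membership, no covariate effects
        rng = np.random.default_rng(7)
        n = 500
        member = np.arange(n) < 250
        eta = -0.5 + 1.5 * member
        outcome = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        meta = make_metadata(n, outcome=outcome, rng_seed=3)
        assignment = balanced_assignment(n, 250)
        res = cluster_outcome_association(assignment, meta, 1)
        assert abs(res.coef - 1.5) < 0.3
        X, y = _design_matrix(meta, list(assignment.labels), set(assignment.members(1)))
        beta, _, p = irls_logistic(np.asarray(X, float), y.to_numpy())
        assert abs(res.wald_p - p[list(X.columns).index("in_cluster")]) < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_wald_p_matches_irls_oracle_on_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        outcome = rng.integers(0, 2, n)
        if outcome.sum() in (0, n):
            outcome[0] = 1 - outcome[0]
        meta = make_metadata(n, outcome=outcome, rng_seed=100 + seed)
        assignment = balanced_assignment(n, int(rng.integers(10, n - 10)))
        res = cluster_outcome_association(assignment, meta, 1)
        if res.separation_flag:
            pytest.skip("separated draw; Wald p not comparable")
        X, y = _design_matrix(meta, list(assignment.labels), set(assignment.members(1)))
        _, _, p = irls_logistic(np.asarray(X, float), y.to_numpy())
        assert abs(res.wald_p - p[list(X.columns).index("in_cluster")]) < 1e-6

    def test_constant_outcome_rejected(self):
        meta = make_metadata(10, outcome=[1] * 10)
        with pytest.raises(ValueError, match="constant"):
            cluster_outcome_association(balanced_assignment(10, 5), meta, 1)


class TestSplitAndTest:
    @pytest.fixture()
    def small_dendro(self):
        rng = np.random.default_rng(5)
        from scipy.spatial.distance import pdist, squareform

        pts = rng.normal(size=(12, 3))
        ids = [f"S{i + 1:03d}" for i in range(12)]
        D = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
        return agglomerate(D, LinkageSpec("ward_d2"))

    def test_k2_mirror_models_share_p_value(self, small_dendro):
        meta = make_metadata(12, outcome=[0, 1] * 6, rng_seed=8)
        results = split_and_test(small_dendro, meta, 2)
        assert len(results) == 2
        np.testing.assert_allclose(results[0].wald_p, results[1].wald_p, atol=1e-9)

    def test_fdr_at_least_nominal(self, small_dendro):
        meta = make_metadata(12, outcome=[0, 1] * 6, rng_seed=8)
        for k in (2, 3, 4):
            for r in split_and_test(small_dendro, meta, k):
                if np.isfinite(r.wald_p):
                    assert r.fdr_p >= r.wald_p - 1e-12


class TestFindOptimalClusters:
    @staticmethod
    def stub_tester(min_ps: dict[int, float], fdrs: dict[int, float]):
        def tester(k):
            return [
                AssociationResult(
                    cluster=1, n_in=2, n_recurrence_in=1, coef=0.0,
                    wald_p=min_ps[k], fdr_p=fdrs[k],
                )
            ] + [
                AssociationResult(
                    cluster=j, n_in=2, n_recurrence_in=1, coef=0.0,
                    wald_p=0.9, fdr_p=0.9,
                )
                for j in range(2, k + 1)
            ]

        return tester

    @pytest.fixture()
    def dendro(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        ids = [f"S{i + 1:03d}" for i in range(10)]
        D = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
        return agglomerate(D, LinkageSpec("complete"))

    def test_stops_when_next_cut_less_significant(self, dendro):
        meta = make_metadata(10, outcome=[0, 1] * 5)
        # k=2 not significant; k=3 significant with min p 0.02; k=4 degrades to 0.04
        tester = self.stub_tester(
            min_ps={2: 0.3, 3: 0.02, 4: 0.04}, fdrs={2: 0.3, 3: 0.06, 4: 0.12}
        )
        call = find_optimal_clusters(dendro, meta, tester=tester)
        assert call.optimal_k == 3
        assert call.best_fdr == 0.06

    def test_keeps_splitting_while_p_improves(self, dendro):
        meta = make_metadata(10, outcome=[0, 1] * 5)
        tester = self.stub_tester(
            min_ps={2: 0.05, 3: 0.03, 4: 0.01, 5: 0.02},
            fdrs={2: 0.1, 3: 0.09, 4: 0.03, 5: 0.06},
        )
        call = find_optimal_clusters(dendro, meta, tester=tester)
        assert call.optimal_k == 4

    def test_returns_none_when_nothing_significant(self, dendro):
        meta = make_metadata(10, outcome=[0, 1] * 5)
        ks_seen = []

        def tester(k):
            ks_seen.append(k)
            return [
                AssociationResult(cluster=j, n_in=2, n_recurrence_in=1, coef=0.0,
                                  wald_p=0.8, fdr_p=0.8)
                for j in range(1, k + 1)
            ]

        assert find_optimal_clusters(dendro, meta, tester=tester) is None
        assert ks_seen == list(range(2, 11))


class TestSelectBestApproach:
    @staticmethod
    def call(fdr, k=2, metric="manhattan", linkage="ward_d"):
        ids = [f"S{i}" for i in range(4)]
        assignment = ClusterAssignment({s: 1 + (i % 2) for i, s in enumerate(ids)}, k=2)
        return SubtypeCall(
            optimal_k=k, assignment=assignment, results=[], best_cluster=1,
            best_fdr=fdr, direction="risk",
            distance=DistanceSpec(metric), linkage=LinkageSpec(linkage),
        )

    def test_single_call_returned(self):
        c = self.call(0.1)
        assert select_best_approach([c]) is c

    def test_lowest_fdr_wins(self):
        a, b = self.call(0.12), self.call(0.03)
        assert select_best_approach([a, b]) is b

    def test_fdr_tie_broken_by_smaller_k_then_grid_order(self):
        a, b = self.call(0.05, k=4), self.call(0.05, k=3)
        assert select_best_approach([a, b]) is b
        c = self.call(0.05, k=3, metric="euclidean")
        d = self.call(0.05, k=3, metric="canberra")
        assert select_best_approach([c, d]) is d

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_approach([])


class TestProcedureInvariance:
    def test_association_pvalues_invariant_to_sample_order(self):
        mats, meta, _ = simulate_cohort(SimParams(seed=21))
        mat, _ = preprocess_pipeline(mats["blood_mirna"], meta)
        dist = compute_distance(mat, DistanceSpec("euclidean"))
        base = split_and_test(agglomerate(dist, LinkageSpec("ward_d2")), meta, 3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(dist))
        ids = [dist.index[i] for i in perm]
        dist_p = dist.loc[ids, ids]
        permuted = split_and_test(agglomerate(dist_p, LinkageSpec("ward_d2")), meta, 3)
        np.testing.assert_allclose(
            sorted(r.wald_p for r in base), sorted(r.wald_p for r in permuted), atol=1e-9
        )


class TestNullCalibration:
    def test_min_p_at_k3_not_anticonservative_under_global_null(self):
        """With no planted effect and equal recurrence rates, the minimum
        nominal p over the 3 clusters of a fixed cut should not be extreme
        too often: P(min p < 0.01) <= 0.05 over 200 simulated cohorts."""
        params_base = dict(
            effect_size=0.0,
            recurrence_rate_subtype=0.45,
            recurrence_rate_background=0.45,
            n_features={"blood_mirna": 120, "blood_mrna": 50,
                        "brain_mirna": 50, "brain_mrna": 50},
            n_signal_features={"blood_mirna": 30, "blood_mrna": 12,
                               "brain_mirna": 12, "brain_mrna": 12},
        )
        hits = 0
        for seed in range(200):
            mats, meta, _ = simulate_cohort(SimParams(seed=seed, **params_base))
            mat, _ = preprocess_pipeline(mats["blood_mirna"], meta)
            dist = compute_distance(mat, DistanceSpec("euclidean"))
            dendro = agglomerate(dist, LinkageSpec("ward_d2"))
            results = split_and_test(dendro, meta, 3)
            ps = [r.wald_p for r in results if np.isfinite(r.wald_p)]
            if ps and min(ps) < 0.01:
                hits += 1
        assert hits / 200 <= 0.05
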