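import numpy as np
import pandas as pd
import pytest

import fateflow as ff
from fateflow.fate import backward_membership, null_entropy, one_hot
from fateflow.ot_core import TransportMap


def stochastic(rng, m, n):
    P = rng.uniform(0.1, 1.0, size=(m, n))
    return P / P.sum(axis=1, keepdims=True)


class TestBarycentric:
    def test_identity_and_uniform(self):
        X = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(ff.barycentric_project(np.eye(4), X), X)
        U = np.full((2, 4), 0.25)
        np.testing.assert_allclose(ff.barycentric_project(U, X),
                                   np.tile(X.mean(axis=0), (2, 1)))

    def test_matches_double_loop_expectation(self):
        rng = np.random.default_rng(0)
        P = stochastic(rng, 6, 5)
        X = rng.normal(size=(5, 3))
        Y = ff.barycentric_project(P, X)
        for i in range(6):
            for k in range(3):
                exp = sum(P[i, j] * X[j, k] for j in range(5))
                assert abs(Y[i, k] - exp) < 1e-10

    def test_convexity_invariant(self):
        rng = np.random.default_rng(1)
        P = stochastic(rng, 10, 7)
        X = rng.normal(size=(7, 4))
        Y = ff.barycentric_project(P, X)
        assert (Y <= X.max(axis=0) + 1e-12).all()
        assert (Y >= X.min(axis=0) - 1e-12).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ff.barycentric_project(np.eye(3), np.zeros((4, 2)))

    def test_project_expression_matches_projection(self, bench):
        rng = np.random.default_rng(2)
        snap = bench.tc.snapshot(7.0)
        P = stochastic(rng, 5, snap.n_obs)
        genes = list(bench.tc.gene_index[:3])
        df = ff.project_expression(P, snap, genes)
        from fateflow._utils import as_dense
        direct = ff.barycentric_project(P, as_dense(snap[:, genes].X))
        np.testing.assert_allclose(df.to_numpy(), direct)
        with pytest.raises(KeyError, match="unknown"):
            ff.project_expression(P, snap, ["nope"])


class TestFatePropensity:
    def test_deterministic_fate_zero_entropy(self):
        P = np.array([[1.0, 0.0, 0.0]])
        prop = ff.fate_propensities(P, ["a", "a", "b"])
        np.testing.assert_allclose(prop.Q, [[1.0, 0.0]])
        assert prop.entropy[0] == 0.0

    def test_uniform_over_equal_clusters_max_entropy(self):
        k = 4
        P = np.full((1, 8), 1 / 8)
        prop = ff.fate_propensities(P, ["a", "a", "b", "b", "c", "c", "d", "d"])
        assert prop.entropy[0] == pytest.approx(np.log(k))

    def test_entropy_matches_direct_sum(self):
        rng = np.random.default_rng(3)
        P = stochastic(rng, 12, 9)
        labels = rng.choice(["x", "y", "z"], 9)
        prop = ff.fate_propensities(P, labels)
        C, _ = one_hot(labels)
        Q = P @ C
        H = np.array([-sum(q * np.log(q) for q in row if q > 0) for row in Q])
        np.testing.assert_allclose(prop.entropy, H, atol=1e-12)
        np.testing.assert_allclose(prop.Q.sum(axis=1), 1.0, atol=1e-8)
        assert (prop.entropy >= -1e-12).all()
        assert (prop.entropy <= np.log(3) + 1e-12).all()


class TestConsistency:
    def test_product_coupling_zero(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(["a", "b", "c"], 30)
        b = np.full(30, 1 / 30)
        P = np.tile(b, (10, 1))
        prop = ff.fate_propensities(P, labels)
        cons, mean = ff.fate_consistency(prop, labels)
        np.testing.assert_allclose(cons, 0.0, atol=1e-10)

    def test_cluster_preserving_coupling_one(self):
        labels = ["a", "a", "b", "b"]
        P = np.array([[0.6, 0.4, 0, 0], [0, 0, 0.5, 0.5]])
        prop = ff.fate_propensities(P, labels)
        cons, mean = ff.fate_consistency(prop, labels)
        np.testing.assert_allclose(cons, 1.0)

    def test_anticoncentrated_coupling_negative(self):
        # unequal clusters; every cell splits 50/50 although the null is skewed
        labels = ["a"] * 9 + ["b"]
        P = np.zeros((3, 10))
        P[:, 0] = 0.5
        P[:, 9] = 0.5
        prop = ff.fate_propensities(P, labels)
        cons, mean = ff.fate_consistency(prop, labels)
        H0 = null_entropy(labels)
        assert np.log(2) > H0           # the split is more uncertain than the null
        np.testing.assert_allclose(cons, 1 - np.log(2) / H0)
        assert (cons < 0).all()

    def test_single_cluster_errors(self):
        P = np.eye(3)
        prop = ff.fate_propensities(P, ["a", "a", "a"])
        with pytest.raises(ValueError, match="undefined"):
            ff.fate_consistency(prop, ["a", "a", "a"])


def make_map(P, src_t, tgt_t, src_ids, tgt_ids):
    return TransportMap(coupling=np.asarray(P, float), source_ids=list(src_ids),
                        target_ids=list(tgt_ids), source_timepoint=src_t,
                        target_timepoint=tgt_t)


class TestEgress:
    def test_within_and_cross_compartment_extremes(self):
        comp = pd.Series({"s0": "spleen", "s1": "spleen", "t0": "spleen", "t1": "gut"})
        stay = make_map([[1.0, 0.0], [1.0, 0.0]], 0, 1, ["s0", "s1"], ["t0", "t1"])
        est = ff.egress_probabilities([stay], comp)
        np.testing.assert_allclose(est.per_cell["egress_probability"], 0.0)
        go = make_map([[0.0, 1.0], [0.0, 1.0]], 0, 1, ["s0", "s1"], ["t0", "t1"])
        est = ff.egress_probabilities([go], comp)
        np.testing.assert_allclose(est.per_cell["egress_probability"], 1.0)
        assert est.per_cell["egress_hi"].all()

    def test_probability_conservation(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(0.1, 1, (4, 6))
        comp = pd.Series({f"s{i}": "spleen" for i in range(4)}
                         | {f"t{j}": ["spleen", "gut"][j % 2] for j in range(6)})
        tm = make_map(P, 0, 1, [f"s{i}" for i in range(4)], [f"t{j}" for j in range(6)])
        est = ff.egress_probabilities([tm], comp)
        Ph = ff.row_normalize(P)
        stay = [(Ph[i] * (np.array(["spleen", "gut"])[np.arange(6) % 2] == "spleen")).sum()
                for i in range(4)]
        np.testing.assert_allclose(est.per_cell["egress_probability"] + stay, 1.0,
                                   atol=1e-12)

    def test_missing_labels_error(self):
        tm = make_map(np.eye(2), 0, 1, ["a", "b"], ["c", "d"])
        with pytest.raises(ValueError, match="compartment"):
            ff.egress_probabilities([tm], pd.Series({"a": "x", "b": "x", "c": "x"}))


class TestArrivalTimes:
    def test_step_function_arrival(self):
        # ancestors in tissue from day 1 onward, outside before
        comp = pd.Series({"a0": "spleen", "a1": "gut", "a2": "gut", "q": "gut"})
        m01 = make_map([[1.0]], 0, 1, ["a0"], ["a1"])
        m12 = make_map([[1.0]], 1, 2, ["a1"], ["a2"])
        m2q = make_map([[1.0]], 2, 3, ["a2"], ["q"])
        est = ff.arrival_times([m01, m12, m2q], comp, 3, "gut")
        assert est.per_cell["arrival_time"].iloc[0] == pytest.approx(1.0)

    def test_entry_at_final_interval(self):
        comp = pd.Series({"a0": "spleen", "a1": "spleen", "a2": "spleen", "q": "gut"})
        maps = [make_map([[1.0]], t, t + 1, [f"a{t}"], [f"a{t+1}" if t < 2 else "q"])
                for t in range(3)]
        est = ff.arrival_times(maps, comp, 3, "gut")
        assert est.per_cell["arrival_time"].iloc[0] == pytest.approx(2.0)

    def test_backward_membership_matches_path_enumeration(self):
        # 3 timepoints, 2-3 cells each: enumerate ancestor paths explicitly
        rng = np.random.default_rng(6)
        ids0, ids1, ids2 = ["x0", "x1"], ["y0", "y1", "y2"], ["z0", "z1"]
        P01 = rng.uniform(0.1, 1, (2, 3))
        P12 = rng.uniform(0.1, 1, (3, 2))
        comp = pd.Series({"x0": "gut", "x1": "spleen", "y0": "gut", "y1": "spleen",
                          "y2": "gut", "z0": "gut", "z1": "gut"})
        maps = [make_map(P01, 0, 1, ids0, ids1), make_map(P12, 1, 2, ids1, ids2)]
        q, qids = backward_membership(maps, comp, 2)
        B12 = ff.transpose_map(P12)          # z -> y
        B01 = ff.transpose_map(P01)          # y -> x
        for zi in range(2):
            q1 = sum(B12[zi, yj] for yj in range(3)
                     if comp[ids1[yj]] == comp[ids2[zi]])
            assert q.loc[ids2[zi], 1] == pytest.approx(q1, abs=1e-12)
            q0 = sum(B12[zi, yj] * B01[yj, xk] for yj in range(3) for xk in range(2)
                     if comp[ids0[xk]] == comp[ids2[zi]])
            assert q.loc[ids2[zi], 0] == pytest.approx(q0, abs=1e-10)
        assert ((q.to_numpy() >= -1e-12) & (q.to_numpy() <= 1 + 1e-12)).all()

    def test_arrival_bounds(self, migration_results):
        arr = migration_results["arrivals"]["arrival_time"]
        assert (arr >= 3.0 - 1e-9).all() and (arr <= 7.0 + 1e-9).all()

    def test_wrong_compartment_query_errors(self):
        comp = pd.Series({"a": "spleen", "q": "spleen"})
        m = make_map([[1.0]], 0, 1, ["a"], ["q"])
        with pytest.raises(ValueError, match="no cells"):
            ff.arrival_times([m], comp, 1, "gut")


class TestTrajectoryCorrelations:
    def test_identity_coupling_perfect_correlation(self, bench):
        sub = bench.circulating
        ids = list(sub.snapshot(7.0).obs_names[:30])
        tm = make_map(np.eye(30), 7.0, 10.0, ids, ids)
        res = ff.trajectory_gene_correlations(sub, [tm], list(sub.gene_index[:20]))
        finite = res.median.dropna()
        np.testing.assert_allclose(finite.to_numpy(), 1.0, atol=1e-12)

    def test_permutation_null_near_zero(self):
        import anndata as ad
        rng = np.random.default_rng(7)
        n, g = 200, 10
        X = rng.normal(size=(2 * n, g))
        obs = pd.DataFrame({"timepoint": [0.0] * n + [1.0] * n},
                           index=[f"c{i}" for i in range(2 * n)])
        tc = ff.TimeCourse(ad.AnnData(X=X, obs=obs,
                                      var=pd.DataFrame(index=[f"g{i}" for i in range(g)])))
        tc.adata.uns["fateflow_normalized"] = True
        perm = np.eye(n)[rng.permutation(n)]
        tm = make_map(perm, 0.0, 1.0, list(obs.index[:n]), list(obs.index[n:]))
        res = ff.trajectory_gene_correlations(tc, [tm], [f"g{i}" for i in range(g)])
        assert np.abs(res.median.to_numpy()).max() < 0.2

    def test_lineage_stable_genes_outrank_transient(self, bench):
        """Heritable lineage-level genes must rank above the day-5 spike genes."""
        sub = bench.circulating
        maps, _, _ = ff.benchmark._fit(bench, sub, "single")
        sets = ff.planted_gene_sets(bench.gt.config)
        genes = sets["lineage_stable"] + sets["transient"]
        res = ff.trajectory_gene_correlations(sub, maps, genes, top_k=len(genes))
        med = res.median
        assert med[sets["lineage_stable"]].median() > med[sets["transient"]].median()
        top = res.top[: len(sets["lineage_stable"])]
        frac_stable = np.mean([g in sets["lineage_stable"] for g in top])
        assert frac_stable >= 0.7

    def test_spearman_invariant_under_monotone_transform(self):
        import anndata as ad
        rng = np.random.default_rng(8)
        n = 50
        X = np.abs(rng.normal(size=(2 * n, 3))) + 0.1
        obs = pd.DataFrame({"timepoint": [0.0] * n + [1.0] * n},
                           index=[f"c{i}" for i in range(2 * n)])
        var = pd.DataFrame(index=["g0", "g1", "g2"])
        P = stochastic(rng, n, n)
        ids_s, ids_t = list(obs.index[:n]), list(obs.index[n:])
        tc1 = ff.TimeCourse(ad.AnnData(X=X.copy(), obs=obs.copy(), var=var.copy()))
        tc1.adata.uns["fateflow_normalized"] = True
        X2 = X.copy()
        X2[:n] = np.exp(X2[:n])                 # monotone transform of the source
        tc2 = ff.TimeCourse(ad.AnnData(X=X2, obs=obs.copy(), var=var.copy()))
        tc2.adata.uns["fateflow_normalized"] = True
        tm = make_map(P, 0.0, 1.0, ids_s, ids_t)
        r1 = ff.trajectory_gene_correlations(tc1, [tm], ["g0", "g1", "g2"])
        r2 = ff.trajectory_gene_correlations(tc2, [tm], ["g0", "g1", "g2"])
        np.testing.assert_allclose(r1.median.to_numpy(), r2.median.to_numpy(),
                                   atol=1e-12)

    def test_constant_gene_interval_dropped_not_zeroed(self):
        import anndata as ad
        n = 10
        X = np.ones((2 * n, 2))
        X[:, 1] = np.arange(2 * n)
        obs = pd.DataFrame({"timepoint": [0.0] * n + [1.0] * n},
                           index=[f"c{i}" for i in range(2 * n)])
        tc = ff.TimeCourse(ad.AnnData(X=X, obs=obs,
                                      var=pd.DataFrame(index=["const", "var"])))
        tc.adata.uns["fateflow_normalized"] = True
        tm = make_map(np.eye(n), 0.0, 1.0, list(obs.index[:n]), list(obs.index[n:]))
        res = ff.trajectory_gene_correlations(tc, [tm], ["const", "var"])
        assert np.isnan(res.median["const"])
        assert res.median["var"] == pytest.approx(1.0)
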