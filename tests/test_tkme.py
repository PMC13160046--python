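import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.pairwise import rbf_kernel

import fateflow as ff
from fateflow.ot_core import TransportMap
from fateflow.tkme import median_bandwidth


def blobs(rng, n, centers, spread=0.3):
    X, lab = [], []
    for i, c in enumerate(centers):
        X.append(rng.normal(c, spread, size=(n, len(c))))
        lab += [i] * n
    return np.vstack(X), np.array(lab)


class TestKernelFeatures:
    def test_exact_nystroem_when_n_equals_d(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        ka = ff.fit_kernel_features(X, d=30, seed=0)
        F = ka.transform(X)
        gamma = 1.0 / (2 * ka.bandwidth ** 2)
        K = rbf_kernel(X, X, gamma=gamma)
        np.testing.assert_allclose(F @ F.T, K, atol=1e-8)

    def test_duplicate_cells_identical_features(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        X[1] = X[0]
        F = ff.fit_kernel_features(X, d=20, seed=0).transform(X)
        np.testing.assert_array_equal(F[0], F[1])

    def test_approximation_improves_with_d(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 6))
        errs = []
        for d in (10, 50):
            ka = ff.fit_kernel_features(X, d=d, seed=0)
            F = ka.transform(X)
            K = rbf_kernel(X, X, gamma=1.0 / (2 * ka.bandwidth ** 2))
            errs.append(np.sqrt(((F @ F.T - K) ** 2).mean()))
        assert errs[1] < errs[0]

    def test_bandwidth_is_median_distance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        from scipy.spatial.distance import pdist
        assert median_bandwidth(X) == pytest.approx(np.median(pdist(X)))

    def test_degenerate_identical_cells_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            ff.fit_kernel_features(np.ones((20, 3)), d=5)

    def test_d_lowered_with_warning(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="lowering d"):
            ka = ff.fit_kernel_features(rng.normal(size=(10, 3)), d=50, seed=0)
        assert ka.d == 10


def toy_course_with_maps(rng, n=20, d=3):
    """Three-timepoint toy system with identity-ish couplings."""
    import anndata as ad
    tps = [0.0, 7.0, 10.0]
    X = {t: rng.normal(size=(n, d)) for t in tps}
    obs = pd.DataFrame({"timepoint": np.repeat(tps, n)},
                       index=[f"c{t}_{i}" for t in tps for i in range(n)])
    tc = ff.TimeCourse(ad.AnnData(X=np.zeros((3 * n, 2)), obs=obs,
                                  var=pd.DataFrame(index=["g0", "g1"])))
    ids = {t: [f"c{t}_{i}" for i in range(n)] for t in tps}
    maps = []
    for s, t in zip(tps[:-1], tps[1:]):
        P = np.eye(n) + 0.01 * rng.uniform(size=(n, n))
        maps.append(TransportMap(coupling=P, source_ids=ids[s], target_ids=ids[t],
                                 source_timepoint=s, target_timepoint=t))
    return tc, maps, X, ids


class TestTKMEEmbed:
    def test_own_block_is_raw_features_and_column_count(self):
        rng = np.random.default_rng(5)
        tc, maps, X, ids = toy_course_with_maps(rng)
        kernels = {t: ff.fit_kernel_features(X[t], d=10, seed=0) for t in (7.0, 10.0)}
        emb = ff.tkme_embed(tc, maps, kernels, X, include_days_after=6.0,
                            standardize_blocks=False)
        assert emb.Z.shape[1] == 2 * 10
        own = kernels[7.0].transform(X[7.0])
        rows = emb.cell_timepoints == 7.0
        np.testing.assert_array_equal(emb.Z[rows][:, :10], own)

    def test_single_included_timepoint_is_kernel_features(self):
        rng = np.random.default_rng(6)
        tc, maps, X, ids = toy_course_with_maps(rng)
        kernels = {10.0: ff.fit_kernel_features(X[10.0], d=8, seed=0)}
        emb = ff.tkme_embed(tc, maps, kernels, X, include_days_after=9.0,
                            standardize_blocks=False)
        rows = emb.cell_timepoints == 10.0
        np.testing.assert_array_equal(emb.Z[rows],
                                      kernels[10.0].transform(X[10.0]))

    def test_identical_cells_identical_embeddings(self):
        rng = np.random.default_rng(7)
        tc, maps, X, ids = toy_course_with_maps(rng)
        X[7.0][1] = X[7.0][0]
        for tm in maps:            # identical couplings too
            if tm.source_timepoint == 7.0:
                tm.coupling[1] = tm.coupling[0]
            if tm.target_timepoint == 7.0:
                tm.coupling[:, 1] = tm.coupling[:, 0]
        kernels = {t: ff.fit_kernel_features(X[t], d=10, seed=0) for t in (7.0, 10.0)}
        emb = ff.tkme_embed(tc, maps, kernels, X, include_days_after=6.0)
        rows = np.where(emb.cell_timepoints == 7.0)[0]
        np.testing.assert_allclose(emb.Z[rows[0]], emb.Z[rows[1]], atol=1e-10)

    def test_missing_kernel_errors(self):
        rng = np.random.default_rng(8)
        tc, maps, X, ids = toy_course_with_maps(rng)
        with pytest.raises(ValueError, match="missing kernel"):
            ff.tkme_embed(tc, maps, {}, X, include_days_after=6.0)

    def test_chained_maps_row_stochastic(self):
        rng = np.random.default_rng(9)
        tc, maps, X, ids = toy_course_with_maps(rng)
        from fateflow.tkme import chained_map
        M = chained_map(maps, 0.0, 10.0)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-10)
        B = chained_map(maps, 10.0, 0.0)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_branch_separation_increases(self, bench, trajectory_results):
        """TKME separates fate branches better than single-timepoint features."""
        gtc = bench.gt.cells
        lab = trajectory_results["labels_kmeans"]
        late = [i for i in gtc[(gtc.day > 6) & (gtc.branch != "progenitor")].index
                if i in lab.index]
        assert adjusted_rand_score(gtc.loc[late, "fate_branch"],
                                   lab.reindex(late)) >= 0.8


class TestClustering:
    def test_two_blobs_perfect_split(self):
        rng = np.random.default_rng(10)
        X, truth = blobs(rng, 60, [(0, 0, 0), (8, 8, 8)])
        km = ff.cluster_trajectories(X, method="kmeans", k=2, seed=0)
        assert adjusted_rand_score(truth, km) == 1.0
        ld = ff.cluster_trajectories(X, method="leiden", resolution=0.5, seed=0)
        assert adjusted_rand_score(truth, ld) == 1.0

    def test_k_exceeds_n_errors(self):
        with pytest.raises(ValueError):
            ff.cluster_trajectories(np.zeros((3, 2)), method="kmeans", k=5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(11)
        X, _ = blobs(rng, 40, [(0, 0), (3, 3), (6, 0)])
        a = ff.cluster_trajectories(X, method="leiden", resolution=1.0, seed=7)
        b = ff.cluster_trajectories(X, method="leiden", resolution=1.0, seed=7)
        assert (a == b).all()

    def test_supercells_two_blobs_and_totality(self):
        rng = np.random.default_rng(12)
        X, truth = blobs(rng, 50, [(0, 0), (10, 10)])
        lab = ff.supercells(X, k_nn=15, resolution=1.0, seed=0)
        assert len(lab) == 100
        # every community sits entirely inside one blob (a refinement)
        for c in np.unique(lab):
            assert len(np.unique(truth[lab == c])) == 1
        coarse = ff.supercells(X, k_nn=15, resolution=0.1, seed=0)
        assert adjusted_rand_score(truth, coarse) == 1.0

    def test_resolution_monotone_cluster_count(self):
        rng = np.random.default_rng(13)
        X, _ = blobs(rng, 40, [(0, 0), (4, 0), (0, 4), (4, 4)], spread=0.8)
        counts = [len(np.unique(ff.supercells(X, resolution=r, seed=0)))
                  for r in (0.2, 1.0, 3.0)]
        assert counts[0] <= counts[1] <= counts[2]


class TestTrajectoryConsistency:
    def test_ground_truth_branches_consistent(self, bench, trajectory_results):
        maps = trajectory_results["maps"]
        gtc = bench.gt.cells
        lab = gtc["fate_branch"]
        df = ff.trajectory_cluster_consistency(lab, maps)
        assert np.nanmean(df["mean_consistency"]) > 0.5

    def test_random_permutation_scores_far_below_truth(self, bench, trajectory_results):
        """Permuted labels lose most of the consistency of the true branches.

        Sharp couplings put a floor under the consistency of any labeling
        (each cell's propensity support is small), so the permutation null
        is a contrast, not an absolute zero; the exact zero null is checked
        with a diffuse product coupling below.
        """
        maps = trajectory_results["maps"]
        gtc = bench.gt.cells
        truth = ff.trajectory_cluster_consistency(gtc["fate_branch"], maps)
        rng = np.random.default_rng(14)
        lab = pd.Series(rng.permutation(gtc["fate_branch"].to_numpy()),
                        index=gtc.index)
        perm = ff.trajectory_cluster_consistency(lab, maps)
        t = np.nanmean(truth["mean_consistency"])
        p = np.nanmean(perm["mean_consistency"])
        assert t - p > 0.2 and p < 0.75 * t

    def test_product_coupling_permutation_null_is_zero(self, bench):
        """With a diffuse product coupling, random labels give consistency 0."""
        rng = np.random.default_rng(15)
        from fateflow.ot_core import TransportMap
        ids_s = [f"s{i}" for i in range(40)]
        ids_t = [f"t{j}" for j in range(50)]
        P = np.tile(np.full(50, 1 / 50), (40, 1))
        tm = TransportMap(coupling=P, source_ids=ids_s, target_ids=ids_t,
                          source_timepoint=0.0, target_timepoint=1.0)
        lab = pd.Series(rng.choice(list("abc"), 90),
                        index=pd.Index(ids_s + ids_t))
        df = ff.trajectory_cluster_consistency(lab, [tm])
        assert abs(df["mean_consistency"].iloc[0]) < 1e-10

    def test_single_cluster_undefined(self, bench, trajectory_results):
        maps = trajectory_results["maps"]
        lab = pd.Series("only", index=bench.gt.cells.index)
        df = ff.trajectory_cluster_consistency(lab, maps)
        assert df["mean_consistency"].isna().all()
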