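"""Trajectory kernel mean embeddings (TKME) and trajectory clustering.

A cell measured at timepoint s is embedded as the concatenation, over all
included timepoints t, of the barycentric projection of that timepoint's
kernel features through the (chained / transposed) row-stochastic coupling:

    Z̃_s = [ Ỹ_{s→t1} | Ỹ_{s→t2} | … | X_s | … | Ỹ_{s→tT} ]

with Ỹ_{s→s} = X_s, the cell's own kernel features. Because the projection
of kernel features is a kernel mean embedding, each block summarizes where
the cell's probable past/future sits in that timepoint's cell-density
landscape; clustering Z̃ groups whole trajectories rather than snapshots.

Kernel features are a d=50 Nystroem approximation of a Gaussian RBF kernel
whose bandwidth is the median inter-cell Euclidean distance at the
timepoint. Clustering on features restricted to late timepoints (after
day 6 by default) avoids confounding by migration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.kernel_approximation import Nystroem

from .ot_core import TransportMap, chain_maps, row_normalize, transpose_map


@dataclass
class KernelApproximator:
    timepoint: float
    bandwidth: float
    nystroem: Nystroem
    d: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return self.nystroem.transform(np.asarray(coords, dtype=np.float64))


def median_bandwidth(coords: np.ndarray, max_cells: int = 2000, seed: int = 0) -> float:
    X = np.asarray(coords, dtype=np.float64)
    if X.shape[0] > max_cells:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_cells, replace=False)]
    return float(np.median(pdist(X)))


def fit_kernel_features(coords: np.ndarray, timepoint: float = 0.0, d: int = 50,
                        seed: int = 0) -> KernelApproximator:
    """Fit a d-landmark Nystroem RBF approximation at one timepoint.

    Bandwidth = median pairwise Euclidean distance among the timepoint's
    cells; landmarks drawn uniformly at random under the seed. If fewer
    than d cells are present d is lowered with a warning.
    """
    X = np.asarray(coords, dtype=np.float64)
    n = X.shape[0]
    if n < d:
        warnings.warn(f"only {n} cells at timepoint {timepoint}; lowering d from {d} to {n}")
        d = n
    bw = median_bandwidth(X, seed=seed)
    if bw <= 0:
        raise ValueError(f"degenerate cells at timepoint {timepoint}: median distance is 0")
    gamma = 1.0 / (2.0 * bw * bw)
    ny = Nystroem(kernel="rbf", gamma=gamma, n_components=d, random_state=seed)
    ny.fit(X)
    return KernelApproximator(timepoint=timepoint, bandwidth=bw, nystroem=ny, d=d)


@dataclass
class TKMEEmbedding:
    Z: np.ndarray
    cell_ids: pd.Index
    cell_timepoints: np.ndarray
    block_timepoints: list[float]
    d: int


def _pairwise_hats(maps: list[TransportMap]) -> tuple[dict, dict, list[float]]:
    """Forward and backward single-step row-stochastic maps keyed by (s, t)."""
    fwd, bwd = {}, {}
    tps = []
    for tm in sorted(maps, key=lambda m: m.source_timepoint):
        fwd[(tm.source_timepoint, tm.target_timepoint)] = row_normalize(tm)
        bwd[(tm.target_timepoint, tm.source_timepoint)] = transpose_map(tm)
        if tm.source_timepoint not in tps:
            tps.append(tm.source_timepoint)
        if tm.target_timepoint not in tps:
            tps.append(tm.target_timepoint)
    return fwd, bwd, sorted(tps)


def chained_map(maps: list[TransportMap], s: float, t: float) -> np.ndarray:
    """Row-stochastic map from timepoint s to t, chained over adjacent steps.

    Uses the transpose rule for s > t and Markov chaining for non-adjacent
    pairs; re-normalizes after every product.
    """
    fwd, bwd, tps = _pairwise_hats(maps)
    if s == t:
        raise ValueError("s == t has no coupling (own features are used instead)")
    si, ti = tps.index(s), tps.index(t)
    steps = []
    if si < ti:
        for k in range(si, ti):
            steps.append(fwd[(tps[k], tps[k + 1])])
    else:
        for k in range(si, ti, -1):
            steps.append(bwd[(tps[k], tps[k - 1])])
    return chain_maps(*steps)


def tkme_embed(
    tc,
    maps: list[TransportMap],
    kernels: dict[float, KernelApproximator],
    coords: dict[float, np.ndarray],
    include_days_after: float = 6.0,
    standardize_blocks: bool = True,
) -> TKMEEmbedding:
    """Embed every cell of the time course into trajectory space.

    ``coords`` maps each timepoint to the (global-PCA) coordinates of the
    cells the couplings were fitted on, row-aligned with the maps'
    source/target id lists. Only timepoints strictly greater than
    ``include_days_after`` contribute feature blocks; blocks are ordered by
    ascending timepoint and optionally variance-scaled so no single
    timepoint dominates the clustering.
    """
    fwd, bwd, tps = _pairwise_hats(maps)
    included = [t for t in tps if t > include_days_after]
    if not included:
        raise ValueError(f"no timepoints after day {include_days_after}")
    missing = [t for t in included if t not in kernels or t not in coords]
    if missing:
        raise ValueError(f"missing kernel or coordinates for timepoints {missing}")
    feats = {t: kernels[t].transform(coords[t]) for t in included}
    d = next(iter(kernels.values())).d

    ids_at: dict[float, list] = {}
    for tm in maps:
        ids_at.setdefault(tm.source_timepoint, tm.source_ids)
        ids_at.setdefault(tm.target_timepoint, tm.target_ids)

    blocks_per_tp: dict[float, np.ndarray] = {}
    all_ids, all_tps = [], []
    for s in tps:
        rows = []
        for t in included:
            if s == t:
                rows.append(feats[t])
            else:
                rows.append(chained_map(maps, s, t) @ feats[t])
        blocks_per_tp[s] = np.hstack(rows)
        all_ids.extend(ids_at[s])
        all_tps.extend([s] * len(ids_at[s]))
    Z = np.vstack([blocks_per_tp[s] for s in tps])
    if standardize_blocks:
        nb = len(included)
        for k in range(nb):
            blk = Z[:, k * d:(k + 1) * d]
            sd = blk.std()
            if sd > 0:
                Z[:, k * d:(k + 1) * d] = blk / sd
    return TKMEEmbedding(
        Z=Z, cell_ids=pd.Index(all_ids), cell_timepoints=np.asarray(all_tps, float),
        block_timepoints=included, d=d,
    )


# -- clustering ------------------------------------------------------------

def leiden_labels(X: np.ndarray, k_nn: int = 15, resolution: float = 1.0,
                  seed: int = 0) -> np.ndarray:
    """Leiden community labels on a kNN graph of the rows of X."""
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    n = X.shape[0]
    k = min(k_nn, n - 1)
    if k < k_nn:
        warnings.warn(f"only {n} cells; lowering k_nn from {k_nn} to {k}")
    A = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
    A = A.maximum(A.T).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(A.row.tolist(), A.col.tolist())),
                     directed=False)
    g.simplify()
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=-1,
    )
    return np.asarray(part.membership)


def cluster_trajectories(
    emb: TKMEEmbedding | np.ndarray,
    method: str = "leiden",
    k: int | None = None,
    resolution: float = 1.0,
    k_nn: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Cluster TKME vectors into discrete trajectories (Leiden or k-means)."""
    Z = emb.Z if isinstance(emb, TKMEEmbedding) else np.asarray(emb, dtype=np.float64)
    if not np.isfinite(Z).all():
        raise ValueError("embedding contains non-finite values")
    if method == "leiden":
        labels = leiden_labels(Z, k_nn=k_nn, resolution=resolution, seed=seed)
    elif method == "kmeans":
        if k is None:
            raise ValueError("k-means requires k")
        if k > Z.shape[0]:
            raise ValueError(f"k={k} exceeds number of cells {Z.shape[0]}")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(Z)
    else:
        raise ValueError(f"unknown method {method!r}")
    idx = emb.cell_ids if isinstance(emb, TKMEEmbedding) else None
    return pd.Series(labels, index=idx, name=f"trajectory_{method}").astype(str)


def supercells(coords: np.ndarray, k_nn: int = 15, resolution: float = 1.0,
               seed: int = 0) -> np.ndarray:
    """Timepoint-local Leiden communities used as Sankey nodes."""
    return leiden_labels(np.asarray(coords, dtype=np.float64), k_nn=k_nn,
                         resolution=resolution, seed=seed)


def trajectory_cluster_consistency(
    labels: pd.Series,
    maps: list[TransportMap],
) -> pd.DataFrame:
    """Mean fate consistency of a clustering at every adjacent interval."""
    from .fate import fate_consistency, fate_propensities

    rows = []
    for tm in sorted(maps, key=lambda m: m.source_timepoint):
        P_hat = row_normalize(tm)
        tgt = labels.reindex(tm.target_ids)
        if tgt.isna().any():
            raise ValueError("unlabeled target cells")
        prop = fate_propensities(P_hat, tgt)
        try:
            _, mean_cons = fate_consistency(prop, tgt)
        except ValueError:
            mean_cons = np.nan       # single occupied target cluster: undefined
        rows.append({
            "source_timepoint": tm.source_timepoint,
            "target_timepoint": tm.target_timepoint,
            "mean_consistency": mean_cons,
            "mean_entropy": float(prop.entropy.mean()),
        })
    return pd.DataFrame(rows)
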