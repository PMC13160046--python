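"""Canonical-state assignment from pairwise gene-set scores, and temporal
gene-module clustering with windowed DTW + k-medoids.

States are scored with composite pairwise scores: for each ordered state
pair (A, B) a gene list l_{A/B} (genes up in A vs B, supplied as input)
yields a per-cell score s_{A/B}; the composite is
ŝ_A = Σ_{k≠A} (s_{A/k} − s_{k/A}), so both up- and down-regulated genes
inform the call. Cells take the argmax state among those whose day window
(mask) admits the cell's timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import child_seed
from .growth import gene_set_score


@dataclass
class CompositeScore:
    scores: pd.DataFrame            # cells x states, ŝ_A
    pair_scores: dict = field(default_factory=dict)   # (A, B) -> per-cell s_{A/B}
    states: list[str] = field(default_factory=list)


def composite_scores(
    snapshot,
    pairwise_lists: dict[tuple[str, str], list[str]],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> CompositeScore:
    """Composite state scores ŝ_A = Σ_{k≠A}(s_{A/k} − s_{k/A}) per cell.

    ``pairwise_lists[(A, B)]`` is the gene list up-regulated in A vs B.
    Control draws are redrawn per pair with a pair-indexed seed.
    """
    states = sorted({s for pair in pairwise_lists for s in pair})
    pair_scores: dict[tuple[str, str], np.ndarray] = {}
    for (A, B), genes in pairwise_lists.items():
        gs = gene_set_score(
            snapshot, genes, n_bins=n_bins, ctrl_size=ctrl_size,
            seed=child_seed(seed, A, B), gene_set_id=f"{A}/{B}",
        )
        pair_scores[(A, B)] = gs.values
    n = next(iter(pair_scores.values())).size
    comp = {}
    for A in states:
        total = np.zeros(n)
        for k in states:
            if k == A:
                continue
            if (A, k) not in pair_scores or (k, A) not in pair_scores:
                raise ValueError(f"missing pairwise list for states ({A}, {k})")
            total += pair_scores[(A, k)] - pair_scores[(k, A)]
        comp[A] = total
    import anndata as ad

    adata = snapshot if isinstance(snapshot, ad.AnnData) else snapshot.adata
    scores = pd.DataFrame(comp, index=adata.obs_names)[states]
    return CompositeScore(scores=scores, pair_scores=pair_scores, states=states)


def assign_states(
    scores: CompositeScore | pd.DataFrame,
    timepoints: np.ndarray,
    masks: dict[str, tuple[float, float]] | None = None,
) -> pd.Series:
    """Argmax state per cell among states unmasked at the cell's day.

    ``masks[state] = (day_min, day_max)`` is the inclusive window inside
    which the state may be assigned; outside it the state's score is
    treated as missing (never a −inf surrogate that could leak into
    downstream numerics). Ties break by state-name order. A timepoint where
    every state is masked raises.
    """
    df = scores.scores if isinstance(scores, CompositeScore) else scores
    df = df[sorted(df.columns)]          # deterministic tie-break order
    tp = np.asarray(timepoints, dtype=float)
    if tp.size != len(df):
        raise ValueError("timepoints do not match score rows")
    masks = masks or {}
    allowed = pd.DataFrame(True, index=df.index, columns=df.columns)
    for state, (lo, hi) in masks.items():
        if state in allowed.columns:
            allowed[state] = (tp >= lo) & (tp <= hi)
    if (~allowed).all(axis=1).any():
        bad = tp[(~allowed).all(axis=1).to_numpy()][0]
        raise ValueError(f"all states masked at day {bad}")
    masked = df.where(allowed)
    # idxmax is left-to-right on ties; columns are in sorted state order
    return masked.idxmax(axis=1).rename("state")


# The day windows inside which each canonical CD8 subset terminology applies.
DEFAULT_STATE_MASKS: dict[str, tuple[float, float]] = {
    "Naive": (0.0, 5.0),
    "EEC": (0.0, 10.0),
    "MP": (0.0, 10.0),
    "TE": (0.0, 10.0),
    "TCM": (14.0, np.inf),
    "TEM": (14.0, np.inf),
    "t-TEM": (14.0, np.inf),
}


# -- temporal gene modules -------------------------------------------------

def dtw_distance(series_a: np.ndarray, series_b: np.ndarray, window: int = 2) -> float:
    """Sakoe–Chiba banded DTW between equal-length temporal profiles.

    Local cost is the squared difference; the returned distance is the
    square root of the accumulated cost along the optimal warping path.
    A window no smaller than the series length reproduces unconstrained DTW.
    """
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty series")
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n = a.size
    w = max(int(window), 0)
    D = np.full((n + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        lo = max(1, i - w)
        hi = min(n, i + w)
        for j in range(lo, hi + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            D[i, j] = cost + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(np.sqrt(D[n, n]))


def dtw_distance_matrix(profiles: np.ndarray, window: int = 2) -> np.ndarray:
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(X[i], X[j], window=window)
    return D


@dataclass
class GeneModuleClustering:
    labels: np.ndarray
    medoid_indices: np.ndarray
    distance_matrix: np.ndarray
    inertia: float


def kmedoids_modules(
    profiles: np.ndarray,
    k: int,
    window: int = 2,
    seed: int = 0,
    max_iters: int = 100,
    n_init: int = 5,
) -> GeneModuleClustering:
    """PAM-style k-medoids on the pairwise DTW distance matrix.

    ``n_init`` seeded restarts of alternating assignment / medoid-update
    steps; the solution with the lowest total within-module cost is kept
    (the cost is non-increasing across iterations within a restart).
    Medoids are always member profiles.
    """
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} profiles")
    D = dtw_distance_matrix(X, window=window)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(int(n_init), 1)):
        medoids = rng.choice(n, size=k, replace=False)
        labels = np.argmin(D[:, medoids], axis=1)
        for _ in range(max_iters):
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.where(labels == c)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = members[int(np.argmin(within))]
            new_labels = np.argmin(D[:, new_medoids], axis=1)
            if (np.array_equal(new_medoids, medoids)
                    and np.array_equal(new_labels, labels)):
                break
            medoids, labels = new_medoids, new_labels
        inertia = float(sum(D[i, medoids[labels[i]]] for i in range(n)))
        if best is None or inertia < best[0]:
            best = (inertia, medoids.copy(), labels.copy())
    inertia, medoids, labels = best
    return GeneModuleClustering(labels=labels, medoid_indices=medoids,
                                distance_matrix=D, inertia=inertia)


def mean_temporal_profiles(tc, genes: list[str], compartment: str | None = None) -> pd.DataFrame:
    """Gene x timepoint matrix of mean expression (one compartment or all)."""
    from ._utils import as_dense

    cols = {}
    for t in tc.timepoints:
        try:
            snap = tc.snapshot(t, compartment)
        except ValueError:
            continue
        X = as_dense(snap[:, genes].X)
        cols[t] = X.mean(axis=0)
    return pd.DataFrame(cols, index=genes)
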