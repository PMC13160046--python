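"""Cluster-level fate flows (Sankey tables) and Sinkhorn EMD distances."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fate import one_hot
from .ot_core import SolverConfig, cost_matrix, solve_uot


@dataclass
class FateFlowTable:
    """Inflow/outflow probability-mass matrices around a middle timepoint s.

    F_in[i, j]  = expected number of cluster-i cells at s drawn from
    cluster j at the previous timepoint r (via the transposed backward map);
    F_out[i, j] = expected number of cluster-i cells at s flowing into
    cluster j at the next timepoint t. Row-stochastic maps contribute
    exactly one unit of mass per s cell, so each matrix totals the number
    of cells at s.
    """

    F_in: np.ndarray | None
    F_out: np.ndarray | None
    clusters_r: list = field(default_factory=list)
    clusters_s: list = field(default_factory=list)
    clusters_t: list = field(default_factory=list)
    timepoint: float = 0.0


def fate_flow(
    labels_s,
    labels_r=None,
    labels_t=None,
    P_sr: np.ndarray | None = None,
    P_st: np.ndarray | None = None,
    timepoint: float = 0.0,
) -> FateFlowTable:
    """F_in = Cₛᵀ P̂_{s,r} C_r and F_out = Cₛᵀ P̂_{s,t} C_t.

    ``P_sr`` is the backward row-stochastic map (transpose rule applied
    upstream); either side may be omitted at the ends of the course.
    """
    Cs, cats_s = one_hot(labels_s)
    F_in = F_out = None
    cats_r: list = []
    cats_t: list = []
    if P_sr is not None:
        if labels_r is None:
            raise ValueError("labels_r required with P_sr")
        Cr, cats_r = one_hot(labels_r)
        P = np.asarray(P_sr, float)
        if P.shape != (Cs.shape[0], Cr.shape[0]):
            raise ValueError("P_sr shape does not match label counts")
        F_in = Cs.T @ P @ Cr
    if P_st is not None:
        if labels_t is None:
            raise ValueError("labels_t required with P_st")
        Ct, cats_t = one_hot(labels_t)
        P = np.asarray(P_st, float)
        if P.shape != (Cs.shape[0], Ct.shape[0]):
            raise ValueError("P_st shape does not match label counts")
        F_out = Cs.T @ P @ Ct
    return FateFlowTable(F_in=F_in, F_out=F_out, clusters_r=cats_r,
                         clusters_s=cats_s, clusters_t=cats_t, timepoint=timepoint)


def sankey_export(
    table: FateFlowTable,
    node_colors: dict | None = None,
    prune_below: float = 0.0,
    normalize: bool = False,
) -> pd.DataFrame:
    """Flatten flow matrices to (source, target, mass[, color]) link records.

    Masses are preserved exactly (optionally also reported normalized per
    flow matrix); links below ``prune_below`` are dropped (default keeps
    all). Nodes are ordered by descending cluster mass with a stable id
    tie-break.
    """
    recs = []
    for F, src_cats, tgt_cats, kind in (
        (table.F_in, table.clusters_s, table.clusters_r, "in"),
        (table.F_out, table.clusters_s, table.clusters_t, "out"),
    ):
        if F is None:
            continue
        total = F.sum()
        order = np.argsort([-F.sum(axis=1)[i] for i in range(F.shape[0])], kind="stable")
        for i in order:
            for j in range(F.shape[1]):
                if F[i, j] < prune_below:
                    continue
                rec = {
                    "flow": kind,
                    "timepoint": table.timepoint,
                    "source": str(src_cats[i]),
                    "target": str(tgt_cats[j]),
                    "mass": float(F[i, j]),
                }
                if normalize and total > 0:
                    rec["mass_normalized"] = float(F[i, j] / total)
                if node_colors is not None:
                    rec["color"] = node_colors.get(src_cats[i])
                recs.append(rec)
    return pd.DataFrame(recs)


def flow_table_from_records(records: pd.DataFrame, kind: str = "out") -> np.ndarray:
    """Rebuild a flow matrix from exported link records (round-trip helper)."""
    sub = records[records["flow"] == kind]
    piv = sub.pivot_table(index="source", columns="target", values="mass",
                          aggfunc="sum", fill_value=0.0)
    return piv.sort_index().sort_index(axis=1).to_numpy()


# -- distributional distances ---------------------------------------------

@dataclass
class EMDResult:
    value: float
    epsilon: float
    draws: np.ndarray | None = None


def _sinkhorn_cost(X: np.ndarray, Y: np.ndarray, epsilon: float) -> float:
    """Entropic OT objective ⟨P,C⟩ − εℋ(P) with uniform balanced marginals."""
    C = cost_matrix(X, Y)
    m, n = C.shape
    a = np.full(m, 1.0 / m)
    b = np.full(n, 1.0 / n)
    cfg = SolverConfig(epsilon=epsilon, tau_a=1.0, tau_b=1.0,
                       max_iters=20_000, tolerance=1e-12)
    tm = solve_uot(C, a, b, cfg)
    P = tm.coupling
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -float(np.where(P > 0, P * np.log(P), 0.0).sum())
    return float((P * C).sum() - epsilon * ent)


def emd(X_A: np.ndarray, X_B: np.ndarray, epsilon: float = 1.0) -> EMDResult:
    """Unbiased Sinkhorn EMD between two cell populations.

    EMD_unbiased(A, B) = EMD(A, B) − ½ EMD(A, A) − ½ EMD(B, B), removing
    the entropic self-distance bias so that the self-distance is ~0. Uses
    uniform marginals, balanced OT and Euclidean cost on the given (PCA)
    coordinates. Not a metric (no triangle inequality is claimed).
    """
    A = np.atleast_2d(np.asarray(X_A, float))
    B = np.atleast_2d(np.asarray(X_B, float))
    if A.size == 0 or B.size == 0:
        raise ValueError("empty population")
    ab = _sinkhorn_cost(A, B, epsilon)
    aa = _sinkhorn_cost(A, A, epsilon)
    bb = _sinkhorn_cost(B, B, epsilon)
    return EMDResult(value=ab - 0.5 * aa - 0.5 * bb, epsilon=epsilon)


def emd_bootstrap(
    X_A: np.ndarray,
    X_B: np.ndarray,
    epsilon: float = 1.0,
    n_cells: int = 100,
    n_boot: int = 10,
    seed: int = 0,
) -> EMDResult:
    """Bootstrap distribution of the unbiased EMD on ``n_cells`` subsamples."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    A = np.atleast_2d(np.asarray(X_A, float))
    B = np.atleast_2d(np.asarray(X_B, float))
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        sub = []
        for X in (A, B):
            if X.shape[0] < n_cells:
                warnings.warn(
                    f"population of {X.shape[0]} < n_cells={n_cells}; "
                    "sampling with replacement")
                idx = rng.choice(X.shape[0], n_cells, replace=True)
            else:
                idx = rng.choice(X.shape[0], n_cells, replace=False)
            sub.append(X[idx])
        draws[i] = emd(sub[0], sub[1], epsilon=epsilon).value
    return EMDResult(value=float(draws.mean()), epsilon=epsilon, draws=draws)
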