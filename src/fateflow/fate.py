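"""Fate-level readouts of fitted couplings.

Everything here consumes row-stochastic maps P̂ (see :mod:`fateflow.ot_core`):
barycentric projections Ỹ_{s→t} = P̂ X_t, per-gene trajectory correlations,
fate propensities Q̃ = P̂ C_t with Shannon entropy and a size-normalized
consistency score, compartment egress probabilities, and arrival-time
estimation for tissue cells via backward-chained maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.isotonic import IsotonicRegression

from .ot_core import TransportMap, chain_maps, row_normalize, transpose_map


def one_hot(labels) -> tuple[np.ndarray, list]:
    """Binary cluster matrix C ∈ {0,1}^(n×k) with a stable category order."""
    lab = pd.Series(labels).astype(str)
    if lab.isna().any():
        raise ValueError("unlabeled cells present")
    cats = sorted(lab.unique())
    C = (lab.to_numpy()[:, None] == np.array(cats)[None, :]).astype(float)
    return C, cats


def barycentric_project(P_hat: np.ndarray, X_t: np.ndarray) -> np.ndarray:
    """Expected target features per source cell: Ỹ_{s→t} = P̂_{s,t} X_t."""
    P = np.asarray(P_hat, dtype=np.float64)
    X = np.asarray(X_t, dtype=np.float64)
    if P.shape[1] != X.shape[0]:
        raise ValueError(f"P̂ has {P.shape[1]} columns but X_t has {X.shape[0]} rows")
    return P @ X


def project_expression(P_hat: np.ndarray, target_snapshot, genes: list[str]) -> pd.DataFrame:
    """Predicted next-timepoint expression of named genes for each source cell."""
    from ._utils import as_dense

    var = pd.Index(target_snapshot.var_names)
    missing = [g for g in genes if g not in var]
    if missing:
        raise KeyError(f"unknown gene(s): {missing}")
    X = as_dense(target_snapshot[:, genes].X)
    Y = barycentric_project(P_hat, X)
    return pd.DataFrame(Y, columns=genes)


@dataclass
class GeneTrajectoryCorrelation:
    per_interval: pd.DataFrame      # genes x intervals, Spearman rho
    median: pd.Series               # per-gene median over defined intervals
    top: list[str] = field(default_factory=list)


def trajectory_gene_correlations(
    tc,
    maps: list[TransportMap],
    genes: list[str],
    top_k: int = 100,
) -> GeneTrajectoryCorrelation:
    """Lineage stability of genes under the couplings.

    For each adjacent interval (s, t), the per-gene Spearman correlation
    between the observed expression at s and the barycentric projection of
    the same gene from t back onto the s cells. Genes whose column is
    constant at either end of an interval have no defined rank correlation
    there; such intervals are dropped from that gene's median (never
    zero-filled). The ``top_k`` genes by median correlation (gene-id
    tie-break) are the lineage-stable candidates.
    """
    from ._utils import as_dense

    genes = [g for g in genes if g in tc.gene_index]
    cols = {}
    for tm in maps:
        P_hat = row_normalize(tm)
        Xs = as_dense(tc.adata[tm.source_ids, genes].X)
        Xt = as_dense(tc.adata[tm.target_ids, genes].X)
        Y = barycentric_project(P_hat, Xt)
        rho = np.full(len(genes), np.nan)
        for j in range(len(genes)):
            xs, ys = Xs[:, j], Y[:, j]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                continue
            rho[j] = spearmanr(xs, ys).statistic
        cols[(tm.source_timepoint, tm.target_timepoint)] = rho
    per_interval = pd.DataFrame(cols, index=genes)
    med = per_interval.median(axis=1, skipna=True)
    order = med.to_frame("m").assign(g=med.index).sort_values(["m", "g"], ascending=[False, True])
    top = list(order.index[: min(top_k, len(order))])
    return GeneTrajectoryCorrelation(per_interval=per_interval, median=med, top=top)


@dataclass
class FatePropensity:
    Q: np.ndarray                  # m x k cluster propensities, rows sum to 1
    clusters: list
    entropy: np.ndarray            # per-cell Shannon entropy, nats


def fate_propensities(P_hat: np.ndarray, target_labels) -> FatePropensity:
    """Q̃_{s→t} = P̂_{s,t} C_t with per-cell entropy ℋ = −Σ q log q (nats)."""
    C, cats = one_hot(target_labels)
    P = np.asarray(P_hat, dtype=np.float64)
    if P.shape[1] != C.shape[0]:
        raise ValueError("target labels do not match coupling columns")
    Q = P @ C
    Q = Q / Q.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.where(Q > 0, Q * np.log(Q), 0.0).sum(axis=1)
    return FatePropensity(Q=Q, clusters=cats, entropy=H)


def null_entropy(target_labels) -> float:
    """ℋ0 = −Σ p_k log p_k from the target cluster frequencies."""
    freq = pd.Series(target_labels).astype(str).value_counts(normalize=True).to_numpy()
    return float(-(freq * np.log(freq)).sum())


def fate_consistency(prop: FatePropensity, target_labels) -> tuple[np.ndarray, float]:
    """Consistency = 1 − ℋ/ℋ0 per cell, plus its mean.

    1 for cluster-preserving deterministic flows, 0 for a product coupling
    (no information beyond cluster sizes), negative for anti-concentrated
    flows on unequal clusters. Undefined when a single cluster occupies the
    target timepoint.
    """
    H0 = null_entropy(target_labels)
    if H0 <= 0:
        raise ValueError("null entropy is zero (single occupied target cluster); "
                         "consistency undefined")
    cons = 1.0 - prop.entropy / H0
    return cons, float(cons.mean())


@dataclass
class MigrationEstimate:
    per_cell: pd.DataFrame
    summary: pd.DataFrame | None = None


def egress_probabilities(
    maps: list[TransportMap],
    compartments: pd.Series,
) -> MigrationEstimate:
    """Per-cell probability of changing compartment over each interval.

    ``compartments`` maps cell id -> compartment label at its own timepoint.
    For a source cell i, P(egress) = Σ_{j in other compartment} P̂_ij.
    The summary gives mean ± SEM per (interval, source compartment).
    """
    comp = pd.Series(compartments).astype(str)
    rows = []
    for tm in maps:
        P_hat = row_normalize(tm)
        src = comp.reindex(tm.source_ids)
        tgt = comp.reindex(tm.target_ids)
        if src.isna().any() or tgt.isna().any():
            raise ValueError("missing compartment labels for some cells")
        cross = src.to_numpy()[:, None] != tgt.to_numpy()[None, :]
        p = (P_hat * cross).sum(axis=1)
        rows.append(pd.DataFrame({
            "cell_id": tm.source_ids,
            "source_timepoint": tm.source_timepoint,
            "target_timepoint": tm.target_timepoint,
            "compartment": src.to_numpy(),
            "egress_probability": p,
            "egress_hi": p > 0.5,
        }))
    per_cell = pd.concat(rows, ignore_index=True)
    grp = per_cell.groupby(["source_timepoint", "compartment"])["egress_probability"]
    summary = grp.agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="size")
    return MigrationEstimate(per_cell=per_cell, summary=summary.reset_index())


def backward_membership(
    maps: list[TransportMap],
    compartments: pd.Series,
    query_timepoint: float,
) -> tuple[pd.DataFrame, list]:
    """P(ancestor at t is in each cell's own query compartment), all t < query.

    Backward maps come from the transpose rule P̂_{t,s} ∝ P_{s,t}ᵀ chained
    Markov-fashion from the query timepoint down to each earlier timepoint.
    """
    comp = pd.Series(compartments).astype(str)
    maps = sorted(maps, key=lambda m: m.source_timepoint)
    upto = [m for m in maps if m.target_timepoint <= query_timepoint]
    if not upto or upto[-1].target_timepoint != query_timepoint:
        raise ValueError(f"no coupling ends at query timepoint {query_timepoint}")
    query_ids = upto[-1].target_ids
    q_cols = {}
    back = None
    for tm in reversed(upto):
        step = transpose_map(tm)                       # target -> source
        back = step if back is None else chain_maps(back, step)
        anc_comp = comp.reindex(tm.source_ids)
        if anc_comp.isna().any():
            raise ValueError("missing compartment labels for ancestor cells")
        own = comp.reindex(query_ids).to_numpy()
        ind = (anc_comp.to_numpy()[None, :] == own[:, None]).astype(float)
        q_cols[tm.source_timepoint] = (back * ind).sum(axis=1)
    q = pd.DataFrame(q_cols, index=query_ids).sort_index(axis=1)
    return q, query_ids


def arrival_times(
    maps: list[TransportMap],
    compartments: pd.Series,
    query_timepoint: float,
    query_compartment: str,
    mode: str = "expectation",
) -> MigrationEstimate:
    """Expected arrival day into a compartment for cells observed there.

    For each query cell the backward membership curve q_t (probability its
    ancestor at day t already sat in the query compartment) is made
    non-decreasing toward the query day by isotonic regression; the
    increments Δq over the pre-query days — with the residual mass
    1 − q_last attributed to the last pre-query day, since entry during the
    final interval cannot be resolved further — form an arrival
    distribution. ``mode="expectation"`` returns Σ t·Δq; ``mode="mode"``
    returns the day with the largest increment.
    """
    if mode not in ("expectation", "mode"):
        raise ValueError("mode must be 'expectation' or 'mode'")
    comp = pd.Series(compartments).astype(str)
    q, query_ids = backward_membership(maps, comp, query_timepoint)
    in_query = comp.reindex(query_ids) == query_compartment
    if not in_query.any():
        raise ValueError(
            f"no cells at {query_timepoint} in compartment {query_compartment!r}")
    q = q.loc[in_query.to_numpy()]
    days = q.columns.to_numpy(dtype=float)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    est = np.empty(len(q))
    for i, (_, row) in enumerate(q.iterrows()):
        qt = iso.fit_transform(days, row.to_numpy())
        qt[-1] = 1.0                                  # entry by the final interval is certain
        inc = np.diff(np.concatenate([[0.0], qt]))
        tot = inc.sum()
        w = inc / tot if tot > 0 else np.full_like(inc, 1.0 / len(inc))
        if mode == "expectation":
            est[i] = float((days * w).sum())
        else:
            est[i] = float(days[int(np.argmax(w))])
    per_cell = pd.DataFrame({
        "cell_id": q.index,
        "arrival_time": est,
        "query_timepoint": query_timepoint,
        "compartment": query_compartment,
    })
    qlo, qhi = np.percentile(est, [25, 75])
    # quartile boundaries: ties go to the inner (mid) group
    per_cell["arrival_group"] = np.where(
        est < qlo, "early", np.where(est > qhi, "late", "mid"))
    return MigrationEstimate(per_cell=per_cell)
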