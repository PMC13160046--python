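"""Growth-calibrated source marginals from proliferation/apoptosis scores.

Each source cell i gets an unnormalized growth factor

    g_i = exp(δ_i · Δt / σ),      δ_i = clip(y_i^prolif − y_i^apop, q95)

with Δt = t_target − t_source in days and δ clipped at the within-timepoint
95th percentile to prevent a single outlier cell from absorbing the whole
source marginal ("marginal collapse"). σ is calibrated so that the largest
per-day growth factor equals a biological cap g_max (default 2³ = 8, i.e.
three divisions per day): per timepoint σ_t = max_i δ_i(t) / log(g_max),
then σ = max_t σ_t. Source marginals are a_i = g_i / Σ g_i. Population
sizes are reconstructed with the recurrence N_t = N_{t−1} · mean_i g_i(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_dense, child_seed


@dataclass
class GeneSetScore:
    """Per-cell gene-set score (mean over set minus binned-control mean)."""

    values: np.ndarray
    gene_set_id: str = ""
    n_bins: int = 25
    ctrl_size: int = 50
    seed: int = 0


@dataclass
class GrowthPrior:
    delta: np.ndarray          # clipped score differentials
    sigma: float
    dt: float                  # t_target - t_source, days
    g: np.ndarray = field(init=False)
    a: np.ndarray = field(init=False)
    g_max: float = 8.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0 (t_target must exceed t_source)")
        self.g = np.exp(self.delta * self.dt / self.sigma)
        self.a = self.g / self.g.sum()


@dataclass
class PopulationSeries:
    timepoints: np.ndarray
    sizes: np.ndarray
    n0: float = 1000.0


def gene_set_score(
    snapshot,
    gene_set: list[str],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
    gene_set_id: str = "",
    control_genes: list[str] | None = None,
) -> GeneSetScore:
    """Score a gene set per cell against expression-matched controls.

    score = mean expression over the set − mean over a control set of
    ``ctrl_size`` genes drawn (with a fixed seed) from the same
    average-expression bin as each set gene, out of ``n_bins`` bins.
    ``control_genes`` overrides the binned draw (used for testing and for
    self-referential degenerate cases). Expects log-normalized data.
    """
    import anndata as ad

    adata = snapshot if isinstance(snapshot, ad.AnnData) else snapshot.adata
    var_names = pd.Index(adata.var_names)
    genes = [g for g in gene_set if g in var_names]
    dropped = len(gene_set) - len(genes)
    if dropped:
        warnings.warn(f"{dropped} gene(s) of set {gene_set_id!r} absent from data; dropped")
    if not genes:
        raise ValueError(f"gene set {gene_set_id!r} has no genes in the data")
    X = as_dense(adata.X)
    gmean = X.mean(axis=0)
    idx = var_names.get_indexer(genes)
    if control_genes is not None:
        cidx = var_names.get_indexer([g for g in control_genes if g in var_names])
        ctrl = np.unique(cidx)
    else:
        # rank genes by average expression, cut into n_bins equal-size bins
        order = np.argsort(gmean, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(order))
        bins = (ranks * n_bins) // max(len(order), 1)
        rng = np.random.default_rng(child_seed(seed, gene_set_id, "ctrl"))
        ctrl_set: set[int] = set()
        for gi in idx:
            pool = np.where(bins == bins[gi])[0]
            take = min(ctrl_size, pool.size)
            ctrl_set.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl = np.array(sorted(ctrl_set - set(idx.tolist())) or sorted(ctrl_set))
    if ctrl.size == 0:
        raise ValueError("control gene set is empty")
    score = X[:, idx].mean(axis=1) - X[:, ctrl].mean(axis=1)
    return GeneSetScore(values=score, gene_set_id=gene_set_id, n_bins=n_bins,
                        ctrl_size=ctrl_size, seed=seed)


def clipped_differential(
    prolif: GeneSetScore | np.ndarray,
    apop: GeneSetScore | np.ndarray,
    clip_q: float = 0.95,
    clip_lower: bool = False,
) -> np.ndarray:
    """δ_i = y^prolif − y^apop clipped at the upper ``clip_q`` quantile.

    Upper-tail clipping guards against marginal collapse onto one highly
    proliferative cell; lower-tail clipping is optional.
    """
    yp = prolif.values if isinstance(prolif, GeneSetScore) else np.asarray(prolif, float)
    ya = apop.values if isinstance(apop, GeneSetScore) else np.asarray(apop, float)
    d = yp - ya
    hi = np.quantile(d, clip_q)
    d = np.minimum(d, hi)
    if clip_lower:
        d = np.maximum(d, np.quantile(d, 1.0 - clip_q))
    return d


def growth_prior(
    prolif: GeneSetScore | np.ndarray,
    apop: GeneSetScore | np.ndarray,
    dt: float,
    sigma: float,
    clip_q: float = 0.95,
    g_max: float = 8.0,
    exponent_sign: float = 1.0,
) -> GrowthPrior:
    """Build the growth prior for one source timepoint.

    ``exponent_sign=-1`` applies the growth exponent with the source-minus-
    target time difference (inverting growth); the default uses
    Δt = t_target − t_source so proliferation-dominant cells get g > 1.
    """
    d = clipped_differential(prolif, apop, clip_q=clip_q) * float(exponent_sign)
    return GrowthPrior(delta=d, sigma=sigma, dt=dt, g_max=g_max)


def calibrate_sigma(
    deltas_per_timepoint: dict[float, np.ndarray],
    g_max: float | None = None,
    divisions_per_day: float = 3.0,
) -> float:
    """Calibrate σ so the fastest cell divides at most ``divisions_per_day``.

    g_max defaults to 2**divisions_per_day. Per timepoint,
    σ_t = max_i δ_i(t) / log(g_max); σ = max_t σ_t, so the per-day growth
    factor of the most proliferative cell equals g_max at the calibrating
    timepoint and is below it elsewhere.
    """
    if g_max is None:
        g_max = 2.0 ** divisions_per_day
    if g_max <= 1:
        raise ValueError("g_max must exceed 1")
    sigmas = []
    for t, d in deltas_per_timepoint.items():
        dmax = float(np.max(d))
        if dmax > 0:
            sigmas.append(dmax / np.log(g_max))
    if not sigmas:
        raise ValueError(
            "no timepoint has a positive clipped differential; "
            "no growth signal to calibrate against — set sigma manually"
        )
    return float(max(sigmas))


def population_sizes(priors: list[GrowthPrior], timepoints: list[float],
                     n0: float = 1000.0) -> PopulationSeries:
    """Reconstruct N_t = N_{t−1} · mean_i g_i(t) from cached interval priors.

    ``timepoints`` are the T observation days; ``priors`` are the T−1
    interval priors ordered by source timepoint.
    """
    if len(priors) != len(timepoints) - 1:
        raise ValueError(
            f"{len(priors)} priors do not cover {len(timepoints)} timepoints "
            "(need one per adjacent interval)"
        )
    N = [float(n0)]
    for p in priors:
        N.append(N[-1] * float(np.mean(p.g)))
    return PopulationSeries(timepoints=np.asarray(timepoints, float),
                            sizes=np.asarray(N), n0=n0)


def cluster_population_kinetics(
    series: PopulationSeries,
    labels_per_timepoint: dict[float, np.ndarray],
) -> pd.DataFrame:
    """Split N_t into per-cluster series by subset proportions.

    Returns a cluster x timepoint DataFrame whose columns sum to N_t.
    """
    cols = {}
    for t, N in zip(series.timepoints, series.sizes):
        if t not in labels_per_timepoint:
            raise ValueError(f"no labels for timepoint {t}")
        lab = pd.Series(labels_per_timepoint[t])
        frac = lab.value_counts(normalize=True)
        cols[t] = frac * N
    df = pd.DataFrame(cols).fillna(0.0)
    return df.sort_index()
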