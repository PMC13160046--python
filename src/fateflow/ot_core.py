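"""Entropic unbalanced optimal transport between adjacent-timepoint snapshots.

The coupling :math:`P^*` between the cells of a source and a target
timepoint is the minimizer of the entropically regularized unbalanced
Kantorovich objective

.. math::

    \\langle P, C\\rangle - \\varepsilon \\mathcal{H}(P)
    + \\lambda_a \\,\\mathrm{KL}(P\\mathbf{1}\\,\\|\\,a)
    + \\lambda_b \\,\\mathrm{KL}(P^\\top\\mathbf{1}\\,\\|\\,b)

where :math:`C` is the Euclidean cost between local-PCA coordinates,
:math:`\\mathcal{H}(P) = -\\langle P, \\log P\\rangle` is the Shannon
entropy of the coupling, and the KL terms let the posterior marginals
deviate from the growth-informed prior ``a`` and the empirical target
``b`` — the relaxation that accommodates proliferation and death. The
marginal-relaxation strength is parameterized by
:math:`\\tau = \\lambda / (\\lambda + \\varepsilon) \\in [0, 1)`, with
:math:`\\tau \\to 1` recovering balanced OT.

The solver runs Sinkhorn scaling iterations in the log domain: with dual
potentials ``f, g`` the coupling is
``P = exp((f[:, None] + g[None, :] - C) / eps)`` and the unbalanced updates
raise each balanced update to the power :math:`\\tau`, which is exact for
KL marginal penalties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp


@dataclass
class SolverConfig:
    """Hyperparameters of the entropic UOT solver.

    ``tau_a``/``tau_b`` in [0, 1]; a value of 1 means that marginal is
    enforced exactly (balanced). ``lambda_a``/``lambda_b`` are derived via
    λ = ε·τ/(1−τ).
    """

    epsilon: float = 0.01
    tau_a: float = 0.95
    tau_b: float = 0.9995
    max_iters: int = 10_000
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        for t in (self.tau_a, self.tau_b):
            if not (0 < t <= 1):
                raise ValueError("tau must lie in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    def lam(self, tau: float) -> float:
        """Marginal KL weight λ = ε·τ/(1−τ) (inf for the balanced τ=1)."""
        return np.inf if tau >= 1 else self.epsilon * tau / (1.0 - tau)

    @property
    def lambda_a(self) -> float:
        return self.lam(self.tau_a)

    @property
    def lambda_b(self) -> float:
        return self.lam(self.tau_b)


# Presets used for the three trajectory model variants.
PRESETS: dict[str, SolverConfig] = {
    "single": SolverConfig(epsilon=0.01, tau_a=0.95, tau_b=0.9995),
    "combined": SolverConfig(epsilon=0.05, tau_a=0.95, tau_b=0.95),
}


@dataclass
class TransportMap:
    """A fitted coupling between two timepoints."""

    coupling: np.ndarray
    source_ids: list = field(default_factory=list)
    target_ids: list = field(default_factory=list)
    source_timepoint: float = 0.0
    target_timepoint: float = 1.0
    prior_a: np.ndarray | None = None
    prior_b: np.ndarray | None = None
    config: SolverConfig | None = None
    converged: bool = True
    n_iters: int = 0
    cost: float = 0.0

    @property
    def posterior_a(self) -> np.ndarray:
        return self.coupling.sum(axis=1)

    @property
    def posterior_b(self) -> np.ndarray:
        return self.coupling.sum(axis=0)


def cost_matrix(source_coords: np.ndarray, target_coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between source and target coordinates."""
    A = np.atleast_2d(np.asarray(source_coords, dtype=np.float64))
    B = np.atleast_2d(np.asarray(target_coords, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    return cdist(A, B, metric="euclidean")


def solve_uot(
    C: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    cfg: SolverConfig | None = None,
    scale_cost: bool = False,
) -> TransportMap:
    """Solve entropic (un)balanced OT by log-domain Sinkhorn iterations.

    Convergence is declared when the L∞ change of both dual potentials
    (on the ε scale) and, for exactly-enforced marginals, the L1 marginal
    residual fall below ``cfg.tolerance``. Non-convergence yields a warning
    and ``converged=False``, never a silent result.

    ``scale_cost=True`` divides C by its mean before solving (making ε
    transferable across datasets) and reports the cost on the original
    scale; off by default.
    """
    cfg = cfg or SolverConfig()
    C = np.asarray(C, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if C.shape != (a.size, b.size):
        raise ValueError(f"cost shape {C.shape} does not match marginals ({a.size}, {b.size})")
    if not np.isfinite(C).all():
        raise ValueError("cost matrix has non-finite entries")
    if (a < 0).any() or (b < 0).any() or a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("marginals must be nonnegative with positive total mass")

    # zero-mass prior entries carry no constraint: drop them and restore after
    ia = np.where(a > 0)[0]
    ib = np.where(b > 0)[0]
    Cs = C[np.ix_(ia, ib)]
    scale = Cs.mean() if (scale_cost and Cs.size and Cs.mean() > 0) else 1.0
    Cs = Cs / scale
    asub, bsub = a[ia], b[ib]

    eps = cfg.epsilon
    loga = np.log(asub)
    logb = np.log(bsub)
    f = np.zeros_like(asub)
    g = np.zeros_like(bsub)
    Ceps = -Cs / eps
    balanced = cfg.tau_a >= 1 and cfg.tau_b >= 1
    converged = False
    it = 0
    err = np.inf
    for it in range(1, cfg.max_iters + 1):
        f_prev = f
        # f-update: f = τ_a * ε * (log a - logsumexp_j((g_j - C_ij)/ε))
        lse_f = logsumexp(Ceps + g[None, :] / eps, axis=1)
        f = cfg.tau_a * eps * (loga - lse_f)
        lse_g = logsumexp(Ceps + f[:, None] / eps, axis=0)
        g = cfg.tau_b * eps * (logb - lse_g)
        if not (np.isfinite(f).all() and np.isfinite(g).all()):
            raise FloatingPointError(
                "Sinkhorn scaling vectors became non-finite; try a larger epsilon"
            )
        if balanced:
            # after the g-update the b-marginal is exact; monitor the a-residual
            row = np.exp(logsumexp(Ceps + f[:, None] / eps + g[None, :] / eps, axis=1))
            err = np.abs(row - asub).sum()
        else:
            err = np.abs(f - f_prev).max() / eps
        if err < cfg.tolerance:
            converged = True
            break

    logP = Ceps + f[:, None] / eps + g[None, :] / eps
    Psub = np.exp(logP)
    if not converged:
        warnings.warn(
            f"Sinkhorn did not converge within {cfg.max_iters} iterations "
            f"(residual {err:.3g})"
        )
    P = np.zeros_like(C)
    P[np.ix_(ia, ib)] = Psub
    return TransportMap(
        coupling=P,
        prior_a=a,
        prior_b=b,
        config=cfg,
        converged=converged,
        n_iters=it,
        cost=float((Psub * Cs).sum() * scale),
    )


# -- coupling algebra ------------------------------------------------------

def row_normalize(P: np.ndarray | TransportMap) -> np.ndarray:
    """Row-stochastic map P̂ = diag(P·1)⁻¹ P; errors on zero rows."""
    M = P.coupling if isinstance(P, TransportMap) else np.asarray(P, dtype=np.float64)
    rs = M.sum(axis=1)
    zero = np.where(rs <= 0)[0]
    if zero.size:
        raise ValueError(f"zero coupling mass for source cells at rows {zero[:5].tolist()}")
    return M / rs[:, None]


def transpose_map(P: np.ndarray | TransportMap) -> np.ndarray:
    """Backward map: transpose the raw coupling, then row-normalize.

    The input must be the un-normalized coupling (a row-stochastic matrix
    has already lost the target-marginal information).
    """
    M = P.coupling if isinstance(P, TransportMap) else np.asarray(P, dtype=np.float64)
    cs = M.sum(axis=0)
    zero = np.where(cs <= 0)[0]
    if zero.size:
        raise ValueError(f"zero coupling mass for target cells at columns {zero[:5].tolist()}")
    return row_normalize(M.T)


def chain_maps(*maps: np.ndarray) -> np.ndarray:
    """Markov-chain row-stochastic maps: P̂_{s,t} = P̂_{s,r} P̂_{r,t}.

    The product of row-stochastic matrices is row-stochastic; each product
    is re-normalized to absorb floating-point drift.
    """
    if not maps:
        raise ValueError("need at least one map")
    out = np.asarray(maps[0], dtype=np.float64)
    for M in maps[1:]:
        M = np.asarray(M, dtype=np.float64)
        if out.shape[1] != M.shape[0]:
            raise ValueError(f"inner dimension mismatch: {out.shape} @ {M.shape}")
        out = out @ M
        out = out / out.sum(axis=1, keepdims=True)
    return out


def equal_compartment_masks(
    tc, timepoints: list[float] | None = None, seed: int = 0
) -> dict[float, np.ndarray]:
    """Per-timepoint boolean masks subsampling compartments to equal size.

    Guards the multi-compartment model against artifacts from nonconstant
    compartment sample sizes. Timepoints where only one compartment is
    observed keep all cells.
    """
    if tc.compartment_key is None:
        raise ValueError("TimeCourse has no compartment labels")
    rng = np.random.default_rng(seed)
    comp = tc.adata.obs[tc.compartment_key].to_numpy()
    out: dict[float, np.ndarray] = {}
    for t in (timepoints if timepoints is not None else tc.timepoints):
        m = tc.mask(t)
        mask = np.zeros(tc.adata.n_obs, dtype=bool)
        groups = [np.where(m & (comp == c))[0] for c in np.unique(comp[m])]
        n_min = min(g.size for g in groups)
        for g in groups:
            mask[rng.choice(g, n_min, replace=False) if g.size > n_min else g] = True
        out[float(t)] = mask
    return out


def fit_timecourse_maps(
    tc,
    priors: dict[float, np.ndarray] | None = None,
    cfg: SolverConfig | None = None,
    n_components: int = 50,
    hvg: list[str] | None = None,
    seed: int = 0,
    timepoints: list[float] | None = None,
    cell_masks: dict[float, np.ndarray] | None = None,
    scale_cost: bool = True,
) -> list[TransportMap]:
    """Fit T−1 couplings between adjacent timepoints of a time course.

    Costs come from a per-pair 50-component local PCA inheriting the parent
    HVG set; each pair's cost matrix is divided by its mean before solving
    (the convention under which the default ε values are calibrated), with
    costs reported on the original scale. ``priors`` maps a source
    timepoint to its growth-informed source marginal (uniform if absent);
    the target marginal is uniform. ``cell_masks`` optionally restricts
    each timepoint to a boolean subset (used for equal-compartment
    subsampling in the combined model).
    """
    from .data_model import fit_basis

    cfg = cfg or SolverConfig()
    tps = list(timepoints) if timepoints is not None else list(tc.timepoints)
    if len(tps) < 2:
        raise ValueError("need at least two timepoints")
    ids_at: dict[float, np.ndarray] = {}
    for t in tps:
        m = tc.mask(t)
        if cell_masks is not None and t in cell_masks:
            m = m & cell_masks[t]
        ids_at[t] = tc.adata.obs_names[m].to_numpy()
        if ids_at[t].size < n_components + 1:
            raise ValueError(
                f"timepoint {t} has {ids_at[t].size} cells < n_components+1="
                f"{n_components + 1}; use a smaller local PCA"
            )
    maps: list[TransportMap] = []
    for s, t in zip(tps[:-1], tps[1:]):
        basis = fit_basis(
            tc, kind="local_pca", n_components=n_components, hvg=hvg,
            timepoint_pair=(s, t), seed=seed,
        )
        Xs = basis.coords_of(ids_at[s])
        Xt = basis.coords_of(ids_at[t])
        C = cost_matrix(Xs, Xt)
        m, n = C.shape
        a = np.full(m, 1.0 / m) if priors is None or s not in priors else priors[s]
        if a.size != m:
            raise ValueError(f"prior for timepoint {s} has size {a.size}, expected {m}")
        b = np.full(n, 1.0 / n)
        tm = solve_uot(C, a, b, cfg, scale_cost=scale_cost)
        tm.source_ids = list(ids_at[s])
        tm.target_ids = list(ids_at[t])
        tm.source_timepoint = float(s)
        tm.target_timepoint = float(t)
        maps.append(tm)
    return maps
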