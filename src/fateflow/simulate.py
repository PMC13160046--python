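"""Ground-truthed synthetic two-compartment single-cell time course.

The generator emulates an acute-infection CD8 T cell response profiled by
scRNA-seq at a handful of days: a founder pool of circulating cells expands
rapidly (birth >> death) up to a configured peak day and contracts
afterwards, while lineages committed to one of several branches (memory-,
terminal-, early-effector-like, and an intermediate branch) drift apart in
a latent state space. During a bounded migration window a branch-dependent
per-day Bernoulli egress moves cells from the circulating to the tissue
compartment, where a residency gene program ramps up with time since
arrival. Observed snapshots are near-uniform subsamples per (day,
compartment) — deliberately uninformative about population size, which is
the regime growth-calibrated OT has to overcome — with counts emitted
through a negative-binomial (Gamma–Poisson) model with lognormal library
sizes.

Ground truth records every sampled cell's lineage, committed branch (or
"progenitor" before its split day), compartment history, arrival day, and
the true (weighted) population size per day, so that every downstream
module can be validated without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .data_model import TimeCourse

BRANCHES = ("memory", "terminal", "early_effector", "intermediate")


@dataclass
class SimulationConfig:
    """Defaults define the benchmark study conditions; see docs/methods.md."""

    days: tuple[float, ...] = (0, 3, 4, 5, 7, 10, 14, 28)
    latent_dim: int = 10
    n_founders: int = 500
    max_tracked: int = 8000
    cells_per_snapshot: int = 300
    # branch tree: common progenitor drift until split_day, then branch drift
    split_day: float = 2.0
    branch_fractions: dict[str, float] = field(default_factory=lambda: {
        "memory": 0.30, "terminal": 0.30, "early_effector": 0.20, "intermediate": 0.20})
    drift_root: float = 0.5          # per-day drift along the shared axis
    drift_branch: float = 1.0        # per-day drift along each branch axis
    drift_until: float = 10.0        # differentiation saturates (drift stops) here
    step_noise: float = 0.3
    reversion: float = 0.15          # per-day OU pull toward the branch attractor
    # birth-death kinetics (per-day probabilities)
    peak_day: float = 7.0
    birth_expansion: float = 0.55
    death_expansion: float = 0.05
    birth_contraction: float = 0.05
    death_contraction: dict[str, float] = field(default_factory=lambda: {
        "memory": 0.17, "terminal": 0.23, "early_effector": 0.21, "intermediate": 0.19})
    resolution_day: float = 14.0     # contraction ends; memory homeostasis begins
    memory_attrition: float = 1.0    # death-rate multiplier after resolution
    # migration: circulating -> tissue inside [window_start, window_end]
    window: tuple[float, float] = (3.0, 7.0)
    egress_early: dict[str, float] = field(default_factory=lambda: {
        "memory": 0.25, "terminal": 0.03, "early_effector": 0.08, "intermediate": 0.08})
    egress_late: dict[str, float] = field(default_factory=lambda: {
        "memory": 0.05, "terminal": 0.22, "early_effector": 0.08, "intermediate": 0.08})
    egress_switch_day: float = 5.0   # early schedule before, late schedule from this day
    return_rate: float = 0.0
    max_transitions: int = 1
    # emission
    n_genes_per_program: int = 25
    n_lineage_stable: int = 30
    n_transient: int = 10
    n_cycling: int = 40
    n_latent_genes: int = 60
    n_mito: int = 5
    n_genes_total: int = 600
    amp_program: float = 1.5         # log-scale amplitude of program genes
    amp_growth: float = 3.0          # amplitude of proliferation/apoptosis programs
    amp_cycling: float = 2.0         # amplitude of the cell-cycle-phase analog
    amp_jitter: float = 0.4          # per-gene relative spread of amplitudes
    base_sigma: float = 1.0          # lognormal spread of baseline expression
    amp_latent: float = 0.30
    spike_day: float = 5.0
    nb_dispersion: float = 10.0
    lib_mean: float = 8000.0
    lib_sigma: float = 0.30
    seed: int = 0
    panel_seed: int = 0              # gene-panel properties are a fixed trait

    def __post_init__(self) -> None:
        if self.window[0] < min(self.days) or self.window[1] > max(self.days):
            raise ValueError("migration window must lie within the observed days")
        for d in (self.egress_early, self.egress_late, self.death_contraction):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates must be >= 0")

    def birth_rate(self, branch: str, day: float) -> float:
        return self.birth_expansion if day <= self.peak_day else self.birth_contraction

    def death_rate(self, branch: str, day: float) -> float:
        if day <= self.peak_day:
            return self.death_expansion
        rate = self.death_contraction[branch]
        if day > self.resolution_day:
            rate *= self.memory_attrition    # slow homeostatic attrition
        return rate

    def egress_rate(self, branch: str, day: float) -> float:
        if not (self.window[0] <= day <= self.window[1]):
            return 0.0
        sched = self.egress_early if day < self.egress_switch_day else self.egress_late
        return sched[branch]


@dataclass
class GroundTruth:
    """Per-sampled-cell truth plus the true population series."""

    cells: pd.DataFrame              # indexed by observed cell id
    population: pd.DataFrame         # day x (total, per-branch) true sizes
    gene_programs: dict[str, list[str]] = field(default_factory=dict)
    config: SimulationConfig | None = None


def _gene_names(cfg: SimulationConfig) -> dict[str, list[str]]:
    p = cfg.n_genes_per_program
    programs = {
        "proliferation": [f"prolif_{i}" for i in range(p)],
        "apoptosis": [f"apop_{i}" for i in range(p)],
        "residency": [f"resid_{i}" for i in range(p)],
        "circulating": [f"circ_{i}" for i in range(p)],
    }
    for b in BRANCHES:
        programs[f"marker_{b}"] = [f"mk_{b}_{i}" for i in range(p)]
    programs["lineage_stable"] = [f"stable_{i}" for i in range(cfg.n_lineage_stable)]
    programs["transient"] = [f"spike_{i}" for i in range(cfg.n_transient)]
    # fate-orthogonal transient phenotype axis (cell-cycle-phase analog):
    # strong cross-sectional variance that carries no lineage information
    programs["cycling"] = [f"cyc_{i}" for i in range(cfg.n_cycling)]
    programs["latent"] = [f"lat_{i}" for i in range(cfg.n_latent_genes)]
    programs["mito"] = [f"mt-{i}" for i in range(cfg.n_mito)]
    used = sum(len(v) for v in programs.values())
    n_house = max(cfg.n_genes_total - used, 0)
    programs["housekeeping"] = [f"hk_{i}" for i in range(n_house)]
    return programs


class _Population:
    """Tracked-cell state; uniform down-sampling keeps a true-size weight."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        n = cfg.n_founders
        fracs = np.array([cfg.branch_fractions[b] for b in BRANCHES])
        counts = np.floor(fracs * n).astype(int)
        counts[0] += n - counts.sum()
        self.branch = np.repeat(np.arange(len(BRANCHES)), counts)
        self.lineage = np.arange(n)
        self.u = rng.uniform(size=n)[self.lineage]       # heritable lineage level
        self.lat = np.zeros((n, cfg.latent_dim))
        self.anchor = np.zeros((len(BRANCHES), cfg.latent_dim))
        # branch attractor directions: memory, terminal and early-effector on
        # orthogonal axes; the intermediate branch between memory and terminal
        D = cfg.latent_dim
        self.directions = np.zeros((len(BRANCHES), D))
        self.directions[0, 1] = 1.0                       # memory
        self.directions[1, 2] = 1.0                       # terminal
        self.directions[2, 3] = 1.0                       # early_effector
        self.directions[3, 1:3] = 1.0 / np.sqrt(2.0)      # intermediate
        self.comp = np.zeros(n, dtype=int)               # 0 = circulating, 1 = tissue
        self.arrival = np.full(n, np.nan)
        self.transitions = np.zeros(n, dtype=int)
        self.weight = 1.0                                # true cells per tracked cell

    @property
    def n(self) -> int:
        return self.branch.size

    def _keep(self, mask: np.ndarray) -> None:
        for name in ("branch", "lineage", "u", "comp", "arrival", "transitions"):
            setattr(self, name, getattr(self, name)[mask])
        self.lat = self.lat[mask]

    def step_day(self, day: float) -> None:
        cfg, rng = self.cfg, self.rng
        # latent dynamics: deterministic branch-attractor drift (saturating at
        # drift_until) plus mean-reverting fluctuation around the attractor,
        # so states neither diverge nor diffuse without bound
        if day <= cfg.drift_until:
            self.anchor[:, 0] += cfg.drift_root
            if day >= cfg.split_day:
                self.anchor += cfg.drift_branch * self.directions
        dev = self.lat - self.anchor[self.branch]
        dev = (1.0 - cfg.reversion) * dev + rng.normal(0.0, cfg.step_noise, dev.shape)
        self.lat = self.anchor[self.branch] + dev
        # migration (before birth/death so newborns inherit compartments)
        egress = np.array([cfg.egress_rate(BRANCHES[b], day) for b in self.branch])
        can_go = (self.comp == 0) & (self.transitions < cfg.max_transitions)
        go = can_go & (rng.uniform(size=self.n) < egress)
        self.comp[go] = 1
        self.arrival[go] = day
        self.transitions[go] += 1
        if cfg.return_rate > 0 and cfg.window[0] <= day <= cfg.window[1]:
            back = ((self.comp == 1) & (self.transitions < cfg.max_transitions)
                    & (rng.uniform(size=self.n) < cfg.return_rate))
            self.comp[back] = 0
            self.transitions[back] += 1
        # birth-death (Poisson thinning of per-day rates)
        birth = np.array([cfg.birth_rate(BRANCHES[b], day) for b in self.branch])
        death = np.array([cfg.death_rate(BRANCHES[b], day) for b in self.branch])
        die = rng.uniform(size=self.n) < death
        self._keep(~die)
        if self.n == 0:
            raise RuntimeError(
                f"all lineages extinct at day {day}; lower the death rates")
        divide = rng.uniform(size=self.n) < birth[~die]
        if divide.any():
            idx = np.where(divide)[0]
            self.branch = np.concatenate([self.branch, self.branch[idx]])
            self.lineage = np.concatenate([self.lineage, self.lineage[idx]])
            self.u = np.concatenate([self.u, self.u[idx]])
            child_lat = self.lat[idx] + rng.normal(0.0, 0.05, (idx.size, cfg.latent_dim))
            self.lat = np.vstack([self.lat, child_lat])
            self.comp = np.concatenate([self.comp, self.comp[idx]])
            self.arrival = np.concatenate([self.arrival, self.arrival[idx]])
            self.transitions = np.concatenate([self.transitions, self.transitions[idx]])
        if self.n > cfg.max_tracked:
            keep = rng.choice(self.n, cfg.max_tracked, replace=False)
            self.weight *= self.n / cfg.max_tracked
            mask = np.zeros(self.n, dtype=bool)
            mask[keep] = True
            self._keep(mask)


def _emit_counts(cfg: SimulationConfig, rng: np.random.Generator,
                 pop: _Population, idx: np.ndarray, day: float,
                 programs: dict[str, list[str]], gene_index: list[str],
                 log_base: np.ndarray, amp_jit: np.ndarray,
                 W: np.ndarray) -> np.ndarray:
    """NB counts for the cells ``idx`` observed at ``day``."""
    n = idx.size
    log_r = np.tile(log_base, (n, 1))
    pos = {name: [gene_index.index(x) for x in genes] for name, genes in programs.items()}
    branch = pop.branch[idx]
    comp = pop.comp[idx]
    arrival = pop.arrival[idx]
    # program expression reflects the kinetics it is about to drive: a cell
    # expressing apoptosis genes is about to die, so rates are evaluated
    # just past the observation day
    eff_day = day + 0.5
    birth = np.array([cfg.birth_rate(BRANCHES[b], eff_day) for b in branch])
    death = np.array([cfg.death_rate(BRANCHES[b], eff_day) for b in branch])
    # growth-program expression scales linearly with the underlying rates,
    # so the score differential is proportional to the net growth rate
    rate_ref = max(cfg.birth_expansion, cfg.birth_contraction,
                   cfg.death_expansion, *cfg.death_contraction.values())
    if rate_ref <= 0:
        prolif_act = np.zeros_like(birth)
        apop_act = np.zeros_like(death)
    else:
        prolif_act = birth / rate_ref
        apop_act = death / rate_ref
    def bump(name: str, act, amp: float | None = None) -> None:
        p = pos[name]
        a = ((cfg.amp_program if amp is None else amp) * amp_jit[p])[None, :]
        log_r[:, p] += a * np.atleast_1d(act)[:, None]

    bump("proliferation", prolif_act, amp=cfg.amp_growth)
    bump("apoptosis", apop_act, amp=cfg.amp_growth)
    res_act = np.where(comp == 1, np.minimum(1.0, (day - arrival + 1.0) / 3.0), 0.0)
    res_act = np.nan_to_num(res_act)
    bump("residency", res_act)
    bump("circulating", 1.0 - res_act)
    commit = np.minimum(1.0, np.maximum(0.0, (day - cfg.split_day) / 2.0))
    # marker-program weights per (cell branch, marker set): the intermediate
    # branch co-expresses the memory and terminal programs at half strength
    # alongside a weaker program of its own (a transitional phenotype)
    mix = np.eye(len(BRANCHES))
    inter = BRANCHES.index("intermediate")
    mix[inter, inter] = 0.9
    mix[inter, BRANCHES.index("memory")] = 0.3
    mix[inter, BRANCHES.index("terminal")] = 0.3
    for bi, b in enumerate(BRANCHES):
        p = pos[f"marker_{b}"]
        w = mix[branch, bi][:, None]
        log_r[:, p] += (cfg.amp_program * amp_jit[p])[None, :] * commit * w
    bump("lineage_stable", pop.u[idx])
    # cycling heterogeneity is confined to proliferating cells: per-cell
    # phase is redrawn at each observation (not heritable) and its
    # amplitude scales with the birth rate (no cycling in memory phase)
    bump("cycling", rng.uniform(size=n) * prolif_act, amp=cfg.amp_cycling)
    if day == cfg.spike_day:
        bump("transient", np.ones(n))
    log_r[:, pos["latent"]] += cfg.amp_latent * (pop.lat[idx] @ W.T)
    r = np.exp(log_r)
    p = r / r.sum(axis=1, keepdims=True)
    lib = rng.lognormal(np.log(cfg.lib_mean), cfg.lib_sigma, size=n)
    mu = lib[:, None] * p
    lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
    return rng.poisson(lam).astype(np.float32)


def simulate_timecourse(cfg: SimulationConfig) -> tuple[TimeCourse, GroundTruth]:
    """Run the birth-death / migration / emission model; see module docstring."""
    rng = np.random.default_rng(cfg.seed)
    # gene-level parameters (baselines, amplitudes, latent loadings) are
    # fixed properties of the gene panel, drawn from their own stream so
    # that different simulation seeds re-run the experiment on the same
    # biological system
    panel_rng = np.random.default_rng(cfg.panel_seed)
    programs = _gene_names(cfg)
    gene_index: list[str] = [g for genes in programs.values() for g in genes]
    # baseline expression strata: cell-cycle/apoptosis machinery is well
    # expressed, subset markers and residency/trafficking genes are lowly
    # expressed (typical of TFs and surface receptors), housekeeping spans
    # the full range; this also keeps gene-set control bins well mixed
    base_mean = {"proliferation": np.log(8.0), "apoptosis": np.log(8.0),
                 "residency": np.log(2.0), "circulating": np.log(2.0),
                 "transient": np.log(2.0), "lineage_stable": np.log(2.0),
                 "mito": np.log(40.0)}
    base_sd = {"proliferation": 0.4, "apoptosis": 0.4, "mito": 0.2}
    for b in BRANCHES:
        base_mean[f"marker_{b}"] = np.log(2.0)
    log_base = np.empty(len(gene_index))
    start = 0
    for name, genes in programs.items():
        stop = start + len(genes)
        log_base[start:stop] = panel_rng.normal(base_mean.get(name, np.log(5.0)),
                                          base_sd.get(name, cfg.base_sigma),
                                          size=len(genes))
        start = stop
    amp_jit = panel_rng.uniform(1.0 - cfg.amp_jitter, 1.0 + cfg.amp_jitter,
                          size=len(gene_index))
    W = panel_rng.normal(0.0, 1.0 / np.sqrt(cfg.latent_dim),
                   size=(cfg.n_latent_genes, cfg.latent_dim))

    pop = _Population(cfg, rng)
    obs_days = sorted(cfg.days)
    max_day = int(max(obs_days))
    counts_blocks, obs_rows = [], []
    pop_rows = []
    cell_counter = 0

    def observe(day: float) -> None:
        nonlocal cell_counter
        row = {"day": day, "total": pop.n * pop.weight}
        for bi, b in enumerate(BRANCHES):
            row[b] = (pop.branch == bi).sum() * pop.weight
        pop_rows.append(row)
        for comp_val, comp_name in ((0, "circulating"), (1, "tissue")):
            avail = np.where(pop.comp == comp_val)[0]
            if avail.size == 0:
                continue
            take = min(cfg.cells_per_snapshot, avail.size)
            idx = rng.choice(avail, take, replace=False)
            counts_blocks.append(
                _emit_counts(cfg, rng, pop, idx, day, programs, gene_index,
                             log_base, amp_jit, W))
            for j in idx:
                committed = day >= cfg.split_day
                obs_rows.append({
                    "cell_id": f"c{cell_counter}",
                    "day": float(day),
                    "compartment": comp_name,
                    "branch": BRANCHES[pop.branch[j]] if committed else "progenitor",
                    "fate_branch": BRANCHES[pop.branch[j]],
                    "lineage": int(pop.lineage[j]),
                    "arrival_day": float(pop.arrival[j]),
                    "lineage_level": float(pop.u[j]),
                })
                cell_counter += 1

    if 0 in obs_days:
        observe(0.0)
    for day in range(1, max_day + 1):
        pop.step_day(float(day))
        if float(day) in obs_days:
            observe(float(day))

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    X = np.vstack(counts_blocks)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({
            "timepoint": obs["day"].to_numpy(),
            "compartment": obs["compartment"].to_numpy(),
        }, index=obs.index),
        var=pd.DataFrame(index=pd.Index(gene_index, name="gene")),
    )
    tc = TimeCourse(adata, timepoint_key="timepoint", compartment_key="compartment")
    gt = GroundTruth(
        cells=obs,
        population=pd.DataFrame(pop_rows).set_index("day"),
        gene_programs={k: list(v) for k, v in programs.items()},
        config=cfg,
    )
    return tc, gt


def planted_gene_sets(cfg: SimulationConfig) -> dict[str, list[str]]:
    """The program gene lists matching the emission model (GMT-writable)."""
    programs = _gene_names(cfg)
    return {k: v for k, v in programs.items()
            if k not in ("housekeeping", "mito", "latent", "cycling")}


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "fateflow_simulated"] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out


def pairwise_marker_lists(cfg: SimulationConfig) -> dict[tuple[str, str], list[str]]:
    """Pairwise up-in-A-vs-B lists from the planted branch markers."""
    programs = _gene_names(cfg)
    lists = {}
    for a in BRANCHES:
        for b in BRANCHES:
            if a != b:
                lists[(a, b)] = list(programs[f"marker_{a}"])
    return lists


def default_benchmark(seed: int = 0) -> tuple[TimeCourse, GroundTruth]:
    """The fixed small benchmark used throughout the test suite.

    Eight observation days {0, 3, 4, 5, 7, 10, 14, 28}, two compartments,
    four fate branches, a days 3-7 migration window with early egress
    biased to the memory-like branch and late egress to the terminal-like
    branch, expansion peaking at day 7, ~300 cells per (day, compartment)
    and ~600 genes. Bitwise reproducible for a fixed seed.
    """
    return simulate_timecourse(SimulationConfig(seed=int(seed)))
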