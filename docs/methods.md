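# Methods

`fateflow` reconstructs single-cell differentiation and migration dynamics
from timepoint-labeled scRNA-seq snapshots using growth-calibrated
unbalanced entropic optimal transport (OT). This note records the model,
its assumptions, the numerical choices, what the bundled simulator does and
does not emulate, and known limitations.

## Transport model

Between each pair of adjacent timepoints the coupling `P` minimizes

    ⟨P, C⟩ − ε·H(P) + λ_a·KL(P·1 ‖ a) + λ_b·KL(Pᵀ·1 ‖ b)

where `C` is the Euclidean distance between cells in a 50-component local
PCA fitted to the two timepoints only (inheriting the parent HVG set),
`H(P) = −⟨P, log P⟩`, `a` is the growth-informed source marginal, and `b`
is uniform over target cells. The marginal relaxation is parameterized by
`τ = λ/(λ+ε) ∈ [0,1]`; `τ → 1` recovers balanced OT. Presets: single
compartment `ε=0.01, τ_a=0.95, τ_b=0.9995`; two-compartment combined model
`ε=0.05, τ_a=τ_b=0.95`. These ε values are calibrated for mean-scaled cost
matrices, so `fit_timecourse_maps` divides each pair's `C` by its mean
before solving (costs are reported on the original scale); `solve_uot`
itself leaves costs untouched unless asked.

The solver is a log-domain Sinkhorn iteration: with dual potentials `f, g`,
`P = exp((f ⊕ g − C)/ε)` and each balanced update is raised to the power τ,
which is exact for KL marginal penalties. Convergence is declared when the
L1 marginal residual (balanced case) or the L∞ dual change divided by ε
falls below `tolerance` (default 1e−6, `max_iters` 10 000; these budgets
are our own — no reference values exist for them). Non-convergence warns
and flags the result; zero-mass prior entries are dropped with index
bookkeeping rather than perturbed.

Coupling algebra: `row_normalize` gives the row-stochastic map
`P̂ = diag(P1)⁻¹P`; backward maps use the transpose of the *raw* coupling,
then row normalization; non-adjacent maps are Markov-chained
(`P̂_{s,t} = P̂_{s,r} P̂_{r,t}`) with re-normalization after every product
to absorb floating-point drift.

## Growth priors

Per-cell proliferation and apoptosis gene-set scores are computed once on
the pooled (all-timepoint) log-normalized data — pooled scoring keeps the
timepoints on a common scale, which the growth signal requires — using
expression-matched binned controls (defaults `n_bins=25`, `ctrl_size=50`;
the pipeline scales `n_bins` to about one bin per 50 genes, capped at 25,
so a program cannot fill its own control bin on small panels). The score
differential is clipped at the within-timepoint 95th percentile (upper
tail only; a single hyper-proliferative outlier would otherwise absorb the
whole source marginal). Growth factors are

    g_i = exp(δ_i · Δt / σ),   a_i = g_i / Σ_j g_j,   Δt = t_target − t_source

with σ calibrated so the largest per-day growth factor equals
`g_max = 2^(divisions/day)`, default 2³ = 8: per timepoint
`σ_t = max_i δ_i(t) / log g_max`, then `σ = max_t σ_t`. Note that the
per-interval cap compounds as `g_max^Δt`. Population sizes follow
`N_t = N_{t−1} · mean_i g_i(t)` from `N_0 = 1000`, and per-cluster series
are obtained by weighting `N_t` with cluster proportions.

Two conventions deserve emphasis. First, the growth exponent uses
`t_target − t_source`, so proliferation-dominant cells get `g > 1`; the
`exponent_sign` flag flips this for auditability. Second, matched-control
scoring subtracts whatever part of a program's elevation is shared across
the pooled cells, so the differential estimates growth *relative to the
pooled time-average*; the reconstructed series is therefore a relative
kinetic profile with an exponentially amplified scale, not an absolute
census — peak location and log-scale correlation are the meaningful
readouts.

## Fate readouts

* Barycentric projection `Ỹ_{s→t} = P̂_{s,t} X_t` — the expected feature
  vector of a cell's descendants (or ancestors, via backward maps).
* Trajectory gene correlations: per interval, the Spearman correlation
  between a gene's observed values at `s` and its projection from `t`;
  the per-gene median over intervals ranks lineage-stable genes (top 100
  by default). Intervals where either column is constant are dropped from
  the median, never zero-filled.
* Fate propensities `Q̃ = P̂ C_t` over one-hot cluster matrices, entropy
  `H = −Σ q log q` in nats with `0·log 0 = 0`, null entropy
  `H0 = −Σ p_k log p_k` from target cluster frequencies, and consistency
  `1 − H/H0` (1 = cluster-preserving flow, 0 = no information beyond
  cluster sizes, negative = anti-concentrated). A single occupied target
  cluster makes consistency undefined; interval aggregations record NaN,
  and comparative analyses score such intervals as zero information.
  Caution: sharp couplings put a floor under the consistency of *any*
  labeling (each row's support is small), so consistency comparisons are
  informative as contrasts between partitions, not as absolute values.
* Egress probabilities: per source cell, the row mass landing in the other
  compartment, summarized as mean ± SEM per (interval, compartment);
  `egress_hi` thresholds at P > 0.5. The combined model first subsamples
  each timepoint so both compartments contribute equally.
* Arrival times: for each tissue cell at the query day, the backward
  membership curve `q_t` (probability its ancestor at day `t` was already
  in the tissue) is made non-decreasing by isotonic regression; the
  increments over pre-query days — with the residual `1 − q_last`
  attributed to the last pre-query day, since entry during the final
  interval cannot be resolved further — form an arrival distribution whose
  expectation (default) or mode is reported. This estimator is our own
  design for a quantity whose original construction is not fully
  specified; it degenerates correctly on step-function histories and is
  validated by simulator recovery. Early/late arrival quartile labels use
  strict inequalities, ties going to the middle group.

## Trajectory kernel mean embeddings

Each timepoint gets a `d=50` Nystroem approximation of a Gaussian RBF
kernel whose bandwidth is the median inter-cell Euclidean distance at that
timepoint (landmarks drawn uniformly at random under the seed). A cell's
TKME concatenates, over all included timepoints (after day 6 by default,
avoiding migration confounds), the barycentric projection of that
timepoint's kernel features through the chained/transposed maps, with the
cell's own features for its own timepoint. Blocks are variance-scaled
before clustering so no single timepoint dominates (switchable). Both
Leiden (kNN graph, k=15) and k-means (k-means++, 10 restarts) are
provided; the supercell resolution (1.0) is a per-timepoint setting —
trajectory-space Leiden uses a coarser resolution (0.2 in the benchmark
analyses) matching the expected number of fate branches. The median
bandwidth heuristic degrades when one population dominates a timepoint
(the median collapses to the within-population scale); strongly imbalanced
late compositions are a known failure mode.

## Distances and temporal modules

The unbiased Sinkhorn divergence uses the full entropic objective with
uniform balanced marginals and subtracts half of each self-term; the self
distance is then ~0 and two singletons at distance `d` score `d`. Default
`ε=1` on PCA coordinates; distributions come from 10 bootstrap draws of
100 cells. The divergence is not a metric and no triangle inequality is
asserted.

Temporal gene modules use banded (Sakoe–Chiba, window 2) dynamic time
warping on timepoint-mean profiles with squared local costs and a
square-root aggregate, clustered by PAM k-medoids (5 seeded restarts,
best within-module cost kept; medoids are always member profiles).

State annotation: composite scores `ŝ_A = Σ_{k≠A}(s_{A/k} − s_{k/A})` from
user-supplied pairwise up-gene lists (deriving such lists from bulk
datasets is out of scope; the simulator plants its own), argmax over
states whose day window admits the cell, masked states recorded as
missing (never −∞ surrogates), ties broken by state name. The default
mask table encodes the canonical windows (naive ≤ day 5; effector subsets
≤ day 10; memory subsets ≥ day 14).

## The simulator

`simulate_timecourse` generates the ground-truthed two-compartment time
course used everywhere in the tests. The default benchmark: observation
days {0, 3, 4, 5, 7, 10, 14, 28}, 500 founder lineages, four fate branches
(memory-, terminal-, early-effector-like and an intermediate that
co-expresses the memory and terminal programs at reduced strength),
commitment from day 2, latent states drifting toward branch attractors
until day 10 and fluctuating around them with mean reversion (OU,
0.15/day) thereafter — differentiation saturates at the memory phase and
states neither diverge nor diffuse without bound. Expansion (birth 0.55,
death 0.05 per day) runs to the peak at day 7; contraction uses
branch-specific death rates (0.17–0.23/day) whose narrow spread keeps a
balanced branch mix at day 28 while the population falls steeply, as in
acute infection. Migration is a per-day Bernoulli egress from circulation
to tissue inside days 3–7 only, memory-biased early and terminal-biased
late, with a residency program ramping over ~3 days after arrival; return
migration is off by default and compartment histories have at most one
transition.

Counts are emitted per cell through a Gamma–Poisson (negative binomial,
dispersion 10) model with lognormal library sizes (mean 8000), from a
600-gene panel stratified into programs: proliferation/apoptosis (well
expressed; activity proportional to the birth/death rates about to act on
the cell, so program expression precedes kinetics), residency/circulating,
branch markers, heritable lineage-level genes, a day-5 transient spike, a
non-heritable cycling program confined to proliferating cells (the
cell-cycle-phase analog — strong cross-sectional variance with no lineage
information, the classic confounder of static expression clustering),
latent-loading genes, mitochondrial genes and housekeeping. Gene-panel
parameters (baselines, amplitudes, loadings) come from a dedicated
`panel_seed` stream: a gene's baseline is a fixed property of the system,
so different simulation seeds re-run the experiment on the same panel.
Snapshots are near-uniform subsamples (~300 cells per day and compartment)
— deliberately uninformative about population size, which is the regime
the growth-calibrated marginals must overcome.

What the simulator does **not** emulate: batch and ambient effects,
doublets, dropout beyond NB sampling, clonal TCR structure, continuous
fate plasticity after commitment (fates are fixed per lineage at the
split day; cells observed before it are labeled "progenitor" and branch
recovery is evaluated where the branch program is actually expressed),
and mechanistic fate-decision dynamics. Passing the simulator recoveries
therefore demonstrates the machinery is correct and well-calibrated under
the stated generative assumptions, not that every conclusion transfers to
arbitrary real data.

## Benchmark analyses and their scope

`fateflow.benchmark` runs the standard analyses end to end at desk scale
(~4 000 cells, 600 genes; each full battery takes on the order of a
minute). Kinetics and migration use the pooled / combined models; the
combined model starts at day 3 with equal-size compartment subsampling.
Trajectory clustering runs on the circulating compartment only, as
trajectory models are fitted per compartment to avoid migration
confounds. The static baseline for the consistency comparison is the
era-windowed canonical nomenclature (early era split by transient
effector intensity, memory era by marker composites): snapshot phenotype
categories that cannot track lineage across eras, which is the limitation
trajectory clustering addresses. A pooled k-means baseline was rejected
because it degenerates to time-phase clusters, which the consistency
score rewards trivially.

## Known limitations

* The growth reconstruction is relative (see above): absolute population
  sizes are exponentially amplified, and σ calibration is a cap, not an
  estimate.
* Consistency has a coupling-sharpness floor; compare partitions, do not
  interpret absolute values.
* Arrival-time resolution is bounded by the observation grid: entries
  after the last pre-query day are attributed to that day.
* The median bandwidth heuristic for kernels assumes reasonably balanced
  populations per timepoint.
* Dense couplings scale as O(m·n) memory per pair; the package targets
  time courses of up to a few thousand cells per timepoint.
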