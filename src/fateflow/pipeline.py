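"""End-to-end orchestration: simulate/load → preprocess → marginals → fit →
fate/tkme/flows, with a provenance manifest.

The run configuration is a plain dict (typically loaded from YAML). Unknown
top-level keys are rejected; the resolved configuration, stage seeds and
output hashes are serialized next to the outputs so a run is reproducible
from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import child_seed
from .data_model import (TimeCourse, filter_cells, filter_genes, fit_basis,
                         load_timecourse, normalize_log1p, select_hvg)
from .fate import arrival_times, egress_probabilities, fate_consistency, fate_propensities
from .flows import fate_flow, sankey_export
from .growth import (GrowthPrior, calibrate_sigma, clipped_differential,
                     gene_set_score, population_sizes)
from .ot_core import (PRESETS, SolverConfig, equal_compartment_masks,
                      fit_timecourse_maps, row_normalize, transpose_map)
from .simulate import default_benchmark, planted_gene_sets
from .tkme import cluster_trajectories, fit_kernel_features, tkme_embed

log = logging.getLogger("fateflow")

_KNOWN_KEYS = {
    "input", "timepoint_key", "compartment_key", "preprocess", "marginals",
    "fit", "tkme", "fate", "flows", "seed", "preset",
}

DEFAULTS: dict = {
    "timepoint_key": "timepoint",
    "compartment_key": None,
    "preprocess": {"max_mito_frac": 0.10, "min_counts": 1500, "min_cells": 2,
                   "target_sum": 1e6, "n_hvg": 3000, "n_pcs": 30},
    "marginals": {"g_max": 8.0, "divisions_per_day": 3.0, "clip_q": 0.95,
                  "prolif_genes": None, "apop_genes": None},
    "fit": {"preset": "single", "n_components": 50},
    "tkme": {"d": 50, "after_day": 6.0, "method": "leiden", "k": 4,
             "resolution": 1.0},
    "fate": {"query_timepoint": None, "query_compartment": None},
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _merged(cfg: dict) -> dict:
    out = json.loads(json.dumps(DEFAULTS))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_growth_priors(
    tc: TimeCourse,
    prolif_genes: list[str],
    apop_genes: list[str],
    timepoints: list[float],
    g_max: float = 8.0,
    clip_q: float = 0.95,
    seed: int = 0,
) -> tuple[dict[float, GrowthPrior], float]:
    """Score, clip, calibrate σ and build per-interval source marginals.

    Scores are computed once on the pooled dataset (so timepoints share a
    common scale and between-day growth contrast survives the matched
    controls), then clipped within each timepoint. The number of
    expression-matching bins is scaled to the panel size (about 50 genes
    per bin, capped at the genome-wide default of 25) so that a program's
    genes never fill their own control bin on small panels.
    """
    n_bins = int(np.clip(tc.adata.n_vars // 50, 4, 25))
    yp = gene_set_score(tc.adata, prolif_genes, n_bins=n_bins,
                        seed=child_seed(seed, "prolif"), gene_set_id="proliferation")
    ya = gene_set_score(tc.adata, apop_genes, n_bins=n_bins,
                        seed=child_seed(seed, "apop"), gene_set_id="apoptosis")
    deltas: dict[float, np.ndarray] = {}
    for t in timepoints[:-1]:
        m = tc.mask(t)
        deltas[t] = clipped_differential(yp.values[m], ya.values[m], clip_q=clip_q)
    sigma = calibrate_sigma(deltas, g_max=g_max)
    priors = {}
    for s, t in zip(timepoints[:-1], timepoints[1:]):
        priors[s] = GrowthPrior(delta=deltas[s], sigma=sigma, dt=float(t - s),
                                g_max=g_max)
    return priors, sigma


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the configured stages and return the artifact directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merged(config)
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- input -------------------------------------------------------------
    inp = cfg.get("input") or {"simulate": {"seed": seed}}
    if "simulate" in inp:
        log.info("stage input: simulating benchmark time course")
        tc, gt = default_benchmark(int(inp["simulate"].get("seed", seed)))
        sets = planted_gene_sets(gt.config)
        if cfg["marginals"]["prolif_genes"] is None:
            cfg["marginals"]["prolif_genes"] = sets["proliferation"]
            cfg["marginals"]["apop_genes"] = sets["apoptosis"]
        gt.cells.to_csv(outdir / "ground_truth_cells.csv")
        gt.population.to_csv(outdir / "ground_truth_population.csv")
    else:
        tc = load_timecourse(inp["path"], timepoint_key=cfg["timepoint_key"],
                             compartment_key=cfg["compartment_key"])

    # -- preprocess ---------------------------------------------------------
    pp = cfg["preprocess"]
    log.info("stage preprocess: %d cells x %d genes", tc.adata.n_obs, tc.adata.n_vars)
    tc = filter_cells(tc, max_mito_frac=pp["max_mito_frac"], min_counts=pp["min_counts"])
    tc = filter_genes(tc, min_cells=pp["min_cells"])
    tc = normalize_log1p(tc, target_sum=pp["target_sum"])
    hvg = select_hvg(tc, n_top=pp["n_hvg"])
    timepoints = [float(t) for t in tc.timepoints]

    # -- marginals ----------------------------------------------------------
    mg = cfg["marginals"]
    if mg["prolif_genes"] is None or mg["apop_genes"] is None:
        raise ValueError("marginals stage requires prolif_genes and apop_genes")
    priors, sigma = build_growth_priors(
        tc, mg["prolif_genes"], mg["apop_genes"], timepoints,
        g_max=mg["g_max"], clip_q=mg["clip_q"], seed=seed)
    log.info("stage marginals: sigma=%.4f", sigma)

    # -- fit ----------------------------------------------------------------
    ft = cfg["fit"]
    preset = ft.get("preset", "single")
    solver = PRESETS.get(preset, SolverConfig())
    cell_masks = None
    if preset == "combined":
        cell_masks = equal_compartment_masks(tc, seed=child_seed(seed, "subsample"))
    marginal_arrays = {}
    for s in timepoints[:-1]:
        a = priors[s].a
        if cell_masks is not None:
            keep = cell_masks[s][tc.mask(s)]
            a = a[keep]
            a = a / a.sum()
        marginal_arrays[s] = a
    maps = fit_timecourse_maps(tc, priors=marginal_arrays, cfg=solver,
                               n_components=ft["n_components"], hvg=hvg,
                               seed=seed, cell_masks=cell_masks)
    log.info("stage fit: %d maps (preset=%s)", len(maps), preset)

    series = population_sizes([priors[s] for s in timepoints[:-1]], timepoints)
    pd.DataFrame({"timepoint": series.timepoints, "N": series.sizes}).to_csv(
        outdir / "population_sizes.csv", index=False)

    # -- tkme ---------------------------------------------------------------
    tk = cfg["tkme"]
    basis = fit_basis(tc, kind="global_pca", n_components=pp["n_pcs"], hvg=hvg, seed=seed)
    coords, kernels = {}, {}
    for tm in maps:
        for t, ids in ((tm.source_timepoint, tm.source_ids),
                       (tm.target_timepoint, tm.target_ids)):
            if t not in coords:
                coords[t] = basis.coords_of(ids)
    for t in [t for t in timepoints if t > tk["after_day"]]:
        kernels[t] = fit_kernel_features(coords[t], timepoint=t, d=tk["d"],
                                         seed=child_seed(seed, "kernel", t))
    emb = tkme_embed(tc, maps, kernels, coords, include_days_after=tk["after_day"])
    labels = cluster_trajectories(emb, method=tk["method"], k=tk["k"],
                                  resolution=tk["resolution"], seed=seed)
    labels.rename("trajectory").to_csv(outdir / "trajectory_clusters.csv")
    log.info("stage tkme: %d trajectory clusters", labels.nunique())

    # -- fate / flows -------------------------------------------------------
    ent_rows, flow_frames = [], []
    label_of = labels
    hats = {(tm.source_timepoint, tm.target_timepoint): row_normalize(tm) for tm in maps}
    for tm in maps:
        tgt_labels = label_of.reindex(tm.target_ids)
        prop = fate_propensities(hats[(tm.source_timepoint, tm.target_timepoint)], tgt_labels)
        try:
            cons, mean_cons = fate_consistency(prop, tgt_labels)
        except ValueError:
            cons, mean_cons = np.full(len(prop.entropy), np.nan), np.nan
        ent_rows.append(pd.DataFrame({
            "cell_id": tm.source_ids,
            "source_timepoint": tm.source_timepoint,
            "fate_entropy": prop.entropy,
            "fate_consistency": cons,
        }))
    pd.concat(ent_rows, ignore_index=True).to_csv(outdir / "fate_entropy.csv", index=False)

    for i in range(1, len(maps)):
        prev, nxt = maps[i - 1], maps[i]
        tab = fate_flow(
            labels_s=label_of.reindex(nxt.source_ids),
            labels_r=label_of.reindex(prev.source_ids),
            labels_t=label_of.reindex(nxt.target_ids),
            P_sr=transpose_map(prev),
            P_st=hats[(nxt.source_timepoint, nxt.target_timepoint)],
            timepoint=nxt.source_timepoint,
        )
        flow_frames.append(sankey_export(tab))
    pd.concat(flow_frames, ignore_index=True).to_csv(outdir / "fate_flows.csv", index=False)

    if tc.compartment_key is not None and preset == "combined":
        comp = tc.adata.obs[tc.compartment_key]
        mig = egress_probabilities(maps, comp)
        mig.per_cell.to_csv(outdir / "egress_probabilities.csv", index=False)
        fa = cfg["fate"]
        if fa.get("query_timepoint") is not None:
            arr = arrival_times(maps, comp, float(fa["query_timepoint"]),
                                fa["query_compartment"])
            arr.per_cell.to_csv(outdir / "arrival_times.csv", index=False)

    # -- manifest -----------------------------------------------------------
    manifest = {
        "fateflow_version": __version__,
        "seed": seed,
        "config": {k: (v if _jsonable(v) else str(v)) for k, v in cfg.items()},
        "sigma": sigma,
        "n_maps": len(maps),
        "timepoints": timepoints,
        "cells_per_timepoint": {
            str(t): int(tc.mask(t).sum() if cell_masks is None
                        else cell_masks[t].sum()) for t in timepoints},
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete: %s", outdir)
    return outdir


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
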