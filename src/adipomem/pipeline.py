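"""End-to-end analysis of a (simulated or user-supplied) study bundle.

Runs the full chain: cell QC -> log normalization -> per-contrast Wilcoxon
DEG tables -> retention and pattern classification -> per-modality NB region
differential tests -> trajectory classes and rule-based enhancer calling ->
enhancer-gene linkage -> gene epigenome map -> epigenetic explanation of
memory and rebound DEGs. All outputs are plain TSV/BED files; given the same
config the run is byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import dynamics, explain, memory
from .regions import RegionSet, link_regions_to_genes, write_bed
from .simulate import (CONTROL_OF, MODALITIES, SimBundle, SimConfig,
                       simulate_all, write_fixture_bundle)

__all__ = ["PipelineResult", "run_pipeline", "run_and_write"]

#: (condition, control) DEG contrasts, in the fixed order they are computed
CONTRASTS = [(c, CONTROL_OF[c]) for c in ("H", "HH", "HC", "HHC", "HCH")]


class PipelineResult(dict):
    """Plain dict of result tables keyed by stage name."""


def _deg_contrasts(bundle: SimBundle) -> dict:
    cfg = bundle.config
    keep, qc_report = diff.qc_filter_cells(
        bundle.sn_counts, min_features=cfg.qc_min_features,
        max_features=cfg.qc_max_features, max_umi=cfg.qc_max_umi)
    cells = bundle.cells.loc[keep].reset_index(drop=True)
    norm = diff.lognormalize(bundle.sn_counts[:, np.flatnonzero(keep)])
    gene_ids = bundle.genes["gene_id"].to_numpy()
    degs = {}
    for cond, ctrl in CONTRASTS:
        if cond not in bundle.config.conditions or ctrl not in bundle.config.conditions:
            continue
        ia = np.flatnonzero((cells["condition"] == cond).to_numpy())
        ib = np.flatnonzero((cells["condition"] == ctrl).to_numpy())
        degs[cond] = diff.wilcoxon_deg(norm, ia, ib, features=gene_ids)
    return {"degs": degs, "qc_report": qc_report, "cells_kept": cells}


def _region_diffs(bundle: SimBundle) -> dict:
    """Per modality and per contrast: NB exact tests on promoter-level
    (nominal P < 0.01, |log2FC| > 1) and enhancer/distal-level counts
    (FDR < 0.05, |log2FC| > 1)."""
    cond = bundle.samples["condition"].to_numpy()
    is_prom = (bundle.regions["kind"] == "promoter").to_numpy()
    prom_genes = bundle.regions.loc[is_prom, "gene_id"].to_numpy()
    dist_ids = bundle.regions.loc[~is_prom, "region_id"].to_numpy()
    promoter, distal, dispersions = {}, {}, {}
    for m in MODALITIES:
        X = bundle.region_counts[m].to_numpy()
        phi = diff.estimate_common_dispersion(X, cond)
        dispersions[m] = phi
        promoter[m], distal[m] = {}, {}
        for c, ctrl in CONTRASTS:
            if c not in bundle.config.conditions or ctrl not in bundle.config.conditions:
                continue
            promoter[m][c] = diff.nb_exact_test(
                X[is_prom], cond, c, ctrl, dispersion=phi, features=prom_genes,
                lfc_threshold=1.0, alpha=0.01, alpha_on="p")
            distal[m][c] = diff.nb_exact_test(
                X[~is_prom], cond, c, ctrl, dispersion=phi, features=dist_ids,
                lfc_threshold=1.0, alpha=0.05, alpha_on="fdr")
    return {"promoter_diffs": promoter, "enhancer_diffs": distal,
            "dispersions": dispersions}


def _h3k27ac_peaks_per_condition(bundle: SimBundle) -> dict:
    """Active-region sets per condition: distal regions whose mean normalized
    H3K27ac count in that condition exceeds the global median level."""
    X = bundle.region_counts["H3K27ac"].to_numpy().astype(float)
    sf = diff.size_factors_median_of_ratios(X)
    Xn = X / sf
    is_dist = (bundle.regions["kind"] == "distal").to_numpy()
    thr = np.median(Xn[is_dist])
    cond = bundle.samples["condition"].to_numpy()
    peaks = {}
    for c in bundle.config.conditions:
        mean = Xn[:, cond == c].mean(axis=1)
        sel = bundle.regions[is_dist & (mean > thr)]
        peaks[c] = RegionSet(sel.rename(columns={"region_id": "name"})[
            ["chrom", "start", "end", "name"]])
    return peaks


def run_pipeline(config: SimConfig) -> PipelineResult:
    """Simulate a study under ``config`` and analyse it end to end."""
    bundle = simulate_all(config)
    res = PipelineResult(bundle=bundle)
    res.update(_deg_contrasts(bundle))
    degs = res["degs"]

    # transcriptional retention per weight-loss arm, and cross-arm patterns
    if {"H", "HC"} <= set(degs):
        res["retention_HC"] = memory.classify_retention(
            degs["H"], degs["HC"], cell_type="adipocyte")
        res["proportions_HC"] = memory.retention_proportions(res["retention_HC"])
    if {"HH", "HHC"} <= set(degs):
        res["retention_HHC"] = memory.classify_retention(
            degs["HH"], degs["HHC"], cell_type="adipocyte")
        res["proportions_HHC"] = memory.retention_proportions(res["retention_HHC"])
    if {"H", "HC", "HH", "HHC"} <= set(degs):
        res["patterns"] = memory.classify_patterns(
            degs["H"], degs["HC"], degs["HH"], degs["HHC"])

    res.update(_region_diffs(bundle))

    # trajectory classes (obese H -> weight loss HC) per modality, distal regions
    traj = {}
    for m in MODALITIES:
        d = res["enhancer_diffs"][m]
        if {"H", "HC"} <= set(d):
            traj[m] = dynamics.classify_trajectory(d["H"], d["HC"])
    res["trajectories"] = traj

    # rule-based enhancer calling from binned tracks
    enh = dynamics.call_enhancers_by_rule(bundle.bins, bundle.promoters,
                                          bin_size=config.bin_size)
    res["called_enhancers"] = enh
    res["acetylation"] = dynamics.acetylation_status(
        enh, _h3k27ac_peaks_per_condition(bundle))

    # enhancer -> gene linkage for the distal count regions
    dist = bundle.regions[bundle.regions["kind"] == "distal"]
    dist_rs = RegionSet(dist.rename(columns={"region_id": "name"})[
        ["chrom", "start", "end", "name"]])
    res["linkage"] = link_regions_to_genes(dist_rs, bundle.genes, max_dist=20000)

    # epigenetic explanation of memory DEGs (persistent = obese AND WL)
    if "retention_HC" in res:
        prom_pairs = {m: (res["promoter_diffs"][m]["H"],
                          res["promoter_diffs"][m]["HC"]) for m in MODALITIES}
        enh_pairs = {m: (res["enhancer_diffs"][m]["H"],
                         res["enhancer_diffs"][m]["HC"]) for m in MODALITIES}
        gmap = explain.build_gene_epigenome_map(
            prom_pairs, enh_pairs, res["linkage"], persistence="obese_and_wl")
        res["gene_epigenome_map"] = gmap
        for mode in ("any_modality", "direction_consistent"):
            rec, frac = explain.explain_memory_degs(res["retention_HC"], gmap,
                                                    mode=mode)
            res[f"explanation_{mode}"] = rec
            res[f"explained_fractions_{mode}"] = frac

    # rebound analysis: HCH DEGs vs prior status / memory / epigenetic marks
    if "HCH" in degs and "retention_HC" in res:
        gmap_wl = explain.build_gene_epigenome_map(
            prom_pairs, enh_pairs, res["linkage"], persistence="wl_only")
        rec, frac = explain.explain_rebound_degs(
            degs["HCH"], degs["HC"], res["retention_HC"], gmap_wl)
        res["rebound_records"] = rec
        res["rebound_fractions"] = frac

    # correlation of each H3K4me1 sample against the aggregated healthy control
    ctrl_idx = np.flatnonzero(bundle.samples["condition"].eq("C").to_numpy())
    if len(ctrl_idx):
        X = bundle.region_counts["H3K4me1"].to_numpy()
        rows = []
        for j, (s, c) in enumerate(zip(bundle.samples["sample"],
                                       bundle.samples["condition"])):
            if j in ctrl_idx:
                continue
            rows.append((s, c, diff.correlation_to_reference(X, ctrl_idx, j)))
        res["control_correlation"] = pd.DataFrame(
            rows, columns=["sample", "condition", "pearson_r"])
    return res


def run_and_write(config: SimConfig, outdir) -> PipelineResult:
    """Run the pipeline and write every result table under ``outdir``."""
    res = run_pipeline(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fixture_bundle(res["bundle"], out / "fixtures")
    for cond, table in res["degs"].items():
        table.to_csv(out / f"deg_{cond}_vs_{CONTROL_OF[cond]}.tsv",
                     sep="\t", index=False)
    for key in ("retention_HC", "retention_HHC", "proportions_HC",
                "proportions_HHC", "patterns", "linkage",
                "explanation_any_modality", "explanation_direction_consistent",
                "explained_fractions_any_modality",
                "explained_fractions_direction_consistent",
                "rebound_records", "rebound_fractions",
                "control_correlation", "acetylation"):
        if key in res:
            res[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    for m in MODALITIES:
        for c, table in res["promoter_diffs"][m].items():
            table.to_csv(out / f"diff_promoter_{m}_{c}.tsv", sep="\t", index=False)
        for c, table in res["enhancer_diffs"][m].items():
            table.to_csv(out / f"diff_enhancer_{m}_{c}.tsv", sep="\t", index=False)
        if m in res["trajectories"]:
            res["trajectories"][m].to_csv(out / f"trajectory_{m}.tsv",
                                          sep="\t", index=False)
    write_bed(res["called_enhancers"], out / "called_enhancers.bed")
    with open(out / "summary.json", "w") as fh:
        json.dump({"qc": res["qc_report"],
                   "dispersions": {m: float(v)
                                   for m, v in res["dispersions"].items()},
                   "n_called_enhancers": len(res["called_enhancers"])},
                  fh, indent=2, sort_keys=True)
    return res
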