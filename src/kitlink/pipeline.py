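"""End-to-end orchestration: simulate/read → demux → QC → normalize →
cluster → score → clonotype → linkage, with every stage re-entrant from
in-memory objects and results persisted as TSV/JSON bundles."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import (cluster as _cluster, clonotype as _clonotype,
               io_formats as _io, linkage as _linkage,
               preprocess as _pre, signatures as _sig, synthetic as _syn)

log = logging.getLogger("kitlink")


def _timed(stage: str, t0: float) -> None:
    log.info("stage %-12s %6.2fs", stage, time.perf_counter() - t0)


def analyze_cohort(
    matrix: _io.CountMatrix,
    hto: _io.HTOCounts | None,
    contigs: list[_io.TcrContig],
    signatures: list[_io.GeneSignature] | None = None,
    cluster_labels: pd.Series | None = None,
    config: dict | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs.

    ``cluster_labels`` (indexed by barcode) bypasses graph clustering —
    used when evaluating against ground-truth cluster identities.
    Returns a dict of tables and the linkage report.
    """
    cfg = config or {}
    pre_cfg = cfg.get("preprocess", {})
    clu_cfg = cfg.get("cluster", {})
    sig_cfg = cfg.get("signatures", {})
    link_cfg = cfg.get("linkage", {})
    thresholds = _pre.QCThresholds(**pre_cfg.get("qc", {}))
    out: dict = {}

    # -- demultiplex --------------------------------------------------------
    t0 = time.perf_counter()
    if hto is not None:
        demux = _pre.call_singlets(
            hto,
            singlet_threshold=pre_cfg.get("singlet_threshold", 0.70),
            min_total=pre_cfg.get("min_total_hto", 10))
        out["demux"] = demux
        singlets = set(demux.index[demux["call"] == "singlet"])
        keep = [b in singlets for b in matrix.barcodes]
        matrix = _io.CountMatrix(
            [b for b, k in zip(matrix.barcodes, keep) if k],
            matrix.features, matrix.counts[np.asarray(keep)])
    _timed("demux", t0)

    # -- QC + normalize -----------------------------------------------------
    t0 = time.perf_counter()
    matrix, qc_report = _pre.qc_filter(matrix, thresholds=thresholds)
    out["qc_report"] = qc_report
    norm = _pre.log_normalize(matrix, thresholds)
    out["barcodes"] = list(matrix.barcodes)
    _timed("qc+norm", t0)

    # -- cluster ------------------------------------------------------------
    t0 = time.perf_counter()
    if cluster_labels is not None:
        labels = cluster_labels.reindex(matrix.barcodes).to_numpy()
    else:
        hvg = _pre.select_variable_genes(
            norm,
            n_bins=pre_cfg.get("n_bins", 20),
            dispersion_z_min=pre_cfg.get("dispersion_z_min", 1.0),
            mean_bounds=tuple(pre_cfg.get("mean_bounds", (0.1, 8.0))))
        cov = _pre.compute_covariates(matrix)
        scaled = _pre.regress_and_scale(norm, cov, gene_indices=hvg)
        n_pcs = min(pre_cfg.get("n_pcs", 30), min(scaled.values.shape) - 1)
        pca = _pre.run_pca(scaled, n_components=n_pcs)
        ccfg = _cluster.ClusterConfig(
            k_neighbors=clu_cfg.get("k_neighbors", 20),
            resolution=clu_cfg.get("resolution", 0.9),
            random_seed=clu_cfg.get("random_seed", 0))
        graph = _cluster.build_snn_graph(pca.embedding, ccfg)
        labels = _cluster.louvain_cluster(graph, ccfg)
        out["pca_elbow"] = pca.elbow_report()
    out["cluster_labels"] = pd.Series(labels, index=matrix.barcodes,
                                      name="cluster")
    _timed("cluster", t0)

    # -- signature + phase scoring -----------------------------------------
    t0 = time.perf_counter()
    scores = None
    if signatures:
        score_tab = []
        for sig in signatures:
            df = _sig.score_signature_per_cell(norm, matrix.symbols, sig)
            df.insert(0, "signature", sig.name)
            df.insert(0, "barcode", matrix.barcodes)
            score_tab.append(df)
        out["signature_scores"] = pd.concat(score_tab, ignore_index=True)
        first = signatures[0].name
        scores = out["signature_scores"].query(
            "signature == @first").set_index("barcode")["score"]
    phases = _sig.score_cell_cycle(
        norm, matrix.symbols,
        n_bins=sig_cfg.get("n_bins", 24),
        n_ctrl=sig_cfg.get("n_ctrl", 100),
        seed=sig_cfg.get("seed", 0))
    out["phases"] = pd.Series(phases.phase, index=matrix.barcodes,
                              name="phase")
    phase_tab = _sig.phase_composition(
        phases.phase, out["cluster_labels"].to_numpy())
    out["phase_composition"] = phase_tab
    _timed("score", t0)

    # -- clonotype ----------------------------------------------------------
    t0 = time.perf_counter()
    clones, thr, pair_report = _clonotype.run_clonotyping(contigs)
    out["clonotypes"] = _clonotype.clonotype_table(clones)
    out["high_threshold"] = thr.high_threshold
    out["pair_filter"] = pair_report
    cell_tiers = _clonotype.cell_tier_table(clones)
    out["cell_tiers"] = cell_tiers
    _timed("clonotype", t0)

    # -- linkage ------------------------------------------------------------
    t0 = time.perf_counter()
    merged = out["cluster_labels"].to_frame().join(cell_tiers, how="inner")
    table = _linkage.tier_cluster_table(merged["tier"], merged["cluster"])
    groups = link_cfg.get("cluster_groups")
    if groups is None:
        groups = {g: m for g, m in _syn.CLUSTER_GROUPS.items()}
    score_args = {}
    if scores is not None:
        aligned = merged.join(scores, how="inner")
        score_args = {"scores": aligned["score"].to_numpy(),
                      "score_tiers": aligned["tier"].to_numpy()}
    out["linkage"] = _linkage.linkage_report(
        table,
        cluster_groups=groups,
        phase_table=phase_tab,
        n_comparisons=link_cfg.get("n_comparisons",
                                   _linkage.DEFAULT_N_COMPARISONS),
        **score_args)
    _timed("linkage", t0)
    return out


def results_bundle(out: dict) -> _io.ResultsBundle:
    """Package pipeline outputs for write_results."""
    bundle = _io.ResultsBundle()
    per_cell = pd.DataFrame({"barcode": out["barcodes"]})
    per_cell["cluster"] = out["cluster_labels"].to_numpy()
    per_cell["phase"] = out["phases"].to_numpy()
    bundle.tables["per_cell"] = per_cell
    bundle.tables["clonotypes"] = out["clonotypes"]
    bundle.tables["cell_tiers"] = out["cell_tiers"].reset_index()
    if "signature_scores" in out:
        bundle.tables["signature_scores"] = out["signature_scores"]
    bundle.summaries["linkage"] = _linkage.round_report(out["linkage"])
    bundle.summaries["linkage_full"] = out["linkage"]
    bundle.summaries["qc"] = {
        "qc_report": out["qc_report"],
        "high_threshold": out["high_threshold"],
        "pair_filter_excluded": out["pair_filter"].excluded,
    }
    return bundle


def run_from_config(config: dict, outdir) -> dict:
    """File-level entry point: simulate or read inputs, analyze, persist."""
    outdir = Path(outdir)
    sim_cfg = config.get("simulate")
    if sim_cfg:
        preset = sim_cfg.get("preset", "mrl")
        maker = {"mrl": _syn.preset_mrl, "yaa": _syn.preset_yaa}[preset]
        scenario = maker(
            n_cells=sim_cfg.get("n_cells", 10_000),
            n_genes=sim_cfg.get("n_genes", 1_000),
            seed=sim_cfg.get("seed", 0))
        matrix, hto, contigs, truth = _syn.simulate_cohort(scenario)
        cluster_labels = (truth.df["cluster"]
                          if sim_cfg.get("use_truth_clusters") else None)
    else:
        inputs = config["inputs"]
        matrix = _io.read_count_matrix(inputs["counts_dir"])
        hto = (_io.read_hto_counts(inputs["hto_csv"])
               if inputs.get("hto_csv") else None)
        contigs, _ = _io.read_contigs(inputs["contigs_csv"])
        cluster_labels = None
    signatures = None
    if config.get("inputs", {}).get("signatures_gmt"):
        signatures = _io.read_gmt(config["inputs"]["signatures_gmt"])
    elif sim_cfg:
        signatures = [_io.GeneSignature("exhaustion",
                                        frozenset(_syn.EXHAUSTION_GENES))]
    out = analyze_cohort(matrix, hto, contigs, signatures=signatures,
                         cluster_labels=cluster_labels, config=config)
    _io.write_results(results_bundle(out), outdir)
    return out
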