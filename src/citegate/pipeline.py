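"""End-to-end pipeline: normalization -> demultiplexing -> doublet removal ->
thresholding -> gating -> clustering -> differential expression ->
importance -> enrichment.

Each stage consumes only upstream outputs; the run report records the
per-stage cell counts (which can only decrease across the doublet cascade)
and every table is written as CSV so a rerun with the same configuration
and inputs is bit-identical.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from .clustering import LIKELY_DOUBLET, cluster_cells, name_clusters
from .config import PipelineConfig
from .doublets import assign_subjects, demultiplex_by_tags, remove_biological_doublets, score_doublets_ann
from .enrich import enrich, rank_pathways
from .errors import CitegateError
from .experiment import CellExperiment
from .gating import CD8_GATE, DEFAULT_NAMING_RULES, apply_gate, select_clustering_antibodies
from .importance import rank_genes_by_importance
from .io import read_experiment, read_gmt
from .normalize import normalize_experiment
from .thresholds import build_threshold_table

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise CitegateError(f"pipeline aborted at stage {name!r}: {exc}") from exc
    logger.info("stage %s: done", name)


def run_pipeline(config: PipelineConfig, experiment: CellExperiment | None = None) -> dict:
    """Execute all stages and write result tables; returns the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "cell_counts": {}}
    counts = report["cell_counts"]

    with _stage("load"):
        if experiment is None:
            if config.input_dir is None:
                raise CitegateError("no experiment given and input_dir unset")
            experiment = read_experiment(config.input_dir)
    counts["total"] = experiment.n_cells

    with _stage("demultiplex"):
        demux = demultiplex_by_tags(experiment.tags, experiment.tag_names)
        subjects = assign_subjects(demux, experiment.cell_meta["plate"].to_numpy(),
                                   experiment.subject_meta)
        demux.to_frame(experiment.barcodes).assign(subject=subjects.to_numpy()) \
            .to_csv(out / "demux.csv")
        exp = experiment.subset_cells(demux.is_singlet)
        exp.cell_meta["subject"] = subjects[demux.is_singlet].to_numpy()
    counts["post_tag_demux"] = exp.n_cells

    with _stage("transcriptomic_doublets"):
        scores = score_doublets_ann(
            exp.rna,
            expected_rate=config.expected_doublet_rate,
            artificial_fraction=config.artificial_fraction,
            n_pcs=config.n_pcs,
            seed=config.doublet_seed,
        )
        pd.DataFrame({"score": scores.score, "flagged": scores.flagged},
                     index=exp.barcodes).to_csv(out / "doublet_scores.csv")
        exp = exp.subset_cells(~scores.flagged)
    counts["post_transcriptomic"] = exp.n_cells

    with _stage("normalize"):
        norm = normalize_experiment(exp.rna, exp.adt, rna_mode=config.rna_norm_mode)
        report["normalization"] = norm.provenance

    with _stage("thresholding"):
        thresholds = build_threshold_table(
            norm, exp.antibody_names,
            min_cells=config.threshold_min_cells,
            sigma_min=config.sigma_min,
            min_separation_sd=config.min_separation_sd,
        )
        thresholds.to_csv(out / "thresholds.csv")
        report["n_thresholds_determined"] = int(thresholds.table["determined"].sum())
        report["undetermined_antibodies"] = thresholds.undetermined()

    with _stage("gate_cd8"):
        gate_mask = apply_gate(norm.adt_clr, exp.antibody_names, thresholds, CD8_GATE)
    counts["cd8_gated"] = int(gate_mask.sum())

    with _stage("biological_doublets"):
        gated_idx = np.flatnonzero(gate_mask)
        keep, removal_log = remove_biological_doublets(
            norm.adt_clr[gated_idx], exp.antibody_names, thresholds,
            conflict_markers=config.conflict_markers,
            min_conflicts=config.min_conflicts,
            barcodes=exp.barcodes[gated_idx],
        )
        (out / "biological_doublets.json").write_text(json.dumps(removal_log))
        cd8_idx = gated_idx[keep]
    counts["post_biological"] = int(cd8_idx.size)

    cd8_clr = norm.adt_clr[cd8_idx]
    cd8_rna_norm = norm.rna_norm[cd8_idx]
    cd8_meta = exp.cell_meta.iloc[cd8_idx]
    cd8_barcodes = exp.barcodes[cd8_idx]
    subject_groups = exp.subject_meta["group"]
    cd8_condition = cd8_meta["subject"].map(subject_groups).to_numpy(dtype=object)

    with _stage("clustering"):
        selected = select_clustering_antibodies(
            exp.antibody_names, cd8_clr, thresholds, gate_rule=CD8_GATE,
            positive_floor=config.positive_floor)
        report["clustering_antibodies"] = selected
        sel_cols = [exp.antibody_names.index(a) for a in selected]
        clusters = cluster_cells(
            cd8_clr[:, sel_cols],
            n_pcs=config.n_pcs, resolution=config.resolution,
            seed=config.cluster_seed, knn=config.knn,
            batch=cd8_meta["plate"].to_numpy(), batch_center=config.batch_center,
            embedding=config.embedding)
        clusters = name_clusters(
            clusters, cd8_clr, exp.antibody_names, thresholds,
            DEFAULT_NAMING_RULES, positive_fraction_cutoff=config.naming_cutoff)
        clusters.to_frame(cd8_barcodes).to_csv(out / "clusters.csv")
        clusters.positive_fraction.to_csv(out / "cluster_marker_fractions.csv")
        clusters.mean_clr.to_csv(out / "cluster_marker_mean_clr.csv")
        pd.DataFrame(clusters.embedding, index=cd8_barcodes,
                     columns=["dim1", "dim2"]).to_csv(out / "embedding.csv")
        report["n_clusters"] = clusters.n_clusters
        report["cluster_names"] = {str(k): v for k, v in clusters.names.items()}
        doublet_clusters = [c for c, bad in clusters.likely_doublet.items() if bad]
        report["likely_doublet_clusters"] = doublet_clusters

    analyzed = ~np.isin(clusters.labels, doublet_clusters)
    counts["analyzed"] = int(analyzed.sum())

    with _stage("differential_expression"):
        m1 = analyzed & (cd8_condition == "CAD_high")
        m2 = analyzed & (cd8_condition == "CAD_low")
        de_all = de_mod.find_markers(
            cd8_rna_norm, m1, m2, exp.gene_names,
            min_detect_fraction=config.min_detect_fraction)
        de_all.to_csv(out / "de_all_cd8.csv", index=False)
        de_sig = de_mod.apply_de_filters(
            de_all, p_cutoff=config.de_p_cutoff,
            lfc_cutoff=config.de_lfc_cutoff,
            pct_ratio_cutoff=config.pct_ratio_cutoff)
        de_sig.to_csv(out / "de_significant.csv", index=False)
        report["n_genes_tested"] = int(de_all.attrs["n_tested"])
        report["n_de_significant"] = int(len(de_sig))

        cluster_tables = de_mod.per_cluster_de(
            cd8_rna_norm, clusters.labels, cd8_condition, exp.gene_names,
            min_cells_per_condition=config.min_cells_per_condition,
            min_detect_fraction=config.min_detect_fraction,
            exclude_clusters=doublet_clusters)
        for cid, tab in cluster_tables.items():
            tab.to_csv(out / f"de_cluster_{cid}.csv", index=False)
        report["clusters_tested_for_de"] = sorted(cluster_tables)

        genes_present = [g for g in config.proportion_genes if g in exp.gene_names]
        fracs, prop_tests = de_mod.expressing_proportions(
            exp.rna[cd8_idx], clusters.labels, cd8_meta["subject"].to_numpy(),
            subject_groups, genes_present, exp.gene_names)
        fracs.to_csv(out / "expressing_fractions.csv", index=False)
        prop_tests.to_csv(out / "expressing_fraction_tests.csv", index=False)

    if config.rf_enabled:
        with _stage("importance"):
            mask = analyzed & pd.notna(cd8_condition)
            idx = np.flatnonzero(mask)
            if idx.size > config.rf_max_cells:   # deterministic cap for runtime
                rng = np.random.default_rng(config.rf_seed)
                idx = np.sort(rng.choice(idx, size=config.rf_max_cells, replace=False))
            imp = rank_genes_by_importance(
                cd8_rna_norm[idx], cd8_condition[idx],
                cd8_meta["subject"].to_numpy()[idx], exp.gene_names,
                grid=config.rf_grid, n_repeats=config.rf_repeats,
                seed=config.rf_seed)
            imp.table.to_csv(out / "importance.csv", index=False)
            report["rf_selected"] = imp.metadata["selected"]
            report["top10_importance"] = imp.top(10)

    with _stage("enrichment"):
        gmt = config.resolved_gmt_path()
        if not gmt.exists():
            raise FileNotFoundError(f"gene-set library not found: {gmt}")
        library = read_gmt(gmt)
        universe = de_all["gene"].tolist()
        query = de_sig[de_sig["direction"] == "up"]["gene"].tolist()
        if query:
            table = enrich(query, library, universe)
            table.to_csv(out / "enrichment.csv", index=False)
            ranked = rank_pathways(table, alpha=config.enrich_alpha)
            ranked.to_csv(out / "enrichment_significant.csv", index=False)
            report["n_pathways_significant"] = int(len(ranked))
            report["top_pathways"] = ranked["set"].head(5).tolist()
        else:
            report["n_pathways_significant"] = 0
            report["top_pathways"] = []

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
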