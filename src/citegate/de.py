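"""Case/control and cluster-vs-rest differential expression.

Per gene: a two-sided Wilcoxon rank-sum test on normalized values, the
Seurat-style average log2 fold change
log2((mean(2^v - 1) over group 1 + 1) / (mean(2^v - 1) over group 2 + 1)),
expressing-cell fractions pct1/pct2 (fraction of cells with nonzero
counts), and Bonferroni adjustment over the genes actually tested.  The
standard downstream filters are adjusted p < 0.05, avg_log2FC > 0 and
optionally pct1/pct2 > 2.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bonferroni, rank_sum_test

logger = logging.getLogger(__name__)


def expression_filter(rna_norm1: np.ndarray, rna_norm2: np.ndarray,
                      min_fraction: float = 0.01) -> np.ndarray:
    """Genes detected (value > 0) in at least ``min_fraction`` of either group."""
    f1 = (rna_norm1 > 0).mean(axis=0)
    f2 = (rna_norm2 > 0).mean(axis=0)
    return (f1 >= min_fraction) | (f2 >= min_fraction)


def find_markers(
    rna_norm,
    group1_mask,
    group2_mask,
    gene_names: list[str],
    tested_genes: list[str] | None = None,
    min_detect_fraction: float = 0.01,
) -> pd.DataFrame:
    """Differential expression between two groups of cells.

    Returns one row per tested gene: statistic, p_raw, Bonferroni-adjusted
    p over the number of genes tested, avg_log2FC (group1 over group2),
    pct1/pct2 and direction.
    """
    x = np.asarray(rna_norm, dtype=float)
    g1 = np.asarray(group1_mask)
    g2 = np.asarray(group2_mask)
    if g1.dtype == bool:
        g1 = np.flatnonzero(g1)
    if g2.dtype == bool:
        g2 = np.flatnonzero(g2)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must contain at least one cell")
    x1, x2 = x[g1], x[g2]

    if tested_genes is None:
        keep = expression_filter(x1, x2, min_detect_fraction)
        tested = [g for g, k in zip(gene_names, keep) if k]
    else:
        tested = [g for g in tested_genes if g in gene_names]
    n_tested = len(tested)
    idx = {g: j for j, g in enumerate(gene_names)}

    rows = []
    for g in tested:
        j = idx[g]
        v1, v2 = x1[:, j], x2[:, j]
        u, p = rank_sum_test(v1, v2)
        m1 = float(np.expm1(v1 * np.log(2)).mean())   # mean de-logged expression
        m2 = float(np.expm1(v2 * np.log(2)).mean())
        lfc = float(np.log2(m1 + 1.0) - np.log2(m2 + 1.0))
        rows.append({
            "gene": g,
            "statistic": u,
            "p_raw": p,
            "avg_log2FC": lfc,
            "pct1": float((v1 > 0).mean()),
            "pct2": float((v2 > 0).mean()),
            "n1": int(v1.size),
            "n2": int(v2.size),
        })
    table = pd.DataFrame(rows, columns=["gene", "statistic", "p_raw", "avg_log2FC",
                                        "pct1", "pct2", "n1", "n2"])
    table["p_adj_bonferroni"] = bonferroni(table["p_raw"].to_numpy(), n_tested) \
        if len(table) else pd.Series(dtype=float)
    table["direction"] = np.where(table["avg_log2FC"] > 0, "up", "down")
    table.attrs["n_tested"] = n_tested
    return table


def apply_de_filters(
    table: pd.DataFrame,
    p_cutoff: float = 0.05,
    lfc_cutoff: float = 0.0,
    pct_ratio_cutoff: float | None = None,
) -> pd.DataFrame:
    """Retain genes with p_adj < cutoff, avg_log2FC > cutoff and (optionally)
    pct1/pct2 above a ratio cutoff; pct2 = 0 passes whenever pct1 > 0."""
    keep = (table["p_adj_bonferroni"] < p_cutoff) & (table["avg_log2FC"] > lfc_cutoff)
    if pct_ratio_cutoff is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = table["pct1"] / table["pct2"]
        passes = np.where(table["pct2"] > 0, ratio > pct_ratio_cutoff, table["pct1"] > 0)
        keep &= passes
    out = table[keep].copy()
    out.attrs["n_tested"] = table.attrs.get("n_tested", len(table))
    return out


def per_cluster_de(
    rna_norm,
    cluster_labels,
    condition_labels,
    gene_names: list[str],
    group1: str = "CAD_high",
    group2: str = "CAD_low",
    min_cells_per_condition: int = 10,
    min_detect_fraction: float = 0.01,
    exclude_clusters=(),
) -> dict[int, pd.DataFrame]:
    """find_markers between conditions within each cluster; thin clusters skipped."""
    labels = np.asarray(cluster_labels)
    cond = np.asarray(condition_labels, dtype=object)
    out: dict[int, pd.DataFrame] = {}
    for cid in np.unique(labels):
        if cid in exclude_clusters:
            continue
        in_c = labels == cid
        m1 = in_c & (cond == group1)
        m2 = in_c & (cond == group2)
        if m1.sum() < min_cells_per_condition or m2.sum() < min_cells_per_condition:
            logger.info("cluster %s skipped: %d vs %d cells below minimum %d",
                        cid, int(m1.sum()), int(m2.sum()), min_cells_per_condition)
            continue
        out[int(cid)] = find_markers(rna_norm, m1, m2, gene_names,
                                     min_detect_fraction=min_detect_fraction)
    return out


def expressing_proportions(
    rna_counts,
    cluster_labels,
    subject_per_cell,
    subject_groups: pd.Series,
    genes: list[str],
    gene_names: list[str],
    group1: str = "CAD_high",
    group2: str = "CAD_low",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject expressing-cell fractions and subject-level rank tests.

    Returns (fractions, tests): fractions has one row per
    gene x cluster x subject with the fraction of that subject's cells in
    the cluster that express the gene (count > 0); tests has one row per
    gene x cluster with the two-sided Wilcoxon rank-sum p across subjects
    between condition groups.  Subjects with zero cells in a cluster are
    omitted from that test.
    """
    from scipy import sparse as sp

    x = rna_counts
    dense = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)
    labels = np.asarray(cluster_labels)
    subj = np.asarray(subject_per_cell, dtype=object)
    idx = {g: j for j, g in enumerate(gene_names)}
    frac_rows, test_rows = [], []
    for cid in np.unique(labels):
        in_c = labels == cid
        for g in genes:
            j = idx[g]
            per_subject: dict[str, float] = {}
            for s in pd.unique(subj[in_c]):
                if s is None or (isinstance(s, float) and np.isnan(s)):
                    continue
                cells = in_c & (subj == s)
                per_subject[str(s)] = float((dense[cells, j] > 0).mean())
                frac_rows.append({"gene": g, "cluster": int(cid), "subject": str(s),
                                  "fraction": per_subject[str(s)]})
            v1 = [f for s, f in per_subject.items() if subject_groups.get(s) == group1]
            v2 = [f for s, f in per_subject.items() if subject_groups.get(s) == group2]
            if v1 and v2:
                _, p = rank_sum_test(v1, v2)
                test_rows.append({"gene": g, "cluster": int(cid), "p": p,
                                  "n1": len(v1), "n2": len(v2)})
    return pd.DataFrame(frac_rows), pd.DataFrame(test_rows)
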