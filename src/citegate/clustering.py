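"""Surface-marker clustering of gated cells and gate-style cluster naming.

Cells are clustered on the CLR values of the selected (thresholded,
non-negative) antibodies only — never on gene expression — via PCA, a
shared-nearest-neighbor (SNN) graph with Jaccard edge weights, and Louvain
community detection at a fixed resolution and seed.  A 2-D embedding is
computed for visualization only and never used in statistics.  Clusters
are then named by ordered gating rules applied to per-cluster marker
positivity fractions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .gating import EXCLUSIVE_LINEAGE_PAIRS, GateRule
from .thresholds import GLOBAL_CONTEXT, ThresholdTable, positivity_calls

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
LIKELY_DOUBLET = "likely doublet"


@dataclass
class ClusterResult:
    """Partition of cells plus per-cluster marker summaries."""

    labels: np.ndarray                     # per-cell cluster id, contiguous from 0
    names: dict[int, str]                  # cluster id -> assigned name
    positive_fraction: pd.DataFrame | None  # cluster x antibody positive fractions
    mean_clr: pd.DataFrame | None           # cluster x antibody mean CLR
    embedding: np.ndarray | None            # cells x 2, visualization only
    params: dict = field(default_factory=dict)
    likely_doublet: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = np.unique(self.labels)
        if ids.size and not np.array_equal(ids, np.arange(ids.size)):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    def name_of(self, cluster: int) -> str:
        return self.names.get(cluster, UNASSIGNED)

    def to_frame(self, barcodes=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "cluster": self.labels,
            "name": [self.name_of(c) for c in self.labels],
        })
        if barcodes is not None:
            df.index = barcodes
        return df


def _snn_graph(pcs: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = pcs.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)                       # includes self
    rows = np.repeat(np.arange(n), k + 1)
    adj = sparse.csr_matrix(
        (np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n))
    inter = adj @ adj.T                               # shared-neighbor counts
    mask = adj.maximum(adj.T)                         # kNN edges (symmetric)
    inter = inter.multiply(mask)
    inter = sparse.triu(inter, k=1).tocoo()
    union = 2.0 * (k + 1) - inter.data
    weights = inter.data / union
    edges = list(zip(inter.row.tolist(), inter.col.tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights.tolist()
    return g


def cluster_cells(
    adt_clr_selected,
    n_pcs: int = 20,
    resolution: float = 0.15,
    seed: int = 42,
    knn: int = 20,
    batch=None,
    batch_center: bool = False,
    embedding: str = "pca",
) -> ClusterResult:
    """Louvain partition of cells from selected-antibody CLR values.

    ``batch``/``batch_center`` enable the per-plate mean-centering stand-in
    for batch integration: each antibody is centered within each plate
    before PCA.  Clusters are relabeled by decreasing size.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x = np.asarray(adt_clr_selected, dtype=float).copy()
    n = x.shape[0]
    if n < 50:
        raise ValueError("clustering needs at least 50 cells")
    if x.shape[1] < 2:
        raise ValueError("clustering needs at least 2 antibodies")
    if batch_center:
        if batch is None:
            raise ValueError("batch_center=True requires per-cell batch labels")
        b = np.asarray(batch)
        for lev in pd.unique(b):
            m = b == lev
            x[m] -= x[m].mean(axis=0, keepdims=True)

    n_comp = min(n_pcs, x.shape[1] - 1, n - 1)
    if x.std() < 1e-12:
        labels = np.zeros(n, dtype=int)     # identical cells: one cluster
        emb = np.zeros((n, 2))
    else:
        pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
        g = _snn_graph(pcs, knn)
        random.seed(seed)                   # igraph draws from Python's random module
        part = g.community_multilevel(weights="weight", resolution=resolution)
        labels = np.asarray(part.membership, dtype=int)
        # relabel by decreasing size (ties by old id) so ids are stable
        counts = pd.Series(labels).value_counts()
        order = sorted(counts.index, key=lambda c: (-counts[c], c))
        remap = {old: new for new, old in enumerate(order)}
        labels = np.array([remap[c] for c in labels], dtype=int)
        if embedding == "umap":
            import umap  # optional, heavy

            emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(pcs)
        else:
            emb = pcs[:, :2].copy()
    logger.info("clustering: %d cells -> %d clusters (resolution=%g, seed=%d)",
                n, labels.max() + 1, resolution, seed)
    return ClusterResult(
        labels=labels, names={}, positive_fraction=None, mean_clr=None,
        embedding=emb,
        params={"n_pcs": n_comp, "resolution": resolution, "seed": seed,
                "knn": knn, "batch_center": batch_center, "embedding": embedding},
    )


def name_clusters(
    result: ClusterResult,
    adt_clr,
    antibodies: list[str],
    thresholds: ThresholdTable,
    naming_rules: list[GateRule],
    positive_fraction_cutoff: float = 0.5,
    context: str = GLOBAL_CONTEXT,
    exclusive_pairs=EXCLUSIVE_LINEAGE_PAIRS,
) -> ClusterResult:
    """Assign population names to clusters from marker positivity fractions.

    A cluster satisfies a rule when the positive fraction of each
    require_positive antibody is >= cutoff and of each require_negative
    antibody is <= 1 - cutoff; the first matching rule (priority order)
    names it, otherwise "unassigned".  Clusters positive for both sides of
    a mutually exclusive lineage pair (e.g. CD3 and CD14) are flagged
    likely doublets and named accordingly.
    """
    clr = np.asarray(adt_clr)
    determined = [ab for ab in antibodies if thresholds.is_determined(ab, context)]
    cols = [antibodies.index(ab) for ab in determined]
    calls = positivity_calls(clr[:, cols], determined, thresholds, context)
    frac = pd.DataFrame(calls, columns=determined).groupby(result.labels).mean()
    mean_clr = pd.DataFrame(clr[:, cols], columns=determined).groupby(result.labels).mean()

    names: dict[int, str] = {}
    likely: dict[int, bool] = {}
    rules = sorted(naming_rules, key=lambda r: r.priority)
    for cid in frac.index:
        row = frac.loc[cid]
        n_conflicts = sum(
            a in row.index and b in row.index
            and row[a] >= positive_fraction_cutoff and row[b] >= positive_fraction_cutoff
            for a, b in exclusive_pairs)
        likely[int(cid)] = n_conflicts >= 1
        name = UNASSIGNED
        if likely[int(cid)]:
            name = LIKELY_DOUBLET
        else:
            for rule in rules:
                if not (rule.require_positive | rule.require_negative) <= set(row.index):
                    continue
                ok = all(row[a] >= positive_fraction_cutoff for a in rule.require_positive)
                ok = ok and all(row[a] <= 1 - positive_fraction_cutoff
                                for a in rule.require_negative)
                if ok:
                    name = rule.name
                    break
        names[int(cid)] = name
    return ClusterResult(
        labels=result.labels, names=names, positive_fraction=frac,
        mean_clr=mean_clr, embedding=result.embedding, params=result.params,
        likely_doublet=likely,
    )
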