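"""Three-stage doublet removal.

Stage 1 demultiplexes hashed samples from the tag count matrix: each tag
gets a positivity threshold from the same two-component mixture machinery
used for antibodies (on log2(count+1)); cells with exactly one positive tag
are singlets, two or more are multiplets, none are undetermined.

Stage 2 scores transcriptomic doublets with an artificial-nearest-neighbor
approach: artificial doublets are synthesized by averaging normalized
profiles of random cell pairs, everything is embedded by PCA, and a cell's
score is the fraction of artificial doublets among its k nearest
neighbors.  The top expected-rate fraction by score is flagged.

Stage 3 removes "biological doublets": gated CD8 T cells positive for a
configured number of myeloid conflict markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, FitError
from .mixture import fit_two_component_mixture, threshold_from_mixture
from .thresholds import GLOBAL_CONTEXT, ThresholdTable, positivity_calls

logger = logging.getLogger(__name__)

SINGLET = "singlet"
MULTIPLET = "multiplet"
UNDETERMINED = "undetermined"


@dataclass
class DemuxResult:
    """Per-cell demultiplexing call and the per-tag thresholds used."""

    call: np.ndarray            # per-cell: "singlet" | "multiplet" | "undetermined"
    tag: np.ndarray             # per-cell tag name for singlets, "" otherwise
    tag_thresholds: dict[str, float]

    @property
    def is_singlet(self) -> np.ndarray:
        return self.call == SINGLET

    def to_frame(self, barcodes=None) -> pd.DataFrame:
        df = pd.DataFrame({"call": self.call, "tag": self.tag})
        if barcodes is not None:
            df.index = barcodes
        return df


def demultiplex_by_tags(tags, tag_names: list[str]) -> DemuxResult:
    """Classify every cell as singlet (with its tag), multiplet or undetermined."""
    x = np.asarray(tags)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("tag matrix must be 2-D with at least one tag")
    if (x < 0).any():
        raise ValueError("tag counts must be non-negative")
    logx = np.log2(x + 1.0)
    thresholds = {}
    for j, name in enumerate(tag_names):
        try:
            fit = fit_two_component_mixture(logx[:, j])
            if not fit.converged or fit.ill_separated:
                raise FitError("tag signal not bimodal")
            thresholds[name] = threshold_from_mixture(fit)
        except FitError as exc:
            raise FitError(
                f"sample tag {name!r}: positivity threshold undetermined "
                f"({exc}); demultiplexing cannot proceed") from exc
    tvec = np.array([thresholds[n] for n in tag_names])
    positive = logx > tvec[None, :]
    n_pos = positive.sum(axis=1)
    call = np.full(x.shape[0], UNDETERMINED, dtype=object)
    call[n_pos == 1] = SINGLET
    call[n_pos >= 2] = MULTIPLET
    tag = np.full(x.shape[0], "", dtype=object)
    singlet_rows = n_pos == 1
    tag[singlet_rows] = np.array(tag_names, dtype=object)[
        positive[singlet_rows].argmax(axis=1)]
    logger.info("demux: %d singlets, %d multiplets, %d undetermined",
                int((call == SINGLET).sum()), int((call == MULTIPLET).sum()),
                int((call == UNDETERMINED).sum()))
    return DemuxResult(call=call, tag=tag, tag_thresholds=thresholds)


def assign_subjects(demux: DemuxResult, plate_per_cell, subject_meta: pd.DataFrame) -> pd.Series:
    """Map singlets to subjects via each plate's tag-to-subject key."""
    key = {(row["plate"], row["tag"]): sid for sid, row in subject_meta.iterrows()}
    plates = np.asarray(plate_per_cell)
    out = []
    for i in range(len(plates)):
        if demux.call[i] == SINGLET:
            out.append(key.get((plates[i], demux.tag[i])))
        else:
            out.append(None)
    return pd.Series(out, dtype="string")


@dataclass
class DoubletScore:
    """Artificial-nearest-neighbor doublet scores and flags."""

    score: np.ndarray           # per-cell fraction of artificial neighbors, in [0,1]
    flagged: np.ndarray         # per-cell bool at the expected-rate cutoff
    params: dict = field(default_factory=dict)


def score_doublets_ann(
    rna_counts,
    expected_rate: float = 0.05,
    artificial_fraction: float = 0.25,
    k: int | None = None,
    n_pcs: int = 20,
    seed: int = 0,
) -> DoubletScore:
    """Score cells by their artificial-doublet neighborhood in PC space.

    Artificial doublets are synthesized the same way real doublets arise —
    by summing the raw counts of two random cells — and then normalized
    jointly with the real cells (log2 CPM), so they share both the mixed
    expression profile and the inflated library size of genuine doublets.
    """
    from scipy import sparse as sp

    x = np.asarray(rna_counts.todense()) if sp.issparse(rna_counts) \
        else np.asarray(rna_counts)
    x = x.astype(float)
    n = x.shape[0]
    if n < 100:
        raise ValueError("doublet scoring needs at least 100 cells")
    if k is None:
        k = int(np.clip(round(0.01 * n), 10, 100))
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    rng = np.random.default_rng(seed)
    n_art = max(int(round(artificial_fraction * n)), 1)
    # draw pairs in a content-sorted (canonical) index space so the artificial
    # doublet set does not depend on the order cells happen to be stored in
    canon = np.lexsort(tuple(x.T))
    ii = rng.integers(0, n, size=n_art)
    jj = rng.integers(0, n - 1, size=n_art)
    jj = np.where(jj >= ii, jj + 1, jj)          # distinct partners
    ii, jj = canon[ii], canon[jj]
    artificial = x[ii] + x[jj]

    joint = np.vstack([x, artificial])
    totals = joint.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    joint = np.log2(1.0 + 1e6 * joint / totals)
    n_comp = min(n_pcs, joint.shape[1] - 1, joint.shape[0] - 1)
    pcs = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=seed).fit_transform(joint)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    # drop self-neighbor (always present at distance 0 for real cells)
    cleaned = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k]
        cleaned[i] = row
    score = (cleaned >= n).mean(axis=1)

    n_flag = int(round(expected_rate * n))
    flagged = np.zeros(n, dtype=bool)
    if n_flag > 0:
        order = np.lexsort((np.arange(n), -score))   # stable: score desc, index asc
        flagged[order[:n_flag]] = True
    return DoubletScore(
        score=score, flagged=flagged,
        params={"k": k, "artificial_fraction": artificial_fraction,
                "expected_rate": expected_rate, "n_pcs": n_comp, "seed": seed},
    )


def remove_biological_doublets(
    adt_clr,
    antibodies: list[str],
    thresholds: ThresholdTable,
    conflict_markers: list[str],
    min_conflicts: int = 2,
    context: str = GLOBAL_CONTEXT,
    barcodes=None,
) -> tuple[np.ndarray, list[dict]]:
    """Flag gated CD8 cells positive for >= min_conflicts lineage-conflict markers.

    Returns (keep mask over the gated cells, removal log listing each removed
    cell's conflicting markers).
    """
    for ab in conflict_markers:
        if ab not in antibodies:
            raise ConfigurationError(f"conflict marker {ab!r} not in the panel")
        if not thresholds.is_determined(ab, context):
            raise ConfigurationError(f"conflict marker {ab!r} has no determined threshold")
    cols = [antibodies.index(ab) for ab in conflict_markers]
    calls = positivity_calls(np.asarray(adt_clr)[:, cols], conflict_markers,
                             thresholds, context)
    n_conf = calls.sum(axis=1)
    remove = n_conf >= min_conflicts
    log = []
    ids = barcodes if barcodes is not None else np.arange(len(remove))
    for i in np.flatnonzero(remove):
        log.append({
            "cell": str(ids[i]),
            "conflicting_markers": [conflict_markers[j] for j in range(len(cols))
                                    if calls[i, j]],
        })
    logger.info("biological doublets: removed %d of %d gated cells",
                int(remove.sum()), len(remove))
    return ~remove, log
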