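"""Count normalization for ADT and RNA matrices.

ADT counts are centered-log-ratio (CLR) transformed on the log2 scale: each
cell's antibody values are log2(count+1) minus the mean log2(count+1) over
all antibodies in that cell, so a cell's CLR values sum to zero.  RNA counts
are log2-normalized either per gene (each gene's counts divided by that
gene's total over all cells and scaled to one million) or per cell
(conventional CPM).  Both use a pseudocount of 1 inside the log.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse

from .experiment import NormalizedMatrices

logger = logging.getLogger(__name__)

SCALE = 1e6


def _dense(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def clr_normalize_adt(adt) -> np.ndarray:
    """CLR-transform an ADT count matrix (cells x antibodies), log2 scale.

    clr(c, a) = log2(x(c, a) + 1) - mean over antibodies a' of log2(x(c, a') + 1).
    A cell with an all-zero panel maps to a row of zeros (logged, not an error).
    """
    x = _dense(adt)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("ADT matrix must be 2-D with at least one antibody")
    if (x < 0).any():
        raise ValueError("ADT counts must be non-negative")
    logx = np.log2(x + 1.0)
    clr = logx - logx.mean(axis=1, keepdims=True)
    n_zero = int((x.sum(axis=1) == 0).sum())
    if n_zero:
        logger.info("CLR: %d cells with all-zero antibody panel -> zero rows", n_zero)
    return clr


def normalize_rna(rna, mode: str = "per_gene") -> np.ndarray:
    """Log2-normalize RNA counts.

    per_gene (default): value(c,g) = log2(1 + 1e6 * x(c,g) / total_g) with
    total_g the gene's total over all cells.  per_cell: the conventional
    log2(1 + CPM) with total_c the cell's library size.  Zero totals yield
    zeros for that gene (or cell) and are logged.
    """
    if mode not in ("per_gene", "per_cell"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = _dense(rna)
    if (x < 0).any():
        raise ValueError("RNA counts must be non-negative")
    axis = 0 if mode == "per_gene" else 1
    totals = x.sum(axis=axis, keepdims=True)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.info("normalize_rna(%s): %d zero totals -> zero output", mode, n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(totals > 0, SCALE * x / np.where(totals > 0, totals, 1.0), 0.0)
    return np.log2(1.0 + scaled)


def normalize_experiment(rna, adt, rna_mode: str = "per_gene") -> NormalizedMatrices:
    """Normalize both assays and record provenance."""
    return NormalizedMatrices(
        adt_clr=clr_normalize_adt(adt),
        rna_norm=normalize_rna(rna, mode=rna_mode),
        provenance={
            "adt": {"method": "clr", "log_base": 2, "pseudocount": 1},
            "rna": {"method": rna_mode, "log_base": 2, "pseudocount": 1, "scale": SCALE},
        },
    )
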