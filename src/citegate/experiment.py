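"""In-memory container for a multiplexed CITE-seq experiment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class CellExperiment:
    """Aligned RNA / ADT / sample-tag count matrices plus metadata.

    All three matrices share the cell axis (rows) in identical order.
    ``rna`` is kept sparse (CSR) since targeted-panel counts are still
    mostly zero; ADT and tag matrices are small and dense.
    """

    rna: sparse.csr_matrix            # cells x genes, non-negative ints
    adt: np.ndarray                   # cells x antibodies, non-negative ints
    tags: np.ndarray                  # cells x sample tags, non-negative ints
    gene_names: list[str]
    antibody_names: list[str]
    tag_names: list[str]
    cell_meta: pd.DataFrame           # index: barcode; columns incl. subject, plate
    subject_meta: pd.DataFrame        # index: subject id; columns incl. group, sex, plate

    def __post_init__(self) -> None:
        n = self.rna.shape[0]
        if self.adt.shape[0] != n or self.tags.shape[0] != n or len(self.cell_meta) != n:
            raise ValueError("RNA, ADT, tag matrices and cell_meta must share the cell axis")
        if self.rna.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length does not match RNA columns")
        if self.adt.shape[1] != len(self.antibody_names):
            raise ValueError("antibody_names length does not match ADT columns")
        if self.tags.shape[1] != len(self.tag_names):
            raise ValueError("tag_names length does not match tag columns")
        for label, names in (
            ("gene", self.gene_names),
            ("antibody", self.antibody_names),
            ("tag", self.tag_names),
        ):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {label} names")
        if self.cell_meta.index.has_duplicates:
            dup = self.cell_meta.index[self.cell_meta.index.duplicated()][0]
            raise ValueError(f"duplicate cell barcode: {dup!r}")
        assigned = self.cell_meta.get("subject")
        if assigned is not None:
            known = set(self.subject_meta.index)
            missing = set(assigned.dropna()) - known
            if missing:
                raise ValueError(f"cells assigned to unknown subjects: {sorted(missing)[:5]}")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    def subset_cells(self, mask_or_idx) -> "CellExperiment":
        """Return a new experiment restricted to the given cells (order kept)."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellExperiment(
            rna=self.rna[idx],
            adt=self.adt[idx],
            tags=self.tags[idx],
            gene_names=list(self.gene_names),
            antibody_names=list(self.antibody_names),
            tag_names=list(self.tag_names),
            cell_meta=self.cell_meta.iloc[idx].copy(),
            subject_meta=self.subject_meta.copy(),
        )


@dataclass
class NormalizedMatrices:
    """CLR-normalized ADT and log2-normalized RNA with provenance."""

    adt_clr: np.ndarray               # cells x antibodies, CLR on log2 scale
    rna_norm: np.ndarray              # cells x genes, log2 scale, >= 0
    provenance: dict = field(default_factory=dict)
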