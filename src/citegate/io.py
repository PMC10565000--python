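"""Readers and writers for all on-disk formats.

A fixture directory holds: ``rna.mtx`` (MatrixMarket coordinate, 1-based on
disk, 0-based in memory), ``genes.txt`` / ``barcodes.txt`` name files,
dense ``adt.csv`` / ``tags.csv`` count tables, ``cell_meta.csv`` /
``subject_meta.csv`` metadata, and optionally ``truth.json`` with the
planted ground truth of a simulated experiment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .errors import FormatError
from .experiment import CellExperiment
from .simulate import GroundTruth

logger = logging.getLogger(__name__)


def _read_names(path: Path) -> list[str]:
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return names


def write_experiment(experiment: CellExperiment, directory) -> Path:
    """Persist an experiment to a fixture directory (text formats only)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(d / "rna.mtx", sparse.coo_matrix(experiment.rna), field="integer")
    (d / "genes.txt").write_text("\n".join(experiment.gene_names) + "\n")
    (d / "barcodes.txt").write_text("\n".join(experiment.barcodes) + "\n")
    pd.DataFrame(experiment.adt, index=experiment.barcodes,
                 columns=experiment.antibody_names).to_csv(d / "adt.csv")
    pd.DataFrame(experiment.tags, index=experiment.barcodes,
                 columns=experiment.tag_names).to_csv(d / "tags.csv")
    experiment.cell_meta.to_csv(d / "cell_meta.csv")
    experiment.subject_meta.to_csv(d / "subject_meta.csv")
    return d


def write_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    payload = {
        "population": list(truth.population),
        "subject": list(truth.subject),
        "is_doublet": [bool(b) for b in truth.is_doublet],
        "doublet_kind": list(truth.doublet_kind),
        "doublet_partner_populations": list(truth.doublet_partner_populations),
        "true_thresholds": truth.true_thresholds,
        "positive_markers": truth.positive_markers,
        "de_genes": [[g, e] for g, e in truth.de_genes],
        "discriminative_genes": [[g, e] for g, e in truth.discriminative_genes],
        "case_subjects": truth.case_subjects,
    }
    path.write_text(json.dumps(payload))
    return path


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        population=np.array(payload["population"], dtype=object),
        subject=np.array(payload["subject"], dtype=object),
        is_doublet=np.array(payload["is_doublet"], dtype=bool),
        doublet_kind=np.array(payload["doublet_kind"], dtype=object),
        doublet_partner_populations=np.array(
            payload["doublet_partner_populations"], dtype=object),
        true_thresholds={k: float(v) for k, v in payload["true_thresholds"].items()},
        positive_markers={k: list(v) for k, v in payload["positive_markers"].items()},
        de_genes=[(g, float(e)) for g, e in payload["de_genes"]],
        discriminative_genes=[(g, float(e)) for g, e in payload["discriminative_genes"]],
        case_subjects=list(payload["case_subjects"]),
    )


def write_fixture(experiment: CellExperiment, truth: GroundTruth, directory) -> Path:
    """Persist experiment plus ground truth; round-trips losslessly."""
    d = write_experiment(experiment, directory)
    write_truth(truth, d / "truth.json")
    return d


def read_experiment(directory) -> CellExperiment:
    """Assemble a :class:`CellExperiment` from a fixture directory."""
    d = Path(directory)
    for f in ("rna.mtx", "genes.txt", "barcodes.txt", "adt.csv", "tags.csv",
              "cell_meta.csv", "subject_meta.csv"):
        if not (d / f).exists():
            raise FormatError(f"missing input file {f} in {d}")
    genes = _read_names(d / "genes.txt")
    barcodes = _read_names(d / "barcodes.txt")
    if len(set(barcodes)) != len(barcodes):
        seen, dup = set(), None
        for b in barcodes:
            if b in seen:
                dup = b
                break
            seen.add(b)
        raise FormatError(f"duplicate barcode in barcodes.txt: {dup!r}")
    rna = sparse.csr_matrix(scipy_io.mmread(d / "rna.mtx"))
    if rna.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"rna.mtx is {rna.shape}, expected ({len(barcodes)}, {len(genes)}) "
            "from barcodes.txt x genes.txt")

    adt_df = pd.read_csv(d / "adt.csv", index_col=0)
    tags_df = pd.read_csv(d / "tags.csv", index_col=0)
    for name, df in (("adt.csv", adt_df), ("tags.csv", tags_df)):
        if list(df.index) != barcodes:
            raise FormatError(f"{name} barcodes do not match barcodes.txt")

    cell_meta = pd.read_csv(d / "cell_meta.csv", index_col=0)
    cell_meta.index.name = "barcode"
    if "subject" in cell_meta.columns:
        cell_meta["subject"] = cell_meta["subject"].astype("string")
    subject_meta = pd.read_csv(d / "subject_meta.csv", index_col=0)
    subject_meta.index = subject_meta.index.astype(str)
    subject_meta.index.name = "subject"

    experiment = CellExperiment(
        rna=rna,
        adt=adt_df.to_numpy(dtype=np.int64),
        tags=tags_df.to_numpy(dtype=np.int64),
        gene_names=genes,
        antibody_names=list(adt_df.columns),
        tag_names=list(tags_df.columns),
        cell_meta=cell_meta,
        subject_meta=subject_meta,
    )
    logger.info("read experiment: %d cells, %d genes, %d antibodies, %d tags",
                experiment.n_cells, len(genes), len(adt_df.columns), len(tags_df.columns))
    return experiment


@dataclass
class GeneSetLibrary:
    """Named gene sets (symbols upper-cased, deduplicated) from a GMT file."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetLibrary:
    """Parse a GMT file: name, description, genes, tab-separated per line."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path.name}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        genes = {g.strip().upper() for g in fields[2:] if g.strip()}
        if not genes:
            raise FormatError(f"{path.name}:{lineno}: gene set {name!r} has no genes")
        sets[name] = genes
    if not sets:
        logger.warning("GMT file %s is empty", path)
    return GeneSetLibrary(sets=sets, source=path.name)


GENSINI_HIGH = 30.0   # score strictly above -> CAD_high
GENSINI_LOW = 6.0     # score strictly below -> CAD_low


def label_subjects_by_gensini(scores) -> pd.Series:
    """Dichotomize angiographic Gensini scores into CAD severity groups.

    Scores above 30 are CAD_high, below 6 are CAD_low; the intermediate
    range is excluded (label <NA>) rather than imputed.
    """
    s = pd.Series(scores, dtype=float)
    if (s < 0).any():
        bad = s[s < 0].index[0]
        raise ValueError(f"negative Gensini score at {bad!r}")
    labels = pd.Series(pd.NA, index=s.index, dtype="string")
    labels[s > GENSINI_HIGH] = "CAD_high"
    labels[s < GENSINI_LOW] = "CAD_low"
    return labels
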