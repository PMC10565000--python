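"""Default antibody panel, gene panel and population archetypes.

The defaults emulate a multiplexed targeted CITE-seq design: a 49-antibody
surface panel, a ~496-gene targeted mRNA panel, and a PBMC composition
dominated by CD8 T cell subsets (naive, effector memory, terminally
differentiated effector memory, CD38+ Emra, MAIT) plus CD4 T, B and myeloid
cells so that lineage gating and biological-doublet detection have real work
to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Lineage markers used by gates and doublet rules.
LINEAGE_MARKERS = [
    "CD3", "CD4", "CD8", "CD19", "CD14", "CD16",
    "CD33", "CD11C", "HLA-DR", "CD56",
]

# Phenotyping markers used for subset clustering and cluster naming.
PHENOTYPE_MARKERS = [
    "CD45RA", "CD45RO", "CCR7", "CD38", "CD161", "CD127",
    "CD27", "CD28", "CD25", "CD69", "CD95", "CD57",
    "KLRG1", "CXCR3", "CXCR5", "CCR6", "PD1", "CD122",
    "CD103", "CD49D",
]

N_ANTIBODIES_DEFAULT = 49

# Myeloid markers used to flag "biological doublets" on gated CD8 T cells.
MYELOID_CONFLICT_MARKERS = ["CD14", "CD33", "CD11C"]

# Named genes of the targeted panel (cytotoxicity, TCR signaling, memory,
# lineage); the remainder of the panel is filled with synthetic symbols.
NAMED_GENES = [
    "GZMB", "PRF1", "GNLY", "GZMK", "GZMH", "NKG7", "KLRD1", "KLRG1",
    "KLRB1", "KLRK1", "KLRC1", "KLRC3", "KLRC4", "KLRF1", "CTSW",
    "ZAP70", "GNAI2", "ITGB2", "JUNB", "CD3E", "LCK", "FYN", "CD2",
    "CD5", "ITK", "LAT", "PTPRC", "IFITM3", "TCF7", "SELL", "CCR7",
    "LEF1", "IL7R", "CD27", "CD28", "LAG3", "PRDM1", "CD38", "CD40LG",
    "MS4A1", "CD79A", "LYZ", "CD14", "S100A8", "IL32", "CXCR5",
]

N_GENES_DEFAULT = 496


def antibody_names(n: int = N_ANTIBODIES_DEFAULT) -> list[str]:
    """Panel of ``n`` antibody names: named markers first, then fillers."""
    named = LINEAGE_MARKERS + PHENOTYPE_MARKERS
    if n <= len(named):
        return named[:n]
    fillers = [f"AB{i:02d}" for i in range(len(named) + 1, n + 1)]
    return named + fillers


def gene_names(n: int = N_GENES_DEFAULT) -> list[str]:
    """Targeted gene panel of size ``n``; filler symbols pad the named set."""
    if n <= len(NAMED_GENES):
        return NAMED_GENES[:n]
    fillers = [f"GENE{i:03d}" for i in range(len(NAMED_GENES) + 1, n + 1)]
    return NAMED_GENES + fillers


@dataclass
class PopulationSpec:
    """A simulated cell population defined by its surface phenotype.

    ``positive_markers`` / ``negative_markers`` are antibody names;
    ``expression_profile`` maps gene name -> multiplicative fold change
    applied to that gene's baseline negative-binomial mean.
    """

    name: str
    frequency: float
    positive_markers: set[str] = field(default_factory=set)
    negative_markers: set[str] = field(default_factory=set)
    expression_profile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive_markers & self.negative_markers:
            raise ValueError(
                f"population {self.name!r}: positive and negative marker "
                "sets overlap"
            )
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"population {self.name!r}: frequency out of (0,1]")


# CD8 T cell subset archetypes.  Naming conventions follow standard flow
# cytometry usage: Emra = CD45RA+ CCR7- terminally differentiated effector
# memory, Em = CD45RO+ CCR7- effector memory, MAIT = CD161+ CD127+.
def cd8_phenotypes() -> list[PopulationSpec]:
    return [
        PopulationSpec(
            "Naive", 0.20,
            positive_markers={"CD3", "CD8", "CD45RA", "CCR7", "CD27", "CD28", "CD127"},
            negative_markers={"CD4", "CD19", "CD14", "CD16", "CD45RO", "CD38", "CD161"},
            expression_profile={"TCF7": 4.0, "SELL": 4.0, "CCR7": 4.0, "LEF1": 4.0},
        ),
        PopulationSpec(
            "Em", 0.20,
            positive_markers={"CD3", "CD8", "CD45RO", "CD69", "CXCR3"},
            negative_markers={"CD4", "CD19", "CD14", "CD16", "CD45RA", "CCR7"},
            expression_profile={"GZMK": 4.0, "IL32": 3.0, "CXCR5": 2.0},
        ),
        PopulationSpec(
            "Emra", 0.15,
            positive_markers={"CD3", "CD8", "CD45RA", "CD57", "KLRG1"},
            negative_markers={"CD4", "CD19", "CD14", "CD16", "CCR7", "CD45RO", "CD27", "CD38"},
            expression_profile={
                "GZMB": 4.0, "PRF1": 4.0, "NKG7": 4.0, "KLRD1": 3.0, "KLRG1": 3.0,
            },
        ),
        PopulationSpec(
            "CD38+ Emra", 0.10,
            positive_markers={"CD3", "CD8", "CD45RA", "CD38", "CD57", "KLRG1"},
            negative_markers={"CD4", "CD19", "CD14", "CD16", "CCR7", "CD45RO"},
            expression_profile={
                "GZMB": 5.0, "PRF1": 5.0, "GNLY": 5.0, "CD38": 4.0, "CTSW": 3.0,
            },
        ),
        PopulationSpec(
            "MAIT", 0.10,
            positive_markers={"CD3", "CD8", "CD161", "CD127", "CD45RO", "CCR6"},
            negative_markers={"CD4", "CD19", "CD14", "CD16", "CCR7", "CD45RA"},
            expression_profile={"KLRB1": 5.0, "IL7R": 5.0},
        ),
    ]


def default_populations() -> list[PopulationSpec]:
    """Full default composition: five CD8 subsets plus CD4 T, B and myeloid."""
    pops = cd8_phenotypes()
    pops += [
        PopulationSpec(
            "CD4 T", 0.05,
            positive_markers={"CD3", "CD4", "CCR7", "CD45RA", "CD127"},
            negative_markers={"CD8", "CD19", "CD14", "CD16"},
            expression_profile={"CD40LG": 3.0, "TCF7": 2.0},
        ),
        PopulationSpec(
            "B", 0.10,
            positive_markers={"CD19", "HLA-DR", "CD45RA"},
            negative_markers={"CD3", "CD4", "CD8", "CD14", "CD16", "CD161"},
            expression_profile={"MS4A1": 6.0, "CD79A": 6.0},
        ),
        PopulationSpec(
            "Myeloid", 0.10,
            positive_markers={"CD14", "CD33", "CD11C", "HLA-DR"},
            negative_markers={"CD3", "CD4", "CD8", "CD19", "CD161"},
            expression_profile={"LYZ": 6.0, "CD14": 5.0, "S100A8": 6.0},
        ),
    ]
    return pops


CD8_POPULATION_NAMES = [p.name for p in cd8_phenotypes()]

# Planted case/control effects (gene, log2 fold change in CAD-high subjects).
DEFAULT_DE_GENES = [
    ("GZMB", 1.0), ("PRF1", 1.0), ("GNLY", 1.0), ("ZAP70", 1.0),
    ("CTSW", 1.0), ("GNAI2", 1.0), ("TCF7", 1.0), ("ITGB2", 1.0),
    ("JUNB", 1.0), ("KLRK1", 1.0),
]

# Planted discriminative genes for the classifier benchmark (disjoint from
# DEFAULT_DE_GENES so the two benchmarks do not confound each other).
DEFAULT_DISCRIMINATIVE_GENES = [
    ("KLRC4", 1.5), ("IFITM3", 1.5), ("CD3E", 1.5), ("LCK", 1.5),
    ("FYN", 1.5), ("CD2", 1.5), ("CD5", 1.5), ("ITK", 1.5),
    ("LAT", 1.5), ("PTPRC", 1.5),
]
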