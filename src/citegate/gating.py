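"""Gate-style cell selection on thresholded surface markers.

A gate is a conjunction of marker requirements, exactly as in a flow
cytometry workflow: a cell passes when it is strictly above threshold for
every required-positive antibody and at or below threshold for every
required-negative antibody.  CD8 T cells are gated as
CD19- CD14- CD16- CD3+ CD4- CD8+.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .thresholds import GLOBAL_CONTEXT, ThresholdTable


@dataclass
class GateRule:
    """Named marker-positivity rule; priority orders rule evaluation."""

    name: str
    require_positive: set[str] = field(default_factory=set)
    require_negative: set[str] = field(default_factory=set)
    priority: int = 0

    def __post_init__(self) -> None:
        overlap = self.require_positive & self.require_negative
        if overlap:
            raise ConfigurationError(
                f"gate {self.name!r}: markers both positive and negative: {sorted(overlap)}")


CD8_GATE = GateRule(
    "CD8 T",
    require_positive={"CD3", "CD8"},
    require_negative={"CD19", "CD14", "CD16", "CD4"},
)

# Ordered naming rules for CD8 T cell subsets; first match wins.
DEFAULT_NAMING_RULES = [
    GateRule("MAIT", {"CD161", "CD127"}, set(), priority=0),
    GateRule("CD38+ Emra", {"CD45RA", "CD38"}, {"CCR7"}, priority=1),
    GateRule("Naive", {"CD45RA", "CCR7"}, set(), priority=2),
    GateRule("Emra", {"CD45RA"}, {"CCR7"}, priority=3),
    GateRule("Em", {"CD45RO"}, {"CCR7"}, priority=4),
]

# Mutually exclusive lineage marker pairs; a cluster positive for both sides
# of >= 2 pairs is flagged as a likely doublet cluster.
EXCLUSIVE_LINEAGE_PAIRS = [
    ("CD3", "CD14"), ("CD3", "CD19"), ("CD3", "CD33"), ("CD8", "CD4"),
]


def _threshold_vector(antibodies: list[str], names, thresholds: ThresholdTable,
                      context: str) -> dict[str, float]:
    vec = {}
    for ab in names:
        if ab not in antibodies:
            raise ConfigurationError(f"gate antibody {ab!r} not in the panel")
        try:
            vec[ab] = thresholds.get(ab, context)
        except KeyError:
            raise ConfigurationError(
                f"gate antibody {ab!r} has no determined threshold") from None
    return vec


def apply_gate(adt_clr, antibodies: list[str], thresholds: ThresholdTable,
               rule: GateRule, context: str = GLOBAL_CONTEXT) -> np.ndarray:
    """Boolean mask of cells passing the gate (strict > for positives)."""
    clr = np.asarray(adt_clr)
    tvec = _threshold_vector(antibodies, rule.require_positive | rule.require_negative,
                             thresholds, context)
    keep = np.ones(clr.shape[0], dtype=bool)
    for ab in sorted(rule.require_positive):
        keep &= clr[:, antibodies.index(ab)] > tvec[ab]
    for ab in sorted(rule.require_negative):
        keep &= clr[:, antibodies.index(ab)] <= tvec[ab]
    return keep


def select_clustering_antibodies(
    antibodies: list[str],
    adt_clr_gated,
    thresholds: ThresholdTable,
    gate_rule: GateRule | None = None,
    positive_floor: float = 0.01,
    context: str = GLOBAL_CONTEXT,
) -> list[str]:
    """Antibodies used for surface-marker clustering of the gated cells.

    Drops (i) antibodies essentially non-expressed within the gate (positive
    fraction below ``positive_floor``), (ii) the gate's own negative markers
    (e.g. CD19 and CD4 for CD8 T cells), and (iii) antibodies whose
    thresholds could not be determined.
    """
    clr = np.asarray(adt_clr_gated)
    excluded = set(gate_rule.require_negative) if gate_rule is not None else set()
    selected = []
    for j, ab in enumerate(antibodies):
        if ab in excluded or not thresholds.is_determined(ab, context):
            continue
        frac = float((clr[:, j] > thresholds.get(ab, context)).mean())
        if frac >= positive_floor:
            selected.append(ab)
    if len(selected) < 3:
        raise ConfigurationError(
            f"only {len(selected)} antibodies survive selection; clustering unsupported")
    return selected
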