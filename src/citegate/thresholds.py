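"""Per-antibody positivity thresholds, optionally per major cell type.

For each antibody (within each cell-type context, or globally) a
two-component normal mixture is fitted to the CLR values and the threshold
placed at the posterior-0.5 crossing.  Antibodies whose mixture is
degenerate or ill-separated are flagged undetermined and excluded from
clustering downstream; a negative-reference quantile fallback can be
configured per antibody (e.g. CD3 thresholded on B cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError
from .experiment import NormalizedMatrices
from .mixture import (
    MixtureFit,
    fit_two_component_mixture,
    threshold_from_mixture,
    threshold_from_negative_reference,
)

logger = logging.getLogger(__name__)

GLOBAL_CONTEXT = "global"


@dataclass
class ThresholdTable:
    """One row per (antibody, context): threshold, method and fit diagnostics."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["antibody", "context", "threshold", "method", "determined",
                 "mu1", "mu2", "sigma1", "sigma2", "pi1", "converged"]))

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["antibody", "context"])
        if dup.any():
            raise ValueError("duplicate (antibody, context) rows in threshold table")

    def add(self, antibody: str, context: str, threshold: float, method: str,
            fit: MixtureFit | None = None, determined: bool = True) -> None:
        row = {
            "antibody": antibody, "context": context, "threshold": threshold,
            "method": method, "determined": determined,
            "mu1": np.nan, "mu2": np.nan, "sigma1": np.nan, "sigma2": np.nan,
            "pi1": np.nan, "converged": pd.NA,
        }
        if fit is not None:
            row.update(mu1=fit.mu1, mu2=fit.mu2, sigma1=fit.sigma1,
                       sigma2=fit.sigma2, pi1=fit.pi1, converged=fit.converged)
        if ((self.table["antibody"] == antibody) & (self.table["context"] == context)).any():
            raise ValueError(f"threshold already set for ({antibody}, {context})")
        self.table.loc[len(self.table)] = row

    def get(self, antibody: str, context: str = GLOBAL_CONTEXT) -> float:
        """Threshold for antibody in context, falling back to global."""
        for ctx in (context, GLOBAL_CONTEXT):
            hit = self.table[(self.table["antibody"] == antibody)
                             & (self.table["context"] == ctx)
                             & self.table["determined"]]
            if len(hit):
                return float(hit["threshold"].iloc[0])
        raise KeyError(f"no determined threshold for antibody {antibody!r} "
                       f"in context {context!r}")

    def is_determined(self, antibody: str, context: str = GLOBAL_CONTEXT) -> bool:
        try:
            self.get(antibody, context)
            return True
        except KeyError:
            return False

    def undetermined(self, context: str = GLOBAL_CONTEXT) -> list[str]:
        return sorted(a for a in self.table["antibody"].unique()
                      if not self.is_determined(a, context))

    def as_vector(self, antibodies: list[str], context: str = GLOBAL_CONTEXT) -> np.ndarray:
        """Thresholds aligned to an antibody list; NaN where undetermined."""
        out = np.full(len(antibodies), np.nan)
        for j, ab in enumerate(antibodies):
            if self.is_determined(ab, context):
                out[j] = self.get(ab, context)
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def positivity_calls(adt_clr: np.ndarray, antibodies: list[str],
                     thresholds: ThresholdTable,
                     context: str = GLOBAL_CONTEXT) -> np.ndarray:
    """Boolean cells x antibodies positivity: strictly above threshold.

    Cells exactly at the threshold are called negative (documented tie
    rule).  Columns without a determined threshold are all-False.
    """
    vec = thresholds.as_vector(antibodies, context)
    with np.errstate(invalid="ignore"):
        calls = adt_clr > vec[None, :]
    calls[:, np.isnan(vec)] = False
    return calls


def build_threshold_table(
    normalized: NormalizedMatrices,
    antibodies: list[str],
    cell_type_map=None,
    min_cells: int = 100,
    sigma_min: float = 0.05,
    min_separation_sd: float = 1.0,
    negative_reference: dict[str, str] | None = None,
    reference_quantile: float = 0.99,
    manual: dict[tuple[str, str], float] | None = None,
) -> ThresholdTable:
    """Fit thresholds for every antibody x context.

    ``cell_type_map`` gives per-cell coarse labels; ``None`` fits a single
    "global" context.  ``negative_reference`` maps an antibody to the coarse
    label of cells known not to express it, used as a fallback when the
    mixture fit fails or is ill-separated.  ``manual`` overrides
    (antibody, context) -> threshold.  Per-antibody failures are recorded
    as undetermined, never fatal.
    """
    clr = normalized.adt_clr
    if cell_type_map is None:
        contexts = {GLOBAL_CONTEXT: np.ones(clr.shape[0], dtype=bool)}
    else:
        labels = np.asarray(cell_type_map)
        contexts = {str(c): labels == c for c in pd.unique(labels)}
    manual = manual or {}
    negative_reference = negative_reference or {}

    result = ThresholdTable()
    for context, mask in contexts.items():
        for j, ab in enumerate(antibodies):
            if (ab, context) in manual:
                result.add(ab, context, manual[(ab, context)], "manual")
                continue
            values = clr[mask, j]
            if values.size < min_cells:
                result.add(ab, context, np.nan, "undetermined", determined=False)
                continue
            fit = None
            try:
                fit = fit_two_component_mixture(values, sigma_min=sigma_min)
                if not fit.converged or fit.separation_sd < min_separation_sd:
                    raise FitError("ill-separated or non-converged mixture")
                result.add(ab, context, threshold_from_mixture(fit), "mixture", fit=fit)
                continue
            except FitError as exc:
                logger.info("mixture threshold failed for %s/%s: %s", ab, context, exc)
            ref_label = negative_reference.get(ab)
            if ref_label is not None and cell_type_map is not None:
                ref_mask = np.asarray(cell_type_map) == ref_label
                try:
                    t = threshold_from_negative_reference(
                        clr[ref_mask, j], quantile=reference_quantile)
                    result.add(ab, context, t, "negative_reference", fit=fit)
                    continue
                except FitError as exc:
                    logger.info("negative-reference fallback failed for %s/%s: %s",
                                ab, context, exc)
            result.add(ab, context, np.nan, "undetermined", fit=fit, determined=False)
    n_und = len(result.table[~result.table["determined"]])
    if n_und:
        logger.info("thresholds undetermined for %d antibody/context pairs", n_und)
    return result
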