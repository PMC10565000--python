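"""Gene ranking by random-forest permutation feature importance.

A random-forest classifier separates CAD-high from CAD-low cells on
normalized gene expression.  Hyperparameters are selected by grid search
over a 3-fold cross-validation whose folds are split by subject (no
subject appears in both train and validation, preventing leakage).  A
gene's raw importance is the mean drop in held-out score when its column
is shuffled, averaged over folds and shuffle repeats; negative means are
floored at 0 and scores scaled so the maximum is 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, GroupKFold

logger = logging.getLogger(__name__)

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [None, 10],
    "max_features": ["sqrt", 0.3],
}
CV_FOLDS = 3


@dataclass
class ImportanceTable:
    """Per-gene permutation importances with model metadata."""

    table: pd.DataFrame                 # gene, raw_importance, scaled_importance, rank
    metadata: dict = field(default_factory=dict)

    def top(self, n: int) -> list[str]:
        return self.table.nsmallest(n, "rank")["gene"].tolist()


def rank_genes_by_importance(
    rna_norm,
    condition_labels,
    subject_ids,
    gene_names: list[str],
    grid: dict | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    scoring: str = "accuracy",
) -> ImportanceTable:
    """Train, select hyperparameters and rank genes by permutation importance."""
    x = np.asarray(rna_norm, dtype=float)
    y = np.asarray(condition_labels, dtype=object)
    groups = np.asarray(subject_ids, dtype=object)
    if x.shape[1] == 0:
        raise ValueError("no genes to rank")
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("importance ranking needs at least two classes")
    for c in range(classes.size):
        if pd.unique(groups[y_enc == c]).size < CV_FOLDS:
            raise ValueError(
                f"class {classes[c]!r} has fewer than {CV_FOLDS} subjects; "
                "subject-grouped folds cannot be built")
    if grid is None:
        grid = DEFAULT_GRID
    score_fn = balanced_accuracy_score if scoring == "balanced_accuracy" else accuracy_score

    folds = list(GroupKFold(n_splits=CV_FOLDS).split(x, y_enc, groups))
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        grid, cv=folds, scoring=scoring, n_jobs=1, refit=False,
    )
    search.fit(x, y_enc)
    best = search.best_params_
    logger.info("selected hyperparameters %s (mean CV %s %.3f)",
                best, scoring, search.best_score_)

    raw = np.zeros(x.shape[1])
    fold_scores = []
    for f, (tr, va) in enumerate(folds):
        model = RandomForestClassifier(random_state=seed + f, n_jobs=1, **best)
        model.fit(x[tr], y_enc[tr])
        fold_scores.append(float(score_fn(y_enc[va], model.predict(x[va]))))
        pi = permutation_importance(
            model, x[va], y_enc[va], n_repeats=n_repeats,
            random_state=seed + 1000 + f, scoring=scoring, n_jobs=1)
        raw += pi.importances_mean
    raw /= len(folds)

    floored = np.maximum(raw, 0.0)
    top = floored.max()
    # divide before scaling so the top gene is exactly 100.0
    scaled = 100.0 * (floored / top) if top > 0 else floored
    order = np.lexsort((np.asarray(gene_names, dtype=object), -scaled))
    rank = np.empty(len(gene_names), dtype=int)
    rank[order] = np.arange(1, len(gene_names) + 1)   # ties broken by gene name

    table = pd.DataFrame({
        "gene": gene_names,
        "raw_importance": raw,
        "scaled_importance": scaled,
        "rank": rank,
    }).sort_values("rank", ignore_index=True)
    return ImportanceTable(
        table=table,
        metadata={
            "grid": grid, "selected": best, "cv_folds": CV_FOLDS,
            "n_repeats": n_repeats, "seed": seed, "scoring": scoring,
            "fold_validation_scores": fold_scores,
            "classes": classes.tolist(),
        },
    )
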