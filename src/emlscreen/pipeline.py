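"""End-to-end convenience: peak table in, ensemble screening result out.

Glue over the module-level building blocks for the common workflow:
presence-filter the features, normalize to the internal standard, impute,
log/autoscale on the training split, screen features, train the seven base
models, admit them, derive the Youden threshold on held-out scores, and
report the diagnostic panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import classifiers, eml, feature_screen, preprocess, qc_filter
from .peaktable import EC, PeakTable


@dataclass
class ScreeningRun:
    """Everything the end-to-end run produced."""

    models: list[classifiers.TrainedModel]
    admitted: list[classifiers.TrainedModel]
    threshold: float
    auc: float
    auc_ci: tuple[float, float]
    panel: eml.DiagnosticPanel
    results: list[eml.EMLResult]
    class_summary: pd.DataFrame
    train_ids: list[str]
    eval_ids: list[str]
    screen_report: feature_screen.ScreenReport


def run_screening_pipeline(
    table: PeakTable,
    kinds: tuple[str, ...] = classifiers.MODEL_KINDS,
    train_fraction: float = 0.7,
    folds: int = 10,
    seed: int = 0,
    presence_threshold: float = 0.80,
    grids: dict | None = None,
    admit: bool = True,
) -> ScreeningRun:
    """Train the ensemble on a stratified split and screen the held-out set.

    The 70:30 stratified split separates training samples (transform
    fitting, feature screening, model training and their cross-validation)
    from evaluation samples, whose ensemble scores determine the Youden
    threshold and the diagnostic panel.
    """
    filtered, _ = qc_filter.filter_features(table, presence_threshold)
    normalized = preprocess.normalize_to_is(filtered)
    completed, _ = preprocess.impute_missing(normalized, "half_min")

    ids = list(completed.samples)
    train_ids, eval_ids = train_test_split(
        ids,
        train_size=train_fraction,
        stratify=completed.labels.to_numpy(),
        random_state=seed,
    )

    matrix = preprocess.log_and_autoscale(completed, fit_on=train_ids)
    train_m = matrix.subset_samples(train_ids)

    screen = feature_screen.screen_features(train_m, train_m.labels)
    if not screen.retained:
        raise ValueError("no features survived screening")
    train_m = train_m.subset_features(screen.retained)

    models = [
        classifiers.train_model(
            kind,
            train_m,
            train_m.labels,
            grid=None if grids is None else grids.get(kind),
            folds=folds,
            seed=seed,
        )
        for kind in kinds
    ]
    admitted = classifiers.admit_models(models) if admit else list(models)
    if not admitted:
        raise ValueError("no model passed the admission gates")

    eval_m = matrix.subset_samples(eval_ids).subset_features(screen.retained)
    results, _ = eml.screen_cohort(admitted, eval_m, threshold=0.0)
    scores = np.array([r.score for r in results])
    threshold, _, auc, ci = eml.choose_threshold(scores, eval_m.labels)

    results = [
        eml.EMLResult(r.sample_id, r.votes, r.score, threshold) for r in results
    ]
    _, class_summary = eml.screen_cohort(admitted, eval_m, threshold=threshold)
    panel = eml.diagnostic_panel(
        [r.predicted for r in results], eval_m.labels, scores
    )
    return ScreeningRun(
        models=models,
        admitted=admitted,
        threshold=threshold,
        auc=auc,
        auc_ci=ci,
        panel=panel,
        results=results,
        class_summary=class_summary,
        train_ids=list(train_ids),
        eval_ids=list(eval_ids),
        screen_report=screen,
    )
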