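"""Training orchestration: two-stage fitting, random search, cross-validation.

The functions here are thin wrappers around :class:`~iwnet.estimators.IWNetSegmenter`
operating on annotated cohorts (lists of :class:`~iwnet.data_io.AnnotatedNodule`).
Cross-validation partitions at scan level -- a scan's nodules never straddle
folds -- with stratification by texture class, and holds out 20% of the
training scans for validation.  Hyper-parameters ``{lambda1, gamma, p}`` are
found by random search with each triple drawn uniformly on [0, 1]^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_io import AnnotatedNodule
from .estimators import IWNetSegmenter
from .evaluation import (EvalRecord, asd, corrected_mean_iou, equivalent_radius,
                         interobserver_iou, iou, mean_iou_vs_annotators,
                         stratified_report, texture_class)
from .interaction import simulate_user_input

__all__ = [
    "TrainConfig",
    "train_two_stage",
    "random_search",
    "run_crossval",
    "evaluate_run",
    "early_stopping_trace",
]


@dataclass
class TrainConfig:
    """Training hyper-parameters; defaults follow the full-scale recipe.

    ``filters`` and epoch caps are configurable downward for desk-scale
    runs on phantom cohorts (e.g. 32^3 cubes with reduced widths).
    """

    learning_rate: float = 0.001
    batch_size: int = 8
    stage1_patience: int = 3
    stage2_patience: int = 5
    stage1_max_epochs: int = 50
    stage2_max_epochs: int = 50
    folds: int = 5
    val_fraction: float = 0.2
    threshold: float = 0.5
    gamma: float = 0.59
    p: float = 0.44
    lambda1: float = 0.68
    filters: Tuple[int, ...] = (12, 24, 68, 110)
    n_bottleneck: int = 2
    min_agreement: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.stage1_patience < 1 or self.stage2_patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


def _cohort_arrays(cohort: Sequence[AnnotatedNodule]):
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    shapes = {n.image.shape for n in cohort}
    if len(shapes) != 1:
        raise ValueError(f"cohort cubes must share one shape, got {shapes}")
    X = np.stack([n.image.values for n in cohort]).astype(np.float32)
    y = [list(n.masks) for n in cohort]
    return X, y


def _estimator(config: TrainConfig, seed=None) -> IWNetSegmenter:
    return IWNetSegmenter(
        filters=tuple(config.filters), n_bottleneck=config.n_bottleneck,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        gamma=config.gamma, p=config.p, lambda1=config.lambda1,
        stage1_patience=config.stage1_patience,
        stage2_patience=config.stage2_patience,
        stage1_max_epochs=config.stage1_max_epochs,
        stage2_max_epochs=config.stage2_max_epochs,
        val_fraction=config.val_fraction, threshold=config.threshold,
        seed=config.seed if seed is None else seed)


def train_two_stage(cohort: Sequence[AnnotatedNodule],
                    config: TrainConfig) -> IWNetSegmenter:
    """Fit the two-stage model on a cohort; returns the fitted estimator.

    Stage 1 trains the automatic block with the IoU loss until validation
    stops improving for ``stage1_patience`` epochs; its weights are then
    frozen and the correction block trains with the combined loss and
    per-epoch re-simulated user input (``stage2_patience``).  Validation
    holds out ``val_fraction`` of the *scans* so a scan's nodules never
    straddle the train/validation boundary.  The training log lives on
    ``estimator.history_``.
    """
    X, y = _cohort_arrays(cohort)
    rng = np.random.default_rng(config.seed)
    scans = sorted({n.scan_id for n in cohort})
    rng.shuffle(scans)
    n_val = max(1, int(round(config.val_fraction * len(scans)))) \
        if len(scans) > 1 else 0
    val_scans = set(scans[:n_val])
    val_idx = [i for i, n in enumerate(cohort) if n.scan_id in val_scans]
    return _estimator(config).fit(X, y, val_indices=val_idx or None)


def early_stopping_trace(val_losses: Sequence[float],
                         patience: int) -> Tuple[int, int]:
    """Epoch at which training stops and the best epoch, for a loss trace.

    Stops after the first epoch completing ``patience`` consecutive epochs
    without strict improvement (1-based epochs; returns ``len(val_losses)``
    if the trace ends first).
    """
    from .estimators import EarlyStopping

    stopper = EarlyStopping(patience)
    for epoch, loss in enumerate(val_losses, start=1):
        if stopper.update(float(loss)):
            return epoch, stopper.best_epoch
    return len(val_losses), stopper.best_epoch


def random_search(cohort: Sequence[AnnotatedNodule], n_steps: int = 100,
                  seed: int = 0, config: Optional[TrainConfig] = None,
                  evaluator: Optional[Callable[[dict], float]] = None) -> dict:
    """Uniform random search over ``{lambda1, gamma, p}`` on [0, 1]^3.

    Each step draws one triple and scores it with ``evaluator`` (higher is
    better); the default evaluator trains on the first train/validation
    split and returns the mean validation IoU of the corrected prediction.
    Returns the best triple plus the full trace of draws and scores.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    draws = [{"lambda1": float(t[0]), "gamma": float(t[1]), "p": float(t[2])}
             for t in rng.uniform(size=(n_steps, 3))]
    if evaluator is None:
        config = config or TrainConfig()
        evaluator = _default_search_evaluator(cohort, config)
    scores = [float(evaluator(d)) for d in draws]
    best = int(np.argmax(scores))
    return {"best": draws[best], "best_score": scores[best],
            "draws": draws, "scores": scores}


def _default_search_evaluator(cohort, config: TrainConfig):
    X, y = _cohort_arrays(cohort)

    def evaluate(triple: dict) -> float:
        cfg = TrainConfig(**{**asdict(config), **triple})
        est = _estimator(cfg).fit(X, y)
        records, _ = evaluate_run(est, cohort, cfg)
        return float(np.mean([r.corrected_iou for r in records]))

    return evaluate


def _scan_folds(cohort, n_folds: int, seed: int):
    """Scan-level folds, stratified by each scan's majority texture class."""
    from sklearn.model_selection import StratifiedGroupKFold

    scans = [n.scan_id for n in cohort]
    classes = [texture_class(n.texture_ratings) if n.texture_ratings else "solid"
               for n in cohort]
    unique_scans = sorted(set(scans))
    if len(unique_scans) < n_folds:
        raise ValueError(
            f"need at least {n_folds} scans for {n_folds} folds, "
            f"got {len(unique_scans)}")
    skf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    idx = np.arange(len(cohort))
    return list(skf.split(idx, classes, groups=scans))


def run_crossval(cohort: Sequence[AnnotatedNodule],
                 config: TrainConfig) -> pd.DataFrame:
    """Scan-level stratified k-fold cross-validation.

    Trains a fresh two-stage model per fold and aggregates the per-nodule
    evaluation records with a fold column.  Scan-level leakage is checked
    programmatically and raises if violated.
    """
    folds = _scan_folds(cohort, config.folds, config.seed)
    all_rows = []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        train_scans = {cohort[i].scan_id for i in train_idx}
        test_scans = {cohort[i].scan_id for i in test_idx}
        if train_scans & test_scans:
            raise RuntimeError(
                f"fold {fold_id}: scan-level leakage {train_scans & test_scans}")
        est = train_two_stage([cohort[i] for i in train_idx], config)
        records, _ = evaluate_run(est, [cohort[i] for i in test_idx], config)
        for r in records:
            all_rows.append({"fold": fold_id, **r.__dict__})
    return pd.DataFrame(all_rows)


def evaluate_run(model: IWNetSegmenter, cohort: Sequence[AnnotatedNodule],
                 config: TrainConfig):
    """Evaluate both protocols on every nodule with sufficient agreement.

    For each nodule with ``agreement_level >= config.min_agreement``: the
    automatic prediction is scored against every annotator (initial mean
    IoU), and one guided prediction per annotator -- driven by that
    annotator's simulated eval-mode diameter endpoints -- feeds the
    keep-the-better corrected score.  ASD follows the same keep decision,
    using IoU as the criterion.  Returns ``(records, summary_table)``.
    """
    records: List[EvalRecord] = []
    for nod in cohort:
        if nod.agreement_level < config.min_agreement:
            continue
        image = nod.image.values.astype(np.float32)
        spacing = nod.image.spacing
        initial = model.predict_proba(image[None])[0]
        initial_bin = initial >= config.threshold

        points = []
        for mask in nod.masks:
            try:
                points.append(simulate_user_input(mask, "eval"))
            except ValueError:
                points.append(None)
        k = nod.agreement_level
        X_rep = np.repeat(image[None], k, axis=0)
        _, corrected = model.predict_guided(X_rep, points)
        corrected_bins = corrected >= config.threshold

        per_init = [iou(m, initial_bin) for m in nod.masks]
        per_corr = [iou(m, c) for m, c in zip(nod.masks, corrected_bins)]
        rec = EvalRecord(
            nodule_id=nod.nodule_id,
            initial_iou=mean_iou_vs_annotators(nod.masks, initial_bin),
            corrected_iou=corrected_mean_iou(nod.masks, initial_bin,
                                             corrected_bins),
            interobserver=(interobserver_iou(nod.masks) if k >= 2 else None),
            initial_asd=_safe_mean_asd(nod.masks, [initial_bin] * k, spacing),
            corrected_asd=_safe_mean_asd(
                nod.masks,
                [c if pc >= pi else initial_bin
                 for c, pc, pi in zip(corrected_bins, per_corr, per_init)],
                spacing),
            radius_mm=equivalent_radius(nod.masks, spacing),
            texture=(texture_class(nod.texture_ratings)
                     if nod.texture_ratings else "solid"),
            per_annotator_initial=per_init,
            per_annotator_corrected=per_corr,
        )
        records.append(rec)
    summary = stratified_report(records) if records else pd.DataFrame()
    return records, summary


def _safe_mean_asd(annotations, preds, spacing) -> float:
    vals = []
    for m, p in zip(annotations, preds):
        if p.any() and m.any():
            vals.append(asd(m, p, spacing))
        else:
            vals.append(np.nan)
    return float(np.nanmean(vals)) if not all(np.isnan(v) for v in vals) else float("nan")
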