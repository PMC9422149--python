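"""Self-recognition and stratified k-fold cross-validation.

Confusion counts follow the clinical-cohort (rows, "Exp") x predicted
("Score" columns) layout, reported per thickness group and aggregated.
Folds are stratified by (group x cohort); by default the unit is the
subject, so the two twin images of a subject can never straddle a
train/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import DataError, ValidationError
from .grouping import EXCLUDED
from .score import ScoreModel, classify_images
from .thickness import COHORTS, cohort_map
from .train import fit_pipeline

log = logging.getLogger(__name__)


@dataclass
class ConfusionReport:
    """3x3 confusion counts per group and aggregated."""

    per_group: dict[str, pd.DataFrame] = field(default_factory=dict)
    excluded: int = 0  # images outside all windows or in unfitted groups

    @staticmethod
    def empty_counts() -> pd.DataFrame:
        z = np.zeros((len(COHORTS), len(COHORTS)), dtype=int)
        return pd.DataFrame(z, index=pd.Index(COHORTS, name="clinical"),
                            columns=pd.Index(COHORTS, name="predicted"))

    @property
    def aggregate(self) -> pd.DataFrame:
        out = self.empty_counts()
        for counts in self.per_group.values():
            out += counts
        return out

    def accuracy(self) -> pd.DataFrame:
        """Per-cohort row totals, correct counts and percentages."""
        agg = self.aggregate
        n = agg.sum(axis=1)
        correct = pd.Series(np.diag(agg), index=agg.index)
        with np.errstate(invalid="ignore"):
            pct = np.where(n > 0, 100.0 * correct / n, np.nan)
        return pd.DataFrame({"n": n, "correct": correct, "percent": pct})

    def add(self, other: "ConfusionReport") -> "ConfusionReport":
        for label, counts in other.per_group.items():
            if label in self.per_group:
                self.per_group[label] = self.per_group[label] + counts
            else:
                self.per_group[label] = counts.copy()
        self.excluded += other.excluded
        return self

    def to_dict(self) -> dict:
        return {
            "per_group": {g: c.to_dict() for g, c in self.per_group.items()},
            "aggregate": self.aggregate.to_dict(),
            "accuracy": self.accuracy().to_dict(),
            "excluded": self.excluded,
        }


def confusion_from_predictions(predictions: pd.DataFrame, metadata: pd.DataFrame) -> ConfusionReport:
    """Build the report from a ``classify_images`` output frame."""
    clinical = cohort_map(metadata).reindex(predictions.index)
    report = ConfusionReport()
    for label, sub in predictions.groupby("group", sort=True):
        pred = sub["predicted"]
        known = pred.notna()
        report.excluded += int((~known).sum())
        if label == EXCLUDED or not known.any():
            continue
        counts = ConfusionReport.empty_counts()
        for clin, p in zip(clinical.loc[sub.index[known]], pred[known]):
            if clin in COHORTS:
                counts.loc[clin, p] += 1
        report.per_group[str(label)] = counts
    return report


def self_recognition(model: ScoreModel, matrix: pd.DataFrame, metadata: pd.DataFrame) -> ConfusionReport:
    """Classify the training images with the model trained on them."""
    return confusion_from_predictions(classify_images(model, matrix), metadata)


@dataclass
class FoldPlan:
    """A k-way partition of image ids, stratified by (group x cohort)."""

    folds: list[list[str]]
    k: int
    unit: str
    seed: int

    def train_test(self, i: int) -> tuple[list[str], list[str]]:
        test = self.folds[i]
        train = [img for j, fold in enumerate(self.folds) if j != i for img in fold]
        return train, test


def stratified_kfold(
    metadata: pd.DataFrame,
    assignment: pd.DataFrame,
    k: int = 3,
    unit: str = "subject",
    seed: int = 0,
) -> FoldPlan:
    """Deterministic stratified folds.

    Strata are (thickness group x clinical cohort).  With
    ``unit="subject"`` all images of a subject share a fold and the
    subject's stratum comes from its first image (twin images sit in the
    same group in all but razor's-edge cases); ``unit="image"`` stratifies
    raw images.  Every stratum must have at least k members.
    """
    if unit not in ("subject", "image"):
        raise ValidationError(f"unit must be 'subject' or 'image', got {unit!r}")
    meta = metadata.set_index("image_id")
    grouped = assignment[assignment["group"] != EXCLUDED]
    info = pd.DataFrame(
        {
            "group": grouped["group"],
            "cohort": meta["cohort"].reindex(grouped.index),
            "subject": meta["subject_id"].reindex(grouped.index),
        }
    )
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    if unit == "image":
        for (g, c), sub in info.groupby(["group", "cohort"], sort=True):
            ids = sorted(sub.index)
            if len(ids) < k:
                raise ValidationError(f"stratum (group {g}, cohort {c}) has {len(ids)} images < k={k}")
            rng.shuffle(ids)
            for i, img in enumerate(ids):
                folds[i % k].append(img)
    else:
        by_subject = info.sort_index().groupby("subject", sort=True)
        stratum_of = {}
        images_of = {}
        for sid, sub in by_subject:
            first = sub.index.min()
            stratum_of[sid] = (sub.loc[first, "group"], sub.loc[first, "cohort"])
            images_of[sid] = sorted(sub.index)
        strata: dict[tuple, list] = {}
        for sid, st in stratum_of.items():
            strata.setdefault(st, []).append(sid)
        for (g, c), sids in sorted(strata.items()):
            if len(sids) < k:
                raise ValidationError(f"stratum (group {g}, cohort {c}) has {len(sids)} subjects < k={k}")
            sids = sorted(sids)
            rng.shuffle(sids)
            for i, sid in enumerate(sids):
                folds[i % k].extend(images_of[sid])
    return FoldPlan(folds=[sorted(f) for f in folds], k=k, unit=unit, seed=seed)


@dataclass
class CrossValResult:
    per_fold: list[ConfusionReport]
    pooled: ConfusionReport
    plan: FoldPlan


def cross_validate(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: AnalysisConfig | None = None,
    k: int = 3,
    unit: str = "subject",
    seed: int = 0,
) -> CrossValResult:
    """Stratified k-fold CV refitting the full pipeline per fold.

    Group windows (quantile mode), ROI selection and the score model are
    all re-derived from each fold's training images, so no test label or
    test thickness value influences the fit.  Held-out images falling
    outside the training windows, or into a group the fold could not
    fit, are counted as excluded.
    """
    config = config or AnalysisConfig()
    full = fit_pipeline(matrix, metadata, config)  # windows for stratification only
    plan = stratified_kfold(metadata, full.assignment, k=k, unit=unit, seed=seed)
    meta = metadata.set_index("image_id")
    per_fold = []
    pooled = ConfusionReport()
    for i in range(k):
        train, test = plan.train_test(i)
        if unit == "subject":
            overlap = set(meta.loc[train, "subject_id"]) & set(meta.loc[test, "subject_id"])
            assert not overlap, f"subject leakage across fold {i}: {sorted(overlap)[:3]}"
        windows = None
        if config.grouping_mode == "explicit":
            windows = full.windows  # explicit boundaries are frozen by configuration
        fitted = fit_pipeline(matrix, metadata, config, image_ids=train, windows=windows)
        predictions = classify_images(fitted.model, matrix[test])
        report = confusion_from_predictions(predictions, metadata)
        per_fold.append(report)
        pooled.add(report)
    return CrossValResult(per_fold=per_fold, pooled=pooled, plan=plan)
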