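"""Fit the full classifier from a thickness matrix: group, select, score."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import AnalysisConfig
from .errors import DataError
from .grouping import (
    GroupWindows,
    assign_groups,
    grouped_image_ids,
    make_group_windows,
    mean_thickness,
)
from .roi import ROISet, ZProfile, select_essential_roi, select_roi, zprofiles_for_group
from .score import ScoreModel, fit_score_model

log = logging.getLogger(__name__)


@dataclass
class FittedPipeline:
    """Trained state of one end-to-end fit."""

    config: AnalysisConfig
    windows: GroupWindows
    assignment: pd.DataFrame
    zprofiles: dict[str, dict[str, ZProfile]]
    roi: dict[str, ROISet]
    essential: dict[str, ROISet]
    model: ScoreModel
    skipped_groups: list[str] = field(default_factory=list)


def fit_pipeline(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: AnalysisConfig | None = None,
    image_ids=None,
    windows: GroupWindows | None = None,
    strict: bool = False,
) -> FittedPipeline:
    """Derive windows, select ROI vertices per group and fit the score model.

    ``image_ids`` restricts training to a subset (cross-validation folds).
    Pre-computed ``windows`` are honoured (explicit-boundary reproduction
    runs); otherwise quantile windows are derived from the training means.
    Groups where some cohort has fewer than 2 images, or where the
    essential set comes out empty, are skipped with a warning — or raise
    when ``strict``.
    """
    config = config or AnalysisConfig()
    cols = list(matrix.columns) if image_ids is None else [c for c in matrix.columns if c in set(image_ids)]
    sub = matrix[cols]
    means = mean_thickness(sub)
    if windows is None:
        if config.grouping_mode == "explicit":
            windows = make_group_windows(
                mode="explicit", boundaries=config.boundaries, trim=config.trim
            )
        else:
            windows = make_group_windows(
                means, n_groups=config.n_groups, mode="quantile",
                trim_fraction=config.trim_fraction,
            )
    assignment = assign_groups(means, windows)
    by_group = grouped_image_ids(assignment)

    zprofiles: dict[str, dict[str, ZProfile]] = {}
    roi: dict[str, ROISet] = {}
    essential: dict[str, ROISet] = {}
    skipped: list[str] = []
    for label, imgs in by_group.items():
        try:
            profs = zprofiles_for_group(sub, metadata, image_ids=imgs, group=label)
            ess = select_essential_roi(
                profs, cutoffs=config.essential_cutoffs,
                roi_cutoff=config.roi_cutoff, combine=config.essential_combine,
            )
            if len(ess) == 0:
                raise DataError(f"group {label}: empty essential ROI")
        except DataError as exc:
            if strict:
                raise
            log.warning("skipping group %s: %s", label, exc)
            skipped.append(label)
            continue
        zprofiles[label] = profs
        roi[label] = select_roi(profs, cutoff=config.roi_cutoff)
        essential[label] = ess
    if not essential:
        raise DataError("no group could be fitted (all skipped)")
    model = fit_score_model(
        sub, metadata, assignment, windows, essential,
        binning=config.binning(), kernel=config.kernel_spec(), cap=config.cap,
    )
    return FittedPipeline(
        config=config, windows=windows, assignment=assignment,
        zprofiles=zprofiles, roi=roi, essential=essential,
        model=model, skipped_groups=skipped,
    )
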