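"""Partition images into thickness groups by their mean cortical thickness.

Each image is summarised by its arithmetic mean thickness over all
(complete) vertices and assigned to one of ``n_groups`` contiguous
windows, labelled A (thickest) downwards.  A small fraction of extreme
means can be trimmed; images outside every window are EXCLUDED.  Windows
are lower-inclusive / upper-exclusive in mm.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class GroupWindows:
    """Ordered thickness windows, thickest (A) first.

    ``windows`` holds ``(label, lower_mm_inclusive, upper_mm_exclusive)``
    tuples, disjoint and contiguous, strictly descending in thickness.
    """

    windows: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValidationError("GroupWindows needs at least one window")
        prev_lo = None
        for label, lo, hi in self.windows:
            if not lo < hi:
                raise ValidationError(f"window {label}: lower {lo} must be < upper {hi}")
            if prev_lo is not None and hi != prev_lo:
                raise ValidationError(f"window {label}: not contiguous with previous window")
            prev_lo = lo

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w[0] for w in self.windows)

    @property
    def bounds(self) -> tuple[float, float]:
        """(global lower, global upper) trim bounds."""
        return self.windows[-1][1], self.windows[0][2]

    def label_of(self, mean_mm: float) -> str:
        for label, lo, hi in self.windows:
            if lo <= mean_mm < hi:
                return label
        return EXCLUDED

    def to_dict(self) -> list[list]:
        return [[label, lo, hi] for label, lo, hi in self.windows]

    @classmethod
    def from_dict(cls, items) -> "GroupWindows":
        return cls(tuple((str(l), float(lo), float(hi)) for l, lo, hi in items))


def mean_thickness(matrix: pd.DataFrame) -> pd.Series:
    """Per-image arithmetic mean thickness (mm) over all vertices."""
    if matrix.shape[0] == 0:
        raise DataError("cannot average over zero vertices")
    means = matrix.mean(axis=0)
    means.name = "mean_thickness"
    return means


def make_group_windows(
    means=None,
    n_groups: int = 4,
    mode: str = "quantile",
    boundaries=None,
    trim=None,
    trim_fraction: float = 0.004,
) -> GroupWindows:
    """Construct thickness windows.

    ``mode="explicit"`` takes the interior ``boundaries`` (descending, mm)
    and outer ``trim=(lower, upper)`` bounds verbatim.  ``mode="quantile"``
    trims ``trim_fraction`` of the images (half at each extreme) and splits
    the remaining means into ``n_groups`` equal-count windows.
    """
    labels = string.ascii_uppercase
    if n_groups < 1 or n_groups > len(labels):
        raise ValidationError(f"n_groups must be in 1..{len(labels)}")

    if mode == "explicit":
        if boundaries is None or trim is None:
            raise ValidationError("explicit mode requires boundaries and trim=(lower, upper)")
        lo_trim, hi_trim = float(trim[0]), float(trim[1])
        edges = [hi_trim] + [float(b) for b in boundaries] + [lo_trim]
        if any(nxt >= prev for prev, nxt in zip(edges, edges[1:])):
            raise ValidationError(f"boundaries not strictly descending: {edges}")
        wins = tuple(
            (labels[i], edges[i + 1], edges[i]) for i in range(len(edges) - 1)
        )
        return GroupWindows(wins)

    if mode != "quantile":
        raise ValidationError(f"unknown grouping mode {mode!r}")
    if means is None:
        raise ValidationError("quantile mode requires the per-image means")
    vals = np.sort(np.asarray(means, dtype=float))
    n = vals.size
    if np.unique(vals).size < n_groups:
        raise ValidationError(f"need at least {n_groups} distinct mean values, got {np.unique(vals).size}")
    n_trim = int(np.floor(n * trim_fraction / 2.0))
    kept = vals[n_trim : n - n_trim]
    lo = kept[0]
    hi = float(np.nextafter(kept[-1], np.inf))  # keep the largest untrimmed mean inside
    m = kept.size
    cuts = [float(kept[(j * m) // n_groups]) for j in range(1, n_groups)]
    edges = [float(lo)] + cuts + [hi]
    if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
        raise ValidationError("quantile edges are not strictly increasing (too many tied means)")
    # edges ascending; label A gets the topmost window
    wins = tuple(
        (labels[i], edges[n_groups - 1 - i], edges[n_groups - i]) for i in range(n_groups)
    )
    return GroupWindows(wins)


def assign_groups(means: pd.Series, windows: GroupWindows) -> pd.DataFrame:
    """Label each image by the window containing its mean, else EXCLUDED.

    Returns a frame indexed by image id with ``mean_thickness`` and
    ``group`` columns.
    """
    groups = means.map(windows.label_of)
    return pd.DataFrame({"mean_thickness": means, "group": groups})


def grouped_image_ids(assignment: pd.DataFrame) -> dict[str, list[str]]:
    """group label -> image ids, EXCLUDED omitted."""
    out: dict[str, list[str]] = {}
    for label, sub in assignment.groupby("group", sort=True):
        if label != EXCLUDED:
            out[str(label)] = list(sub.index)
    return out
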