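"""Cortical-thickness matrices and image metadata.

The canonical in-memory container is a pandas ``DataFrame`` of thickness
values in millimetres with vertices as rows and images as columns (the
``t[p, h]`` orientation every downstream computation indexes).  A second
``DataFrame`` carries per-image metadata: subject id, clinical cohort
(CN / MCI / AD, or UNKNOWN for query images), sex, age and the
acquisition label distinguishing the two T1 images taken per subject.

Thickness tables arrive as delimited text (TSV, or CSV when the file ends
in ``.csv``) with ids in the first row and column.  Values must lie in
[0, 6) mm — the range the 0.2 mm binning downstream can represent — and
unparseable cells become missing values that survive until
:func:`drop_incomplete_vertices` removes their vertices.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError, ThicknessRangeError, ValidationError

log = logging.getLogger(__name__)

THICKNESS_MIN = 0.0
THICKNESS_MAX = 6.0

COHORTS = ("CN", "MCI", "AD")
UNKNOWN_COHORT = "UNKNOWN"

#: Required metadata columns; sex/age/acquisition_label are optional on load.
METADATA_COLUMNS = ("image_id", "subject_id", "cohort", "sex", "age", "acquisition_label")
_REQUIRED_METADATA = ("image_id", "subject_id", "cohort")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_thickness_table(path, orientation: str = "vertices") -> pd.DataFrame:
    """Read a delimited thickness table into vertex x image orientation.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row and an id column.
    orientation
        ``"vertices"`` if rows are vertices, ``"images"`` if rows are
        images (the table is transposed into canonical orientation).
    """
    if orientation not in ("vertices", "images"):
        raise ValidationError(f"orientation must be 'vertices' or 'images', got {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"empty thickness table: {path}")
    if orientation == "images":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate vertex ids: {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate image ids: {dupes[:5]}")
    # unparseable cells -> NaN (missing until drop_incomplete_vertices)
    df = df.apply(pd.to_numeric, errors="coerce").astype(float)
    validate_thickness_values(df)
    return df


def validate_thickness_values(matrix: pd.DataFrame) -> None:
    """Reject finite values outside [0, 6) mm; missing values are allowed."""
    vals = matrix.to_numpy()
    finite = np.isfinite(vals)
    bad = finite & ((vals < THICKNESS_MIN) | (vals >= THICKNESS_MAX))
    if bad.any():
        p, h = np.argwhere(bad)[0]
        raise ThicknessRangeError(
            f"thickness {vals[p, h]!r} at vertex {matrix.index[p]!r}, image "
            f"{matrix.columns[h]!r} outside [{THICKNESS_MIN}, {THICKNESS_MAX}) mm"
        )


def write_thickness_table(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep=_sep_for(path))


def drop_incomplete_vertices(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep only vertices with a thickness value for every image.

    Vertex order is preserved; the number of dropped vertices is logged.
    Idempotent on complete matrices.
    """
    keep = matrix.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise DataError("all vertices have at least one missing value")
    if n_dropped:
        log.info("dropped %d incomplete vertices, %d remain", n_dropped, int(keep.sum()))
    return matrix.loc[keep]


def load_metadata(path) -> pd.DataFrame:
    """Read the image metadata table and validate cohort labels."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise DataError(f"metadata missing required columns: {missing}")
    for col, default in (("sex", ""), ("age", np.nan), ("acquisition_label", "")):
        if col not in df.columns:
            df[col] = default
    df = df[list(METADATA_COLUMNS)].copy()
    for col in ("image_id", "subject_id", "cohort"):
        df[col] = df[col].astype(str)
    return validate_metadata(df)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    allowed = set(COHORTS) | {UNKNOWN_COHORT}
    bad = sorted(set(metadata["cohort"]) - allowed)
    if bad:
        raise ValidationError(f"unknown cohort labels {bad}; allowed: {sorted(allowed)}")
    if metadata["image_id"].duplicated().any():
        dupes = metadata.loc[metadata["image_id"].duplicated(), "image_id"].tolist()
        raise DataError(f"duplicate image ids in metadata: {dupes[:5]}")
    return metadata


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep=_sep_for(path), index=False)


def check_pairing(matrix: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Every image column must have exactly one metadata row."""
    missing = sorted(set(matrix.columns) - set(metadata["image_id"]))
    if missing:
        raise DataError(f"images without metadata: {missing[:5]}")


def cohort_map(metadata: pd.DataFrame) -> pd.Series:
    """image_id -> cohort label."""
    return metadata.set_index("image_id")["cohort"]
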