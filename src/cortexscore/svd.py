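"""Singular-value diagnostics of the combined score matrix.

The three per-cohort score matrices are concatenated along the bin axis
into S(All) (vertices x 3*m_max, block order CN | MCI | AD), so each
right singular vector carries one curve over the bin index m per cohort.
Modes whose cohort segments track each other describe shared "default"
structure; modes whose segments diverge carry the cohort-discriminating
content.  The module reports the leading modes and cosine similarities
between cohort segments — as numbers for inspection, not as assertions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .score import ScoreMatrix
from .thickness import COHORTS

log = logging.getLogger(__name__)


def combined_score_matrix(s_cn, s_mci, s_ad) -> np.ndarray:
    """Horizontally concatenate the cohort score matrices (CN | MCI | AD)."""
    mats = []
    vertex_sets = []
    for s in (s_cn, s_mci, s_ad):
        if isinstance(s, ScoreMatrix):
            mats.append(s.values)
            vertex_sets.append(tuple(s.vertex_ids))
        else:
            mats.append(np.asarray(s, dtype=float))
    if vertex_sets and len(set(vertex_sets)) > 1:
        raise DataError("score matrices do not share a vertex set")
    if len({m.shape for m in mats}) > 1:
        raise DataError(f"score matrices have mismatched shapes: {[m.shape for m in mats]}")
    return np.hstack(mats)


@dataclass
class SVDModes:
    """Leading singular modes of a vertices x 3*m_max matrix."""

    singular_values: np.ndarray        # descending, length k
    left_vectors: np.ndarray           # (n_vertices, k)
    right_vectors: np.ndarray          # (k, 3*m_max)
    m_max: int

    @property
    def k(self) -> int:
        return len(self.singular_values)

    def segments(self, i: int) -> dict[str, np.ndarray]:
        """Cohort segments (length m_max each) of right vector i."""
        v = self.right_vectors[i]
        return {k: v[j * self.m_max : (j + 1) * self.m_max] for j, k in enumerate(COHORTS)}


def svd_modes(matrix: np.ndarray, k: int = 6, m_max: int | None = None) -> SVDModes:
    """Top-k singular modes with a deterministic sign convention.

    Each right vector is scaled so its largest-magnitude component is
    positive (the paired left vector is flipped with it).  If ``k``
    exceeds the numerical rank, the available rank modes are returned
    with a warning.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2:
        raise ValidationError("svd_modes expects a 2-D matrix")
    if m_max is None:
        if A.shape[1] % len(COHORTS):
            raise ValidationError("cannot infer m_max: column count not divisible by 3")
        m_max = A.shape[1] // len(COHORTS)
    if k > min(A.shape):
        raise ValidationError(f"k={k} exceeds min(matrix dims)={min(A.shape)}")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    tol = s[0] * max(A.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if k > rank:
        log.warning("requested k=%d modes but rank is %d; returning %d", k, rank, rank)
        k = rank
    U, s, Vt = U[:, :k].copy(), s[:k].copy(), Vt[:k].copy()
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    return SVDModes(singular_values=s, left_vectors=U, right_vectors=Vt, m_max=m_max)


def reconstruct(modes: SVDModes, k: int | None = None) -> np.ndarray:
    """Rank-k reconstruction sum_i s_i u_i v_i^T."""
    k = modes.k if k is None else min(k, modes.k)
    return (modes.left_vectors[:, :k] * modes.singular_values[:k]) @ modes.right_vectors[:k]


def segment_cosines(modes: SVDModes) -> pd.DataFrame:
    """Cosine similarity between cohort segments of each mode.

    High values mean the cohorts' curves follow a common trend in that
    mode; low or negative values flag cohort-specific structure.
    """
    rows = []
    for i in range(modes.k):
        seg = modes.segments(i)
        row = {"mode": i + 1, "singular_value": float(modes.singular_values[i])}
        for a, b in (("CN", "MCI"), ("CN", "AD"), ("MCI", "AD")):
            x, y = seg[a], seg[b]
            denom = np.linalg.norm(x) * np.linalg.norm(y)
            row[f"cos_{a}_{b}"] = float(x @ y / denom) if denom > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("mode")
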