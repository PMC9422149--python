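"""Continuous severity degree from a covariance correlation matrix.

Thickness profiles restricted to the essential ROI vertices are
standardised per vertex (population convention),

    t'[p, h] = (t[p, h] - <t[p]>) / sigma_p,

and the Gram matrix t''[i, j] = sum_p t'[p, i] t'[p, j], normalised by
its maximum element, gives the covariance correlation matrix C between
images.  For each image the contrast

    Cbar_i = <C[i, j]>_{j in AD} - <C[i, j]>_{j in CN}

is affinely rescaled so the severity degree

    SD_i = (Cbar_i - <Cbar>_CN) / (<Cbar>_AD - <Cbar>_CN)

averages exactly 0 over the CN reference images and 1 over the AD
reference images; MCI images land in between (and may overshoot either
end).  The same frozen normalisation — per-vertex mean/sigma, the Gram
maximum and the two reference anchors — scores new subjects on the
training scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .grouping import EXCLUDED
from .thickness import COHORTS, cohort_map

log = logging.getLogger(__name__)

COHORT_BLOCK_ORDER = ("CN", "MCI", "AD")


@dataclass
class NormalizedProfiles:
    """Per-vertex standardised thickness profiles and the stats used."""

    values: pd.DataFrame  # vertex x image
    mean: pd.Series       # per-vertex mean (mm)
    sigma: pd.Series      # per-vertex population std (mm)


@dataclass
class CovarianceCorrelation:
    """Image x image max-normalised Gram matrix."""

    values: pd.DataFrame
    max_gram: float  # the normalising max{t''}, taken over all elements


@dataclass
class SeverityModel:
    """Frozen training-side state for scoring new profiles."""

    vertex_ids: np.ndarray
    mean: pd.Series
    sigma: pd.Series
    ref_profiles: pd.DataFrame  # normalised training profiles (vertex x image)
    ref_cohorts: pd.Series      # image -> cohort for the reference images
    max_gram: float
    cbar_cn: float
    cbar_ad: float
    include_self: bool = True


def normalize_profiles(matrix: pd.DataFrame) -> NormalizedProfiles:
    """Standardise each vertex row to mean 0, variance 1 (population sigma).

    Constant vertices cannot be standardised and raise ``DataError``
    naming the first offending vertex; exclude them before calling.
    """
    mean = matrix.mean(axis=1)
    sigma = matrix.std(axis=1, ddof=0)
    zero = sigma == 0.0
    if zero.any():
        raise DataError(f"constant thickness at vertex {matrix.index[zero][0]!r}: sigma is 0")
    values = matrix.sub(mean, axis=0).div(sigma, axis=0)
    return NormalizedProfiles(values=values, mean=mean, sigma=sigma)


def covariance_correlation(profiles) -> CovarianceCorrelation:
    """Gram matrix of normalised profiles, divided by its maximum element.

    The maximum is taken over all elements including the diagonal, so
    the largest entry of C is exactly 1.
    """
    tp = profiles.values if isinstance(profiles, NormalizedProfiles) else profiles
    if tp.shape[1] < 2:
        raise DataError("covariance correlation needs at least 2 images")
    gram = tp.T @ tp
    max_gram = float(gram.to_numpy().max())
    if max_gram == 0.0:
        raise DataError("degenerate profiles: Gram matrix is all zero")
    return CovarianceCorrelation(values=gram / max_gram, max_gram=max_gram)


def _cohort_contrast(C: pd.DataFrame, cohorts: pd.Series, include_self: bool) -> pd.Series:
    """Cbar_i = mean_j-in-AD C[i,j] - mean_j-in-CN C[i,j]."""
    vals = C.to_numpy()
    out = np.zeros(len(C))
    parts = {}
    for k in ("AD", "CN"):
        cols = np.asarray(cohorts.reindex(C.columns) == k)
        n = int(cols.sum())
        if n == 0:
            raise DataError(f"no {k} reference images for the severity contrast")
        sums = vals[:, cols].sum(axis=1)
        if include_self:
            parts[k] = sums / n
        else:
            is_k = np.asarray(cohorts.reindex(C.index) == k)
            diag = np.diag(vals)
            nn = np.where(is_k, n - 1, n)
            if (nn == 0).any():
                raise DataError(f"cohort {k} needs >= 2 images to exclude the self term")
            parts[k] = (sums - np.where(is_k, diag, 0.0)) / nn
    out = parts["AD"] - parts["CN"]
    return pd.Series(out, index=C.index, name="cbar_ad_cn")


def severity_degree(
    C: CovarianceCorrelation | pd.DataFrame,
    cohorts: pd.Series,
    include_self: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Severity degree per image, anchored at CN mean 0 and AD mean 1.

    ``cohorts`` maps image id to clinical cohort.  ``include_self``
    keeps the j = i term in the cohort averages (the anchors hold either
    way).  Returns the severity table (cohort, cbar_ad_cn, SD, rank
    ascending within cohort) and the frozen anchors.
    """
    Cdf = C.values if isinstance(C, CovarianceCorrelation) else C
    cbar = _cohort_contrast(Cdf, cohorts, include_self)
    co = cohorts.reindex(Cdf.index)
    cbar_cn = float(cbar[co == "CN"].mean())
    cbar_ad = float(cbar[co == "AD"].mean())
    if cbar_ad == cbar_cn:
        raise DataError("degenerate severity separation: <Cbar>_AD equals <Cbar>_CN")
    sd = (cbar - cbar_cn) / (cbar_ad - cbar_cn)
    table = pd.DataFrame({"cohort": co, "cbar_ad_cn": cbar, "SD": sd})
    table["rank"] = table.groupby("cohort")["SD"].rank(method="first").astype(int)
    table.index.name = "image_id"
    constants = {"cbar_cn": cbar_cn, "cbar_ad": cbar_ad}
    return table, constants


def fit_severity(
    matrix_at_roi: pd.DataFrame,
    cohorts: pd.Series,
    include_self: bool = True,
) -> tuple[pd.DataFrame, CovarianceCorrelation, SeverityModel]:
    """Normalise, correlate and score one group's images; freeze the model."""
    profiles = normalize_profiles(matrix_at_roi)
    C = covariance_correlation(profiles)
    table, constants = severity_degree(C, cohorts, include_self=include_self)
    model = SeverityModel(
        vertex_ids=matrix_at_roi.index.to_numpy(),
        mean=profiles.mean,
        sigma=profiles.sigma,
        ref_profiles=profiles.values,
        ref_cohorts=cohorts.reindex(matrix_at_roi.columns),
        max_gram=C.max_gram,
        cbar_cn=constants["cbar_cn"],
        cbar_ad=constants["cbar_ad"],
        include_self=include_self,
    )
    return table, C, model


def severity_for_new(queries: pd.DataFrame, model: SeverityModel) -> pd.Series:
    """Severity degree for query profiles on the frozen training scale.

    ``queries`` is vertex x image at the model's essential vertices.
    Queries are standardised with the training per-vertex mean/sigma,
    correlated against the training CN and AD reference images, and
    rescaled with the training anchors.
    """
    try:
        q = queries.loc[model.vertex_ids]
    except KeyError as exc:
        raise DataError(f"query profiles missing essential ROI vertices: {exc}") from exc
    qn = q.sub(model.mean.to_numpy(), axis=0).div(model.sigma.to_numpy(), axis=0)
    gram = model.ref_profiles.T @ qn  # ref images x queries
    Cq = gram / model.max_gram
    parts = {}
    for k in ("AD", "CN"):
        refs = np.asarray(model.ref_cohorts == k)
        if refs.sum() == 0:
            raise DataError(f"severity model has no {k} reference images")
        parts[k] = Cq.loc[np.asarray(model.ref_cohorts.index)[refs]].mean(axis=0)
    cbar = parts["AD"] - parts["CN"]
    sd = (cbar - model.cbar_cn) / (model.cbar_ad - model.cbar_cn)
    sd.name = "SD"
    return sd


def reorder_by_severity(
    C: CovarianceCorrelation | pd.DataFrame,
    table: pd.DataFrame,
) -> tuple[list[str], pd.DataFrame]:
    """Permute images into cohort blocks (CN, MCI, AD) sorted by ascending SD.

    Returns the permutation (as image ids) and the reordered matrix.
    Idempotent: reordering an already-ordered matrix is the identity.
    """
    Cdf = C.values if isinstance(C, CovarianceCorrelation) else C
    missing = set(Cdf.index) - set(table.index)
    if missing:
        raise DataError(f"severity table does not cover images {sorted(missing)[:5]}")
    sub = table.loc[list(Cdf.index)]
    known = [k for k in COHORT_BLOCK_ORDER]
    order_key = sub["cohort"].map({k: i for i, k in enumerate(known)}).fillna(len(known))
    perm = sub.assign(_block=order_key).sort_values(["_block", "SD"], kind="stable").index.tolist()
    return perm, Cdf.loc[perm, perm]


def severity_by_group(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    assignment: pd.DataFrame,
    roisets,
    include_self: bool = True,
    predicted: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit the severity predictor per thickness group and pool the tables.

    ``roisets`` maps group label to the essential ROISet (or vertex ids).
    The pooled table gains ``group`` and, when ``predicted`` is given,
    ``predicted_cohort`` columns.  Returns (table, per-group dict of
    (CovarianceCorrelation, SeverityModel)).
    """
    cmap = cohort_map(metadata)
    tables = []
    per_group: dict[str, tuple[CovarianceCorrelation, SeverityModel]] = {}
    for label, sub in assignment.groupby("group", sort=True):
        if label == EXCLUDED or label not in roisets:
            continue
        roiset = roisets[label]
        vids = roiset.vertex_ids if hasattr(roiset, "vertex_ids") else np.asarray(list(roiset))
        block = matrix.loc[vids, sub.index]
        sigma = block.std(axis=1, ddof=0)
        block = block.loc[sigma > 0]  # constant-in-group vertices carry no profile signal
        table, C, model = fit_severity(block, cmap, include_self=include_self)
        table.insert(0, "group", label)
        tables.append(table)
        per_group[str(label)] = (C, model)
    if not tables:
        raise DataError("no group produced a severity table")
    pooled = pd.concat(tables)
    if predicted is not None:
        pooled["predicted_cohort"] = predicted.reindex(pooled.index)
    return pooled, per_group
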