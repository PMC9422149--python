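"""Statistical score matrices and cohort classification.

Within each thickness group, the thickness values of each cohort k are
histogrammed per essential-ROI vertex p into m = 1..30 bins of width
0.2 mm (covering 0-6 mm) to give a probability matrix P[p, m].  To
stabilise sparse cohorts, each image deposits a discrete nine-point
kernel (weights proportional to 56:43:21:7:1 at offsets 0, +-1..+-4
bins) instead of a point mass.  The score matrix is

    S[p, m] = -ln( Q[p, m] / Q[p] ),
    Q[p, m] = P[p, m] / sum_m P[p, m],
    Q[p]    = sum_m P[p, m] / sum_p sum_m P[p, m],

with zero-probability entries capped at a large constant.  A subject is
classified by summing, over the essential vertices of its thickness
group, the score at its own bin index, and taking the cohort with the
minimum total (ties broken CN < MCI < AD).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import erf

from ._version import __version__
from .errors import DataError, ValidationError
from .grouping import EXCLUDED, GroupWindows, assign_groups, grouped_image_ids, mean_thickness
from .roi import ROISet
from .thickness import COHORTS

log = logging.getLogger(__name__)

DEFAULT_CAP = 50.0
KERNEL_MODES = ("integer-ratio", "erf-recursion", "delta")
#: Guard against values an ulp below a bin boundary landing in the lower bin.
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class BinningSpec:
    """Thickness binning: ``m = 1..m_max`` bins of width ``delta`` mm.

    ``delta * m_max`` must equal 6 mm, the representable thickness range.
    Bins are lower-inclusive, upper-exclusive, so a value exactly on a
    boundary belongs to the upper bin.
    """

    delta: float = 0.2
    m_max: int = 30

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.m_max < 1:
            raise ValidationError("delta must be > 0 and m_max >= 1")
        if abs(self.delta * self.m_max - 6.0) > 1e-9:
            raise ValidationError(
                f"delta * m_max must equal 6 mm, got {self.delta} * {self.m_max} = {self.delta * self.m_max}"
            )

    @property
    def upper(self) -> float:
        return self.delta * self.m_max


@dataclass(frozen=True)
class KernelSpec:
    """Discrete smoothing kernel: weight ``weights[l + 4]`` at offset l bins."""

    mode: str
    weights: tuple[float, ...]

    @property
    def offsets(self) -> np.ndarray:
        half = (len(self.weights) - 1) // 2
        return np.arange(-half, half + 1)

    @property
    def sigma(self) -> float:
        """Standard deviation in bin widths, sqrt(sum w*l^2 / sum w)."""
        w = np.asarray(self.weights)
        l = self.offsets
        return float(np.sqrt((w * l**2).sum() / w.sum()))

    @property
    def mass(self) -> float:
        return float(np.sum(self.weights))


def kernel_weights(mode: str = "integer-ratio") -> KernelSpec:
    """Build a smoothing kernel.

    ``integer-ratio``
        Weights proportional to 56:43:21:7:1 at offsets 0, ±1..±4,
        normalised to sum exactly 1 (sigma = 1.4353 bin widths).
    ``erf-recursion``
        a_0 = erf(0.25); a_l = 0.5*erf(0.25 + 0.5*l) + a_0/2 - sum_{l'<l} a_{l'}
        for l = 1..4 (total mass ~= 0.9988).
    ``delta``
        Unit point mass (no smoothing).
    """
    if mode == "integer-ratio":
        ratios = np.array([1, 7, 21, 43, 56, 43, 21, 7, 1], dtype=float)
        return KernelSpec(mode=mode, weights=tuple(ratios / ratios.sum()))
    if mode == "erf-recursion":
        a = [float(erf(0.25))]
        for l in range(1, 5):
            a.append(float(0.5 * erf(0.25 + 0.5 * l) + a[0] / 2.0 - sum(a[:l])))
        w = a[:0:-1] + a  # a4..a1, a0, a1..a4
        return KernelSpec(mode=mode, weights=tuple(w))
    if mode == "delta":
        return KernelSpec(mode=mode, weights=(0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0))
    raise ValidationError(f"unknown kernel mode {mode!r}; choose from {KERNEL_MODES}")


def bin_index(t, binning: BinningSpec = BinningSpec()):
    """1-based bin index of thickness ``t``: m = floor(t/delta) + 1.

    Accepts scalars or arrays; every value must lie in [0, 6) mm.
    """
    arr = np.asarray(t, dtype=float)
    if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) >= binning.upper):
        raise ValidationError(f"thickness outside [0, {binning.upper}) mm cannot be binned")
    if np.isnan(arr).any():
        raise ValidationError("cannot bin missing thickness values")
    m = np.floor(arr / binning.delta + _BOUNDARY_EPS).astype(int) + 1
    m = np.minimum(m, binning.m_max)
    return m if m.ndim else int(m)


@dataclass
class ProbabilityMatrix:
    """Per-cohort vertex x bin probabilities P[p, m]."""

    cohort: str
    vertex_ids: np.ndarray
    values: np.ndarray  # (n_vertices, m_max)
    binning: BinningSpec
    kernel: KernelSpec
    n_images: int
    truncated: np.ndarray = field(default=None)  # per-vertex mass lost off the bin edges

    def __post_init__(self) -> None:
        if self.truncated is None:
            self.truncated = np.zeros(len(self.vertex_ids))


@dataclass
class ScoreMatrix:
    """Per-cohort vertex x bin scores S[p, m], capped where P = 0."""

    cohort: str
    vertex_ids: np.ndarray
    values: np.ndarray
    cap: float


def probability_matrix(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    roi: ROISet | Iterable[str],
    cohort: str,
    binning: BinningSpec = BinningSpec(),
    kernel: KernelSpec | None = None,
    image_ids: Iterable[str] | None = None,
) -> ProbabilityMatrix:
    """Estimate P[p, m] for one cohort over the ROI vertices.

    Each image deposits the kernel weights into bins centred on its bin
    index; mass falling outside bins 1..m_max is truncated (and recorded
    per vertex), then everything is divided by the cohort image count.
    """
    kernel = kernel or kernel_weights()
    vertex_ids = np.asarray(roi.vertex_ids if isinstance(roi, ROISet) else list(roi))
    if len(vertex_ids) == 0:
        raise DataError("probability_matrix: empty ROI")
    sub = metadata
    if image_ids is not None:
        sub = metadata[metadata["image_id"].isin(set(image_ids))]
    cols = sub.loc[sub["cohort"] == cohort, "image_id"].tolist()
    if not cols:
        raise DataError(f"cohort {cohort} has no images for probability estimation")
    vals = matrix.loc[vertex_ids, cols].to_numpy()
    m0 = bin_index(vals, binning) - 1  # 0-based centre bins, (v, n)
    n_v, n_img = vals.shape
    P = np.zeros((n_v, binning.m_max))
    truncated = np.zeros(n_v)
    rows = np.broadcast_to(np.arange(n_v)[:, None], m0.shape)
    for l, w in zip(kernel.offsets, kernel.weights):
        if w == 0.0:
            continue
        target = m0 + l
        ok = (target >= 0) & (target < binning.m_max)
        np.add.at(P, (rows[ok], target[ok]), w)
        truncated += w * (~ok).sum(axis=1)
    P /= n_img
    truncated /= n_img
    total_lost = float(truncated.sum())
    if total_lost > 0:
        log.info("cohort %s: truncated kernel mass %.4g (summed over %d vertices)", cohort, total_lost, n_v)
    return ProbabilityMatrix(
        cohort=cohort, vertex_ids=vertex_ids, values=P,
        binning=binning, kernel=kernel, n_images=n_img, truncated=truncated,
    )


def score_matrix(P: ProbabilityMatrix, cap: float = DEFAULT_CAP) -> ScoreMatrix:
    """S[p, m] = -ln(Q[p, m] / Q[p]) with zero-probability entries set to ``cap``."""
    vals = P.values
    row_sums = vals.sum(axis=1)
    if (row_sums == 0).any():
        bad = P.vertex_ids[row_sums == 0][:5]
        raise DataError(f"all-zero probability rows at vertices {bad.tolist()}")
    Q = vals / row_sums[:, None]
    Qp = row_sums / row_sums.sum()
    with np.errstate(divide="ignore"):
        S = -np.log(Q) + np.log(Qp)[:, None]
    S[Q == 0.0] = cap
    return ScoreMatrix(cohort=P.cohort, vertex_ids=P.vertex_ids, values=S, cap=cap)


@dataclass
class CohortScores:
    """Total scores S' per cohort for one image, plus the argmin cohort."""

    image_id: str
    scores: dict[str, float]
    predicted: str
    group: str = ""


def total_score(
    profile: pd.Series,
    score_matrices: Mapping[str, ScoreMatrix],
    binning: BinningSpec = BinningSpec(),
    image_id: str = "",
    group: str = "",
) -> CohortScores:
    """Sum each cohort's score at the subject's bin over the essential vertices.

    ``profile`` must supply a thickness for every vertex of the score
    matrices; the predicted cohort attains the minimum total, ties broken
    in CN < MCI < AD order.
    """
    ref = next(iter(score_matrices.values()))
    try:
        vals = profile.loc[ref.vertex_ids].to_numpy(dtype=float)
    except KeyError as exc:
        raise DataError(f"profile is missing essential ROI vertices: {exc}") from exc
    if np.isnan(vals).any():
        raise DataError("profile has missing values at essential ROI vertices")
    m0 = bin_index(vals, binning) - 1
    idx = np.arange(len(vals))
    totals = {}
    for k in COHORTS:
        if k not in score_matrices:
            raise ValidationError(f"missing score matrix for cohort {k}")
        totals[k] = float(score_matrices[k].values[idx, m0].sum())
    predicted = min(COHORTS, key=lambda k: (totals[k], COHORTS.index(k)))
    return CohortScores(image_id=image_id, scores=totals, predicted=predicted, group=group)


@dataclass
class GroupModel:
    """Trained per-group state: essential vertices, P/S per cohort, severity stats."""

    group: str
    vertex_ids: np.ndarray
    binning: BinningSpec
    kernel: KernelSpec
    cap: float
    P: dict[str, ProbabilityMatrix]
    S: dict[str, ScoreMatrix]
    train_mean: np.ndarray   # per-vertex mean over all group images (mm)
    train_sigma: np.ndarray  # population std over all group images (mm)
    n_images: dict[str, int]


@dataclass
class ScoreModel:
    """The full trained classifier: group windows plus one GroupModel each."""

    windows: GroupWindows
    binning: BinningSpec
    kernel: KernelSpec
    cap: float
    groups: dict[str, GroupModel]


def fit_score_model(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    assignment: pd.DataFrame,
    windows: GroupWindows,
    roisets: Mapping[str, ROISet],
    binning: BinningSpec = BinningSpec(),
    kernel: KernelSpec | None = None,
    cap: float = DEFAULT_CAP,
) -> ScoreModel:
    """Fit P and S for every cohort of every group in ``roisets``.

    Vertices whose thickness is constant across a group's images are
    dropped from that group's essential set (they carry no profile
    information and would break the severity normalisation).
    """
    kernel = kernel or kernel_weights()
    by_group = grouped_image_ids(assignment)
    groups: dict[str, GroupModel] = {}
    for label, roiset in roisets.items():
        if label not in by_group:
            raise DataError(f"group {label} has no images")
        imgs = by_group[label]
        sub = metadata[metadata["image_id"].isin(set(imgs))]
        for k in COHORTS:
            if (sub["cohort"] == k).sum() == 0:
                raise DataError(f"group {label} is missing cohort {k}")
        vids = np.asarray(roiset.vertex_ids)
        if len(vids) == 0:
            raise DataError(f"group {label}: empty essential ROI")
        vals = matrix.loc[vids, imgs].to_numpy()
        sigma = vals.std(axis=1)  # population std over images
        keep = sigma > 0
        if not keep.all():
            log.warning("group %s: dropping %d constant vertices from essential set", label, int((~keep).sum()))
            vids, vals, sigma = vids[keep], vals[keep], sigma[keep]
            if len(vids) == 0:
                raise DataError(f"group {label}: essential ROI is entirely constant")
        P = {
            k: probability_matrix(matrix, sub, vids, k, binning=binning, kernel=kernel)
            for k in COHORTS
        }
        S = {k: score_matrix(P[k], cap=cap) for k in COHORTS}
        groups[label] = GroupModel(
            group=label, vertex_ids=vids, binning=binning, kernel=kernel, cap=cap,
            P=P, S=S,
            train_mean=vals.mean(axis=1), train_sigma=sigma,
            n_images={k: P[k].n_images for k in COHORTS},
        )
    return ScoreModel(windows=windows, binning=binning, kernel=kernel, cap=cap, groups=groups)


def classify_images(model: ScoreModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Classify every image column of ``matrix``.

    Returns a frame indexed by image id with the per-image mean
    thickness, assigned group (or EXCLUDED), per-cohort total scores and
    the predicted cohort (NA when the image falls outside all windows or
    into a group the model was not fitted for).
    """
    means = mean_thickness(matrix)
    assignment = assign_groups(means, model.windows)
    rows = []
    for label, sub in assignment.groupby("group", sort=False):
        if label == EXCLUDED or label not in model.groups:
            if label != EXCLUDED:
                log.warning("no fitted model for group %s; %d images left unclassified", label, len(sub))
            for img in sub.index:
                rows.append({"image_id": img, "mean_thickness": means[img], "group": label,
                             **{f"score_{k}": np.nan for k in COHORTS}, "predicted": pd.NA})
            continue
        gm = model.groups[label]
        vals = matrix.loc[gm.vertex_ids, sub.index].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise DataError(f"missing thickness at essential vertices of group {label}")
        m0 = bin_index(vals, model.binning) - 1
        idx = np.arange(vals.shape[0])[:, None]
        totals = {k: gm.S[k].values[idx, m0].sum(axis=0) for k in COHORTS}
        stacked = np.vstack([totals[k] for k in COHORTS])
        pred = np.argmin(stacked, axis=0)  # argmin picks first min: CN < MCI < AD tie order
        for j, img in enumerate(sub.index):
            rows.append({"image_id": img, "mean_thickness": means[img], "group": label,
                         **{f"score_{k}": float(totals[k][j]) for k in COHORTS},
                         "predicted": COHORTS[pred[j]]})
    out = pd.DataFrame(rows).set_index("image_id")
    return out.loc[matrix.columns]


# -- model persistence: a directory of TSV matrices plus a JSON manifest -----

def save_model(model: ScoreModel, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "package_version": __version__,
        "binning": {"delta": model.binning.delta, "m_max": model.binning.m_max},
        "kernel": model.kernel.mode,
        "cap": model.cap,
        "windows": model.windows.to_dict(),
        "groups": {
            label: {"n_images": gm.n_images, "n_vertices": int(len(gm.vertex_ids))}
            for label, gm in model.groups.items()
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bin_cols = [f"m{m}" for m in range(1, model.binning.m_max + 1)]
    for label, gm in model.groups.items():
        vinfo = pd.DataFrame(
            {"train_mean": gm.train_mean, "train_sigma": gm.train_sigma},
            index=pd.Index(gm.vertex_ids, name="vertex_id"),
        )
        for k in COHORTS:
            vinfo[f"truncated_{k}"] = gm.P[k].truncated
        # %.17g guarantees bit-identical float round-trips through text
        vinfo.to_csv(path / f"group_{label}_vertices.tsv", sep="\t", float_format="%.17g")
        for k in COHORTS:
            pd.DataFrame(gm.P[k].values, index=pd.Index(gm.vertex_ids, name="vertex_id"),
                         columns=bin_cols).to_csv(path / f"group_{label}_P_{k}.tsv", sep="\t",
                                                  float_format="%.17g")
            pd.DataFrame(gm.S[k].values, index=pd.Index(gm.vertex_ids, name="vertex_id"),
                         columns=bin_cols).to_csv(path / f"group_{label}_S_{k}.tsv", sep="\t",
                                                  float_format="%.17g")
    return path


def load_model(path) -> ScoreModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    binning = BinningSpec(delta=manifest["binning"]["delta"], m_max=manifest["binning"]["m_max"])
    kernel = kernel_weights(manifest["kernel"])
    cap = float(manifest["cap"])
    windows = GroupWindows.from_dict(manifest["windows"])
    groups: dict[str, GroupModel] = {}
    for label, ginfo in manifest["groups"].items():
        vinfo = pd.read_csv(path / f"group_{label}_vertices.tsv", sep="\t", index_col=0,
                            float_precision="round_trip")
        vinfo.index = vinfo.index.astype(str)
        vids = vinfo.index.to_numpy()
        P, S = {}, {}
        for k in COHORTS:
            pv = pd.read_csv(path / f"group_{label}_P_{k}.tsv", sep="\t", index_col=0,
                             float_precision="round_trip").to_numpy()
            sv = pd.read_csv(path / f"group_{label}_S_{k}.tsv", sep="\t", index_col=0,
                             float_precision="round_trip").to_numpy()
            P[k] = ProbabilityMatrix(
                cohort=k, vertex_ids=vids, values=pv, binning=binning, kernel=kernel,
                n_images=int(ginfo["n_images"][k]),
                truncated=vinfo[f"truncated_{k}"].to_numpy(),
            )
            S[k] = ScoreMatrix(cohort=k, vertex_ids=vids, values=sv, cap=cap)
        groups[label] = GroupModel(
            group=label, vertex_ids=vids, binning=binning, kernel=kernel, cap=cap,
            P=P, S=S,
            train_mean=vinfo["train_mean"].to_numpy(),
            train_sigma=vinfo["train_sigma"].to_numpy(),
            n_images={k: int(ginfo["n_images"][k]) for k in COHORTS},
        )
    return ScoreModel(windows=windows, binning=binning, kernel=kernel, cap=cap, groups=groups)
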