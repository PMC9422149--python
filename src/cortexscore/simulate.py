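"""Synthetic cohort studies with known ground truth.

The generator emulates the statistical structure the classifier assumes
in vertex-wise cortical thickness data: a per-vertex baseline thickness,
a per-subject global offset (the across-subject spread of mean thickness
that the A-D grouping controls), cohort effects concentrated at planted
vertex sets, and i.i.d. Gaussian measurement noise.  Each subject
contributes two twin images (the two T1 acquisitions) that share the
subject's offset and disease effect and differ only by noise.

Planted vertex sets mirror the separation categories the selector is
meant to find: AD-thinner and AD-thicker vertices (AD stands apart from
CN and MCI by one effect step) and monotone-descending vertices where
thickness falls CN > MCI > AD in two equal steps.  In severity mode a
latent severity s in [0, 1] per subject scales the planted effects
linearly — CN near 0, AD near 1, MCI spread across the whole range — so
a continuous severity estimate can be validated against the latent
truth.

Defaults (mm): baseline N(2.5, 0.2) clipped to [1.8, 3.2]; subject
offset N(0, 0.12) (the across-subject spread of mean thickness that the
thickness grouping is designed to control); noise N(0, 0.1); effect
step 0.2 (a standardised separation near 2 against the within-group
spread).  Gaussian tails are truncated (offsets at 4 sigma, noise at
5 sigma) so all values stay inside [0, 6) by construction; the
truncation is far enough out to be statistically invisible at these
scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

_BASELINE_CLIP = (1.8, 3.2)
_OFFSET_CLIP_SD = 4.0
_NOISE_CLIP_SD = 5.0

ACQUISITIONS = ("MPRAGE", "MPRAGE_SENSE2")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_vertices: int = 300
    subjects_per_cohort: int = 50
    images_per_subject: int = 2
    baseline_mean: float = 2.5
    baseline_sd: float = 0.2
    offset_sd: float = 0.12
    n_ad_thinner: int = 50
    n_ad_thicker: int = 30
    n_monotone: int = 40
    effect_mm: float = 0.2
    noise_sd: float = 0.1
    severity_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n_planted = self.n_ad_thinner + self.n_ad_thicker + self.n_monotone
        if n_planted > self.n_vertices:
            raise ValidationError(f"{n_planted} planted vertices exceed n_vertices={self.n_vertices}")
        if self.images_per_subject < 1 or self.subjects_per_cohort < 1:
            raise ValidationError("need >= 1 subject per cohort and >= 1 image per subject")
        if self.effect_mm < 0 or self.noise_sd < 0 or self.offset_sd < 0:
            raise ValidationError("effect, noise and offset spreads must be non-negative")
        max_effect = 2.0 * self.effect_mm  # the AD end of the monotone two-step descent
        hi = (
            _BASELINE_CLIP[1]
            + _OFFSET_CLIP_SD * self.offset_sd
            + max_effect
            + _NOISE_CLIP_SD * self.noise_sd
        )
        lo = (
            _BASELINE_CLIP[0]
            - _OFFSET_CLIP_SD * self.offset_sd
            - max_effect
            - _NOISE_CLIP_SD * self.noise_sd
        )
        if hi >= 6.0 or lo <= 0.0:
            raise ValidationError(
                f"configured effects can push thickness outside [0, 6) mm (range [{lo:.3g}, {hi:.3g}])"
            )


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated study."""

    ad_thinner: np.ndarray
    ad_thicker: np.ndarray
    monotone: np.ndarray
    severity: pd.Series   # latent s per subject, 0 = CN basin, 1 = AD basin
    cohorts: pd.Series    # subject -> cohort
    config: SimulationConfig

    @property
    def planted(self) -> np.ndarray:
        return np.concatenate([self.ad_thinner, self.ad_thicker, self.monotone])

    def severity_per_image(self, metadata: pd.DataFrame) -> pd.Series:
        s = metadata.set_index("image_id")["subject_id"].map(self.severity)
        s.name = "latent_severity"
        return s

    def to_dict(self) -> dict:
        return {
            "ad_thinner": self.ad_thinner.tolist(),
            "ad_thicker": self.ad_thicker.tolist(),
            "monotone": self.monotone.tolist(),
            "severity": self.severity.to_dict(),
            "cohorts": self.cohorts.to_dict(),
        }


def _latent_severity(rng: np.random.Generator, cohort: str, n: int, severity_mode: bool) -> np.ndarray:
    if not severity_mode:
        return np.full(n, {"CN": 0.0, "MCI": 0.5, "AD": 1.0}[cohort])
    if cohort == "CN":
        return rng.uniform(0.0, 0.1, n)
    if cohort == "AD":
        return rng.uniform(0.9, 1.0, n)
    return rng.uniform(0.0, 1.0, n)  # MCI spans the whole CN-AD range


def simulate_cohort_study(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (thickness matrix, image metadata, truth), deterministically per seed."""
    rng = np.random.default_rng(config.seed)
    nv = config.n_vertices
    vertex_ids = np.array([f"v{i:05d}" for i in range(nv)])

    baseline = np.clip(rng.normal(config.baseline_mean, config.baseline_sd, nv), *_BASELINE_CLIP)

    perm = rng.permutation(nv)
    i0, i1 = config.n_ad_thinner, config.n_ad_thinner + config.n_ad_thicker
    i2 = i1 + config.n_monotone
    thin_ix, thick_ix, mono_ix = perm[:i0], perm[i0:i1], perm[i1:i2]

    # signed per-vertex effect at the AD end, in units of effect_mm;
    # monotone vertices descend two steps CN -> MCI -> AD
    direction = np.zeros(nv)
    direction[thin_ix] = -1.0
    direction[thick_ix] = +1.0
    direction[mono_ix] = -2.0
    is_mono = np.zeros(nv, dtype=bool)
    is_mono[mono_ix] = True

    cohorts, subjects, sev = [], [], []
    for k in ("CN", "MCI", "AD"):
        n = config.subjects_per_cohort
        ids = [f"{k}{j:03d}" for j in range(n)]
        subjects += ids
        cohorts += [k] * n
        sev.append(_latent_severity(rng, k, n, config.severity_mode))
    severity = pd.Series(np.concatenate(sev), index=subjects, name="latent_severity")
    cohort_s = pd.Series(cohorts, index=subjects, name="cohort")

    offsets = np.clip(
        rng.normal(0.0, config.offset_sd, len(subjects)),
        -_OFFSET_CLIP_SD * config.offset_sd, _OFFSET_CLIP_SD * config.offset_sd,
    )

    columns, meta_rows = [], []
    data = np.empty((nv, len(subjects) * config.images_per_subject))
    col = 0
    for si, sid in enumerate(subjects):
        k = cohort_s[sid]
        if config.severity_mode:
            effect = severity[sid] * config.effect_mm * direction
        else:
            effect = np.zeros(nv)
            if k == "AD":
                effect = config.effect_mm * direction
            elif k == "MCI":
                # MCI sits one step down the monotone-descending vertices only
                effect = np.where(is_mono, -config.effect_mm, 0.0)
        base = baseline + offsets[si] + effect
        for j in range(config.images_per_subject):
            acq = ACQUISITIONS[j % len(ACQUISITIONS)] if config.images_per_subject <= len(ACQUISITIONS) else f"ACQ{j}"
            noise = np.clip(
                rng.normal(0.0, config.noise_sd, nv),
                -_NOISE_CLIP_SD * config.noise_sd, _NOISE_CLIP_SD * config.noise_sd,
            )
            data[:, col] = base + noise
            image_id = f"{sid}_{acq}"
            columns.append(image_id)
            meta_rows.append(
                {
                    "image_id": image_id,
                    "subject_id": sid,
                    "cohort": k,
                    "sex": rng.choice(["F", "M"]),
                    "age": float(np.round(rng.normal(74.0, 6.0), 1)),
                    "acquisition_label": acq,
                }
            )
            col += 1

    matrix = pd.DataFrame(data, index=pd.Index(vertex_ids, name="vertex_id"), columns=columns)
    metadata = pd.DataFrame(meta_rows)
    truth = SyntheticTruth(
        ad_thinner=np.sort(vertex_ids[thin_ix]),
        ad_thicker=np.sort(vertex_ids[thick_ix]),
        monotone=np.sort(vertex_ids[mono_ix]),
        severity=severity,
        cohorts=cohort_s,
        config=config,
    )
    return matrix, metadata, truth


#: Documented study conditions used by the test-suite and acceptance runs.
PRESETS: dict[str, dict] = {
    # strong planted effects (standardised effect ~2 against the vertex noise)
    "separated": dict(),
    # same layout, half the effect: cohorts overlap substantially
    "overlapping": dict(effect_mm=0.1),
    # no planted signal at all: type-I error / permutation-null checks
    "null": dict(n_ad_thinner=0, n_ad_thicker=0, n_monotone=0, effect_mm=0.0),
    # latent severity drives planted thinning/thickening linearly; balanced
    # directions keep the severity axis orthogonal to the global offset
    "severity-gradient": dict(
        subjects_per_cohort=25, n_ad_thinner=120, n_ad_thicker=120, n_monotone=0,
        severity_mode=True,
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A named, documented simulation configuration."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)
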