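"""Analysis and pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .score import DEFAULT_CAP, KERNEL_MODES, BinningSpec, KernelSpec, kernel_weights
from .roi import DEFAULT_ESSENTIAL_CUTOFF, DEFAULT_ROI_CUTOFF


@dataclass
class AnalysisConfig:
    """Everything needed to fit the classifier from a thickness matrix.

    Grouping: ``quantile`` mode derives ``n_groups`` equal-count windows
    after trimming ``trim_fraction`` of extreme means; ``explicit`` mode
    takes ``boundaries`` (descending interior boundaries, mm) and
    ``trim`` = (lower, upper) verbatim.  ROI: ``roi_cutoff`` on |Z| for
    the broad ROI set, ``essential_cutoffs`` (scalar or per-pair mapping)
    for the essential set, combined across pairs by ``essential_combine``.
    """

    n_groups: int = 4
    grouping_mode: str = "quantile"
    boundaries: tuple | None = None
    trim: tuple | None = None
    trim_fraction: float = 0.004
    roi_cutoff: float = DEFAULT_ROI_CUTOFF
    essential_cutoffs: object = DEFAULT_ESSENTIAL_CUTOFF
    essential_combine: str = "union"
    delta: float = 0.2
    m_max: int = 30
    kernel: str = "integer-ratio"
    cap: float = DEFAULT_CAP
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_MODES:
            raise ValidationError(f"unknown kernel {self.kernel!r}; choose from {KERNEL_MODES}")
        if self.grouping_mode not in ("quantile", "explicit"):
            raise ValidationError(f"unknown grouping mode {self.grouping_mode!r}")
        self.binning()  # validates delta * m_max

    def binning(self) -> BinningSpec:
        return BinningSpec(delta=self.delta, m_max=self.m_max)

    def kernel_spec(self) -> KernelSpec:
        return kernel_weights(self.kernel)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("boundaries", "trim"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("boundaries", "trim"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end run: input source, analysis parameters, validation, seed."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    preset: str | None = None           # simulate this preset instead of reading files
    thickness_path: str | None = None
    metadata_path: str | None = None
    orientation: str = "vertices"
    cv_k: int = 3
    cv_unit: str = "subject"
    run_cv: bool = True
    run_svd: bool = True
    svd_k: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.analysis, dict):
            self.analysis = AnalysisConfig.from_dict(self.analysis)
        if self.preset is None and (self.thickness_path is None or self.metadata_path is None):
            raise ValidationError("config needs either a simulation preset or thickness + metadata paths")
        if self.cv_unit not in ("subject", "image"):
            raise ValidationError(f"cv_unit must be 'subject' or 'image', got {self.cv_unit!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis"] = self.analysis.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
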