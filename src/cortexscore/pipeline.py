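"""End-to-end orchestration: simulate/load -> group -> ROI -> train ->
classify -> severity -> diagnostics -> reports, with a run manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from ._version import __version__
from .config import PipelineConfig
from .errors import CortexScoreError, DataError
from .roi import roi_table
from .score import classify_images, save_model
from .severity import reorder_by_severity, severity_by_group
from .simulate import preset, simulate_cohort_study
from .svd import combined_score_matrix, segment_cosines, svd_modes
from .thickness import (
    COHORTS,
    check_pairing,
    drop_incomplete_vertices,
    load_metadata,
    load_thickness_table,
    write_metadata,
    write_thickness_table,
)
from .train import fit_pipeline
from .validation import cross_validate, self_recognition

log = logging.getLogger(__name__)


class _Stage:
    """Context manager labelling failures with the pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, CortexScoreError):
            exc.args = (f"stage '{self.name}': {exc.args[0] if exc.args else exc}",)
        return False


def load_inputs(config: PipelineConfig):
    """Simulate a preset or read thickness + metadata files."""
    if config.preset is not None:
        matrix, metadata, truth = simulate_cohort_study(preset(config.preset, seed=config.seed))
        return matrix, metadata, truth
    matrix = load_thickness_table(config.thickness_path, orientation=config.orientation)
    matrix = drop_incomplete_vertices(matrix)
    metadata = load_metadata(config.metadata_path)
    check_pairing(matrix, metadata)
    return matrix, metadata, None


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, str]:
    """Execute the full flow and write every artifact under ``outdir``.

    Returns a mapping from artifact name to file path.  Every run writes
    a ``manifest.json`` capturing the full configuration, seed and
    package version, from which the run can be regenerated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> Path:
        artifacts[name] = str(path)
        return path

    with _Stage("load"):
        matrix, metadata, truth = load_inputs(config)
        if config.preset is not None:
            write_thickness_table(matrix, emit("thickness", outdir / "thickness.tsv"))
            write_metadata(metadata, emit("metadata", outdir / "metadata.tsv"))
            (emit("truth", outdir / "truth.json")).write_text(json.dumps(truth.to_dict(), indent=2))

    with _Stage("fit"):
        fitted = fit_pipeline(matrix, metadata, config.analysis)
        fitted.assignment.rename_axis("image_id").to_csv(emit("groups", outdir / "groups.tsv"), sep="\t")
        for label, profs in fitted.zprofiles.items():
            roi_table(profs, fitted.roi[label], fitted.essential[label],
                      cutoff=config.analysis.roi_cutoff).to_csv(
                emit(f"roi_{label}", outdir / f"roi_{label}.tsv"), sep="\t")
        save_model(fitted.model, emit("model", outdir / "model"))

    with _Stage("classify"):
        predictions = classify_images(fitted.model, matrix)
        predictions.to_csv(emit("predictions", outdir / "predictions.tsv"), sep="\t")
        report = self_recognition(fitted.model, matrix, metadata)
        (emit("self_recognition", outdir / "self_recognition.json")).write_text(
            json.dumps(report.to_dict(), indent=2))

    with _Stage("severity"):
        table, per_group = severity_by_group(
            matrix, metadata, fitted.assignment, fitted.essential,
            include_self=config.analysis.include_self,
            predicted=predictions["predicted"],
        )
        table.to_csv(emit("severity", outdir / "severity.tsv"), sep="\t")
        for label, (C, _model) in per_group.items():
            C.values.to_csv(emit(f"C_{label}", outdir / f"C_{label}.tsv"), sep="\t")
            order, _ = reorder_by_severity(C, table)
            pd.Series(order, name="image_id").to_csv(
                emit(f"C_{label}_order", outdir / f"C_{label}_order.tsv"), sep="\t", index_label="rank")

    if config.run_svd:
        with _Stage("svd"):
            rows = []
            for label, gm in fitted.model.groups.items():
                s_all = combined_score_matrix(*(gm.S[k] for k in COHORTS))
                modes = svd_modes(s_all, k=min(config.svd_k, min(s_all.shape)))
                cos = segment_cosines(modes)
                cos.insert(0, "group", label)
                rows.append(cos)
            pd.concat(rows).to_csv(emit("svd", outdir / "svd_modes.tsv"), sep="\t")

    if config.run_cv:
        with _Stage("crossval"):
            cv = cross_validate(matrix, metadata, config.analysis,
                                k=config.cv_k, unit=config.cv_unit, seed=config.seed)
            payload = {
                "pooled": cv.pooled.to_dict(),
                "per_fold": [r.to_dict() for r in cv.per_fold],
                "k": cv.plan.k, "unit": cv.plan.unit, "seed": cv.plan.seed,
            }
            (emit("crossval", outdir / "crossval.json")).write_text(json.dumps(payload, indent=2))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_vertices": int(matrix.shape[0]),
        "n_images": int(matrix.shape[1]),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
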