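"""Pipeline orchestration: synthesize (or load contours) -> reconstruct ->
plan -> simulate -> analyze -> report, with every artifact carrying the
config hash and master seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import build_cohort, emit_contour_stack
from .config import RunConfig
from .contours import read_contour_stack, write_contour_stack
from .engine import error_sweep, run_cohort
from .metrics import compare_strategies, summarize
from .reconstruct import (
    ShrinkageFactor,
    align_slices,
    correct_shrinkage,
    interpolate_shape,
    lesion_inventory,
)

log = logging.getLogger("biopsim")

__all__ = ["run_pipeline", "ReconstructedProstate"]


@dataclass(frozen=True)
class _VoxelLesion:
    """Minimal lesion record for voxel-backed models."""

    id: str
    volume_ml: float
    gleason: str = "<=6"
    is_index: bool = False
    is_false_target: bool = False


@dataclass(frozen=True)
class ReconstructedProstate:
    """A prostate model backed by a reconstructed voxel volume.

    Anatomy references (urethra line, anus point) are estimated from the
    gland mask extents; lesion Gleason grades come from contour-stack
    metadata when present, otherwise they default to <=6 with a warning at
    load time.
    """

    model_id: str
    voxel: object
    lesions: tuple[_VoxelLesion, ...]
    urethra_xy: tuple[float, float] = (0.0, 0.0)
    anus_reference: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def true_lesions(self):
        return tuple(l for l in self.lesions if not l.is_false_target)

    @property
    def is_benign_target_model(self) -> bool:
        return len(self.lesions) > 0 and len(self.true_lesions) == 0

    @property
    def false_target_ids(self) -> frozenset:
        return frozenset(l.id for l in self.lesions if l.is_false_target)


def reconstruct_model(stack, model_id: str, config: RunConfig) -> ReconstructedProstate:
    """Contour stack -> aligned, interpolated, shrinkage-corrected model."""
    aligned = align_slices(stack)
    voxel = interpolate_shape(aligned, spacing=config.voxel_spacing_mm)
    voxel = correct_shrinkage(voxel, ShrinkageFactor(config.shrinkage_factor))
    inv = lesion_inventory(voxel)
    lesions = []
    for _, row in inv.iterrows():
        meta = stack.metadata.get(row["lesion_id"], {})
        lesions.append(
            _VoxelLesion(
                id=row["lesion_id"],
                volume_ml=float(row["volume_ml"]),
                gleason=meta.get("gleason", "<=6"),
                is_index=bool(row["is_index"]),
            )
        )
    idx = np.argwhere(voxel.gland_mask)
    world = voxel.origin + voxel.spacing * idx[:, ::-1]
    center = 0.5 * (world.min(axis=0) + world.max(axis=0))
    semi = 0.5 * (world.max(axis=0) - world.min(axis=0))
    anus = center + np.array([0.0, -(semi[1] + 30.0), -(semi[2] + 30.0)])
    return ReconstructedProstate(
        model_id=model_id,
        voxel=voxel,
        lesions=tuple(lesions),
        urethra_xy=(float(center[0]), float(center[1] - 0.10 * semi[1])),
        anus_reference=anus,
    )


def _cohort_manifest(cohort, config: RunConfig) -> pd.DataFrame:
    from .metrics import case_is_significant

    rows = []
    for m in cohort:
        index = next((l for l in m.lesions if l.is_index), None)
        rows.append(
            {
                "model_id": m.model_id,
                "gland_volume_ml": getattr(m, "gland_volume_ml",
                                           getattr(getattr(m, "voxel", None),
                                                   "gland_volume_ml", np.nan)),
                "n_lesions": len(m.lesions),
                "n_true_lesions": len(m.true_lesions),
                "index_volume_ml": index.volume_ml if index else np.nan,
                "index_gleason": index.gleason if index else "",
                "benign_target": m.is_benign_target_model,
                "significant": (
                    case_is_significant(m, config.significance)
                    if not m.is_benign_target_model
                    else False
                ),
            }
        )
    return pd.DataFrame(rows)


def synthesize_cohort(config: RunConfig):
    return build_cohort(config.cohort)


def load_contour_cohort(config: RunConfig):
    paths = sorted(Path(config.contour_dir).glob("*.txt"))
    if not paths:
        raise FileNotFoundError(f"no contour stacks (*.txt) in {config.contour_dir}")
    return [
        reconstruct_model(read_contour_stack(p), p.stem, config) for p in paths
    ]


def run_pipeline(config: RunConfig, resume: bool = True) -> dict:
    """Execute the full pipeline; returns a dict of artifact paths.

    With ``resume=True`` a stage whose output already exists under the same
    config hash is skipped.  Stage failures are re-raised annotated with the
    stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "run_manifest.json"
    artifacts = {"run_manifest": str(manifest_path)}

    def _stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _fresh(path: Path) -> bool:
        if not (resume and path.exists() and manifest_path.exists()):
            return False
        try:
            return json.loads(manifest_path.read_text())["config_hash"] == chash
        except (ValueError, KeyError):
            return False

    config.to_yaml(out / "config.yaml")
    artifacts["config"] = str(out / "config.yaml")

    if config.contour_dir:
        cohort = _stage("reconstruct", lambda: load_contour_cohort(config))
    else:
        cohort = _stage("synthesize", lambda: synthesize_cohort(config))
    manifest = _cohort_manifest(cohort, config)
    manifest.to_csv(out / "cohort_manifest.csv", index=False)
    artifacts["cohort_manifest"] = str(out / "cohort_manifest.csv")

    results_path = out / "results.csv"
    if _fresh(results_path):
        results = pd.read_csv(results_path)
    else:
        results = _stage(
            "simulate",
            lambda: run_cohort(
                cohort,
                config.strategies,
                config.error,
                config.reps,
                config.seed,
                effective_length=config.effective_length_mm,
                target_threshold=config.target_threshold_ml,
                positivity_threshold=config.positivity_threshold_mm,
            ),
        )
        results.to_csv(results_path, index=False)
    artifacts["results"] = str(results_path)

    summary = _stage(
        "analyze",
        lambda: summarize(
            results, cohort, config.risk, config.significance,
            aggregation=config.aggregation,
        ),
    )
    summary.table.to_csv(out / "summary.csv", index=False)
    summary.sensitivities.to_csv(out / "sensitivity.csv", index=False)
    artifacts["summary"] = str(out / "summary.csv")
    artifacts["sensitivity"] = str(out / "sensitivity.csv")

    comparisons = {}
    strategies = list(config.strategies)
    base = strategies[0] if strategies else None
    for other in strategies[1:]:
        a = results[results["strategy"] == base]
        b = results[results["strategy"] == other]
        if len(a) and len(b):
            try:
                comparisons[f"{base}_vs_{other}"] = compare_strategies(a, b)
            except ValueError as exc:
                comparisons[f"{base}_vs_{other}"] = {"error": str(exc)}
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
    artifacts["comparisons"] = str(out / "comparisons.json")

    if config.sweep_errors_mm:
        sweep = _stage(
            "sweep",
            lambda: error_sweep(
                cohort, config.strategies, config.sweep_errors_mm,
                config.reps, config.seed, em=config.error,
                effective_length=config.effective_length_mm,
                target_threshold=config.target_threshold_ml,
                positivity_threshold=config.positivity_threshold_mm,
            ),
        )
        sweep.to_csv(out / "sweep.csv", index=False)
        artifacts["sweep"] = str(out / "sweep.csv")

    manifest_path.write_text(
        json.dumps(
            {
                "config_hash": chash,
                "seed": config.seed,
                "version": __version__,
                "n_models": len(cohort),
                "artifacts": artifacts,
            },
            indent=2,
        )
    )
    return artifacts


def export_contours(config: RunConfig, directory) -> list[str]:
    """Write the synthetic cohort out as contour-stack text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort = synthesize_cohort(config)
    paths = []
    for model in cohort:
        stack = emit_contour_stack(model, config.slice_thickness_mm)
        p = directory / f"{model.model_id}.txt"
        write_contour_stack(stack, p)
        paths.append(str(p))
    return paths
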