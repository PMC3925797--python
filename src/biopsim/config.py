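"""Run configuration: one flat, serialisable object drives the pipeline.

Every named constant of the study design lives here with its default —
target threshold 0.2 ml, significance 0.5 ml / Gleason >=7, risk thresholds
6 mm / 50%, false-positive rate 34%, 500 repetitions, 5 mm total targeting
error, 1.10 shrinkage, 5-mm slices — so no comparison ever depends on a
hidden default.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .cohort import CohortSpec
from .engine import ErrorModel
from .metrics import RiskCriteria, SignificanceCriteria

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    error: ErrorModel = field(default_factory=ErrorModel)
    strategies: tuple[str, ...] = ("TRUS12", "TARGETED_3", "TARGETED_4")
    reps: int = 500
    target_threshold_ml: float = 0.2
    significance: SignificanceCriteria = field(default_factory=SignificanceCriteria)
    risk: RiskCriteria = field(default_factory=RiskCriteria)
    shrinkage_factor: float = 1.10
    slice_thickness_mm: float = 5.0
    voxel_spacing_mm: float = 0.5
    effective_length_mm: float = 17.0
    positivity_threshold_mm: float = 0.0
    aggregation: str = "mean"
    sweep_errors_mm: tuple[float, ...] = ()
    seed: int = 0
    contour_dir: str | None = None
    output_dir: str = "runs/out"

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("gland_volume_range", "index_volume_range",
                        "nonindex_volume_range", "gland_axis_ratios",
                        "lesion_aspect_b", "lesion_aspect_c",
                        "lesion_count_range"):
                if key in c and isinstance(c[key], list):
                    c[key] = tuple(c[key])
            d["cohort"] = CohortSpec(**c)
        if "error" in d and isinstance(d["error"], dict):
            d["error"] = ErrorModel(**d["error"])
        if "significance" in d and isinstance(d["significance"], dict):
            d["significance"] = SignificanceCriteria(**d["significance"])
        if "risk" in d and isinstance(d["risk"], dict):
            d["risk"] = RiskCriteria(**d["risk"])
        for key in ("strategies", "sweep_errors_mm"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
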