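"""Pipeline configuration: one YAML document governs every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import (DARK_THRESHOLD, MIN_COMPONENT_AREA, MIN_MARKED_AREA,
                         RESIDUAL_TOLERANCE)
from .synthetic import NoiseModel

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the generate -> preprocess -> classify -> evaluate run.

    Every field has a working default; the config round-trips losslessly
    through YAML.
    """

    # template overrides
    canvas_height: int = 1200
    canvas_width: int = 900
    line_width: int = 3
    # cohort
    n_eds: int = 60
    n_gbs: int = 32
    seed: int = 0
    label_a: str = "EDS"
    label_b: str = "GBS"
    prob_overrides_a: dict[str, float] = field(default_factory=dict)
    prob_overrides_b: dict[str, float] = field(default_factory=dict)
    # noise model
    shift_range: float = 10.0
    rotation_range: float = 3.0
    speckle_density: float = 0.0005
    stroke_jitter: int = 1
    # preprocessing
    threshold: int = DARK_THRESHOLD
    min_component_area: int = MIN_COMPONENT_AREA
    min_marked_area: int = MIN_MARKED_AREA
    residual_tolerance: float = RESIDUAL_TOLERANCE
    clip_to_body: bool = False
    # classification / evaluation
    cutoff: float = 0.5
    positive_label: str = "EDS"
    n_boot: int = 2000
    ci_level: float = 0.95
    # output
    outdir: str = "paindraw_out"

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            shift_range=self.shift_range,
            rotation_range=self.rotation_range,
            speckle_density=self.speckle_density,
            stroke_jitter=self.stroke_jitter,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
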