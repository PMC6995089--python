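"""Flat, typed pipeline configuration with YAML round-trip.

Every knob of the measurement and reporting pipeline lives here with a
documented default; unknown keys in a config file are errors so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline.

    mirror_plane_mode: "auto" derives the reflection plane from the
    landmarks (through subnasale, normal along the outer-eye axis);
    "explicit" uses ``mirror_plane_point`` / ``mirror_plane_normal``.
    The choice does not affect the metrics (plane-independence holds);
    it only orients intermediate meshes.
    """

    mirror_plane_mode: str = "auto"  # auto | explicit
    mirror_plane_point: list = field(default_factory=lambda: [0.0, 0.0, 0.0])
    mirror_plane_normal: list = field(default_factory=lambda: [1.0, 0.0, 0.0])
    r_chin_mm: float = 15.0  # chin-overlay sphere radius around pogonion
    flip_boundary_normal: bool = False  # flips the lower-face boundary side
    chin_threshold_mm: float = 4.0  # binarization cutoff for the chin score
    roc_thresholds_mm: list = field(
        default_factory=lambda: [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    )
    mw_exact_max_n: int = 20  # combined-n cutoff for exact Mann-Whitney
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> "PipelineConfig":
        if self.mirror_plane_mode not in ("auto", "explicit"):
            raise ValidationError(
                f"mirror_plane_mode must be 'auto' or 'explicit', "
                f"got {self.mirror_plane_mode!r}"
            )
        if self.r_chin_mm <= 0:
            raise ValidationError("r_chin_mm must be positive")
        if self.chin_threshold_mm <= 0:
            raise ValidationError("chin_threshold_mm must be positive")
        if len(self.roc_thresholds_mm) == 0:
            raise ValidationError("roc_thresholds_mm must be non-empty")
        return self

    def mirror_plane(self):
        """(point, normal) for explicit mode, (None, None) for auto."""
        if self.mirror_plane_mode == "explicit":
            return self.mirror_plane_point, self.mirror_plane_normal
        return None, None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(
                "unknown config key(s): " + ", ".join(sorted(unknown))
            )
        return cls(**data).validate()

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
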