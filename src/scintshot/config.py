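"""Analysis configuration, loadable from a YAML/JSON mapping."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .calibration import MM_PER_INCH, CameraModel
from .errors import BadInputError

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """All tunables of the star-shot pipeline with their defaults.

    ``pixel_pitch_mm`` is the camera operating scale; give ``dpi`` instead
    for scanned film (pitch = 25.4/dpi).  ``gantry_angles_deg`` enables the
    orientation sanity check of extracted star-lines; leave ``None`` to
    accept any orientations.
    """

    pixel_pitch_mm: float | None = 0.16
    dpi: float | None = None
    camera: CameraModel | None = None
    gantry_angles_deg: tuple[float, ...] | None = None
    ring_radius_frac: float = 0.35
    pair_tolerance_deg: float = 10.0
    min_intersection_angle_deg: float = 5.0
    orientation_tolerance_deg: float = 3.0
    sample_interval_px: int = 100
    profile_phase: str | int = "centered"
    contrast_factor: float = 3.0
    ball_min_radius_px: float = 3.0
    ball_max_radius_px: float = 60.0
    report_y_up: bool = True
    line_distance_variant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dpi is not None:
            if not self.dpi > 0:
                raise BadInputError("dpi must be positive")
            self.pixel_pitch_mm = MM_PER_INCH / self.dpi
        if self.pixel_pitch_mm is None or not self.pixel_pitch_mm > 0:
            raise BadInputError("pixel_pitch_mm (or dpi) must be positive")
        if not 0 < self.ring_radius_frac < 0.5:
            raise BadInputError("ring_radius_frac must be in (0, 0.5)")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        cam = d.pop("camera", None)
        if isinstance(cam, dict):
            cam = CameraModel.from_dict(cam)
        angles = d.pop("gantry_angles_deg", None)
        if angles is not None:
            angles = tuple(float(a) for a in angles)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise BadInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(camera=cam, gantry_angles_deg=angles, **d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["camera"] = self.camera.to_dict() if self.camera else None
        if self.gantry_angles_deg is not None:
            d["gantry_angles_deg"] = list(self.gantry_angles_deg)
        return d

    def without_camera(self) -> "AnalysisConfig":
        d = self.to_dict()
        d["camera"] = None
        return AnalysisConfig.from_dict(d)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML (or JSON) file."""
    path = Path(path)
    if not path.exists():
        raise BadInputError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise BadInputError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise BadInputError(f"config {path} must be a mapping")
    return AnalysisConfig.from_dict(data)
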