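"""Synthetic scintillator-phantom renderer with known ground truth.

Renders the three image types the analysis pipeline consumes — beam frames
(one Gaussian-profile scintillation stripe per gantry angle), a steel-ball
image (dark disk on a bright ambient field), and a room-laser image (two
perpendicular bright strips on a dark background) — from a single
:class:`PhantomSpec` that fixes every geometric quantity.  Because the truth
is known exactly, every downstream detector and the full star-shot pipeline
can be validated without a treatment machine.

Orientation convention: a beam at gantry angle θ renders as a stripe along
the raster direction ``(cos θ, sin θ)`` (x right, y down), so θ = 0 is
horizontal and θ = 90 vertical; angles 180° apart give the same line.  The
signed per-angle offset displaces the stripe along the left normal
``(−sin θ, cos θ)``.

All renderers are deterministic: the same spec and seed give bit-identical
images.  Noise is additive Gaussian applied before clipping to the bit
depth; optional salt-and-pepper flecks emulate stray sensor hits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .calibration import CameraModel, undistort_points
from .errors import BadInputError, GeometryError
from .image import GrayImage, write_image

__all__ = [
    "PhantomSpec",
    "render_beam_frame",
    "render_ball_image",
    "render_laser_image",
    "write_phantom_set",
]

# independent noise streams per image type
_STREAM_BALL = 1
_STREAM_LASER = 2
_STREAM_BEAM0 = 100


@dataclass
class PhantomSpec:
    """Complete geometric description of one synthetic measurement session.

    Millimetre coordinates use the raster frame (origin at the top-left
    pixel center, y down); ``pixel_pitch_mm`` converts to pixels.

    Attributes
    ----------
    gantry_angles_deg
        One beam per entry; reduced mod 180 they must be pairwise distinct
        or two stripes would coincide.
    beam_sigma_mm
        Gaussian sigma of the stripe's perpendicular intensity profile.
        Default 2 mm, a typical proton-spot scale on a scintillator sheet.
    beam_offsets_mm
        Signed perpendicular displacement of each stripe from
        ``true_isocenter_mm``; all-zero means perfectly concurrent beams.
    laser_width_px
        Rendered full width of each laser strip, 8-10 px (the 1-1.5 mm a
        room laser projects at this camera scale).
    noise_sigma
        Additive Gaussian sensor noise in intensity units (pre-clipping).
    distortion
        Optional lens model; when set, rendered images are geometrically
        distorted exactly as a real lens would, i.e. the scene appears at
        ``distort(ideal)`` pixel positions.
    """

    image_width_px: int = 960
    image_height_px: int = 960
    pixel_pitch_mm: float = 0.16
    true_isocenter_mm: tuple[float, float] = (76.8, 76.8)
    gantry_angles_deg: tuple[float, ...] = (240.0, 300.0, 0.0, 30.0, 90.0, 150.0)
    beam_sigma_mm: float = 2.0
    beam_offsets_mm: tuple[float, ...] | None = None
    ball_center_mm: tuple[float, float] = (76.8, 76.8)
    ball_radius_mm: float = 1.0
    laser_center_mm: tuple[float, float] = (76.8, 76.8)
    laser_width_px: float = 9.0
    laser_angle_deg: float = 0.0
    psf_sigma_px: float = 0.7
    noise_sigma: float = 0.0
    salt_pepper_fraction: float = 0.0
    beam_mask_radius_mm: float | None = None
    distortion: CameraModel | None = None
    bit_depth: int = 8
    rng_seed: int = 0
    # rendering intensity levels (8-bit scale; scaled x257 for 16-bit)
    beam_peak: float = 200.0
    beam_background: float = 6.0
    ambient_level: float = 180.0
    ball_level: float = 25.0
    laser_peak: float = 210.0
    laser_background: float = 10.0

    def __post_init__(self) -> None:
        if self.image_width_px < 64 or self.image_height_px < 64:
            raise BadInputError("image dimensions must be at least 64 px")
        if not self.pixel_pitch_mm > 0:
            raise BadInputError("pixel_pitch_mm must be positive")
        if not self.beam_sigma_mm > 0:
            raise BadInputError("beam_sigma_mm must be positive")
        if self.noise_sigma < 0:
            raise BadInputError("noise_sigma must be nonnegative")
        if not 8.0 <= self.laser_width_px <= 10.0:
            raise BadInputError("laser_width_px must lie in [8, 10]")
        if self.bit_depth not in (8, 16):
            raise BadInputError("bit_depth must be 8 or 16")
        geom = (*self.true_isocenter_mm, *self.ball_center_mm,
                *self.laser_center_mm, self.ball_radius_mm,
                *self.gantry_angles_deg)
        if not np.all(np.isfinite(geom)):
            raise BadInputError("all geometric fields must be finite")
        reduced = np.sort(np.asarray(self.gantry_angles_deg, float) % 180.0)
        if len(reduced) > 1 and np.min(np.diff(np.concatenate(
                [reduced, [reduced[0] + 180.0]]))) < 1e-9:
            raise BadInputError(
                "gantry angles reduced mod 180 must be pairwise distinct")
        if self.beam_offsets_mm is None:
            self.beam_offsets_mm = tuple(0.0 for _ in self.gantry_angles_deg)
        if len(self.beam_offsets_mm) != len(self.gantry_angles_deg):
            raise BadInputError("beam_offsets_mm must match gantry_angles_deg")

    # --- derived quantities ------------------------------------------------

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def intensity_scale(self) -> float:
        """Multiplier from the 8-bit level fields to the target bit depth."""
        return 1.0 if self.bit_depth == 8 else 257.0

    def mm_to_px(self, p_mm) -> np.ndarray:
        return np.asarray(p_mm, dtype=float) / self.pixel_pitch_mm

    def beam_line_mm(self, angle_index: int):
        """(point_mm, unit direction, unit normal) of one true beam line."""
        theta = np.deg2rad(self.gantry_angles_deg[angle_index])
        u = np.array([np.cos(theta), np.sin(theta)])
        n = np.array([-np.sin(theta), np.cos(theta)])
        p0 = np.asarray(self.true_isocenter_mm) + self.beam_offsets_mm[angle_index] * n
        return p0, u, n

    def truth(self) -> dict:
        """Ground-truth sidecar content, px and mm."""
        pitch = self.pixel_pitch_mm
        iso = list(self.true_isocenter_mm)
        return {
            "pixel_pitch_mm": pitch,
            "true_isocenter_mm": iso,
            "true_isocenter_px": [c / pitch for c in iso],
            "gantry_angles_deg": list(self.gantry_angles_deg),
            "beam_offsets_mm": list(self.beam_offsets_mm),
            "ball_center_mm": list(self.ball_center_mm),
            "ball_center_px": [c / pitch for c in self.ball_center_mm],
            "ball_radius_mm": self.ball_radius_mm,
            "laser_center_mm": list(self.laser_center_mm),
            "laser_center_px": [c / pitch for c in self.laser_center_mm],
            "laser_width_px": self.laser_width_px,
            "rng_seed": self.rng_seed,
        }


def _pixel_grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(x_mm, y_mm) coordinate arrays of every pixel center, rectified.

    With a distortion model set, a raw pixel at (u, v) images the scene
    point that an ideal camera would see at ``undistort((u, v))``; we
    therefore evaluate the scene at the undistorted coordinates.
    """
    ys, xs = np.mgrid[0:spec.image_height_px, 0:spec.image_width_px].astype(float)
    if spec.distortion is not None and not spec.distortion.is_identity:
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        rect = undistort_points(spec.distortion, pts)
        xs = rect[:, 0].reshape(xs.shape)
        ys = rect[:, 1].reshape(ys.shape)
    return xs * spec.pixel_pitch_mm, ys * spec.pixel_pitch_mm


def _finalize(spec: PhantomSpec, field_img: np.ndarray, stream: int) -> GrayImage:
    """Add seeded noise, clip to bit depth, quantize."""
    rng = np.random.default_rng([spec.rng_seed & 0x7FFFFFFF, stream])
    img = field_img * spec.intensity_scale
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma * spec.intensity_scale,
                               size=img.shape)
    if spec.salt_pepper_fraction > 0:
        n_flecks = int(round(spec.salt_pepper_fraction * img.size))
        idx = rng.choice(img.size, size=n_flecks, replace=False)
        vals = rng.integers(0, 2, size=n_flecks)
        img.ravel()[idx] = vals * (2 ** spec.bit_depth - 1)
    top = 2 ** spec.bit_depth - 1
    img = np.clip(np.rint(img), 0, top)
    return GrayImage(img.astype(spec.dtype), pixel_pitch_mm=spec.pixel_pitch_mm)


def render_beam_frame(spec: PhantomSpec, angle_index: int) -> GrayImage:
    """Render the scintillation stripe of one gantry angle.

    The stripe's intensity perpendicular to its axis is Gaussian with
    ``beam_sigma_mm``, centered on the line through ``true_isocenter_mm``
    displaced by the per-angle offset.  The stripe spans the field of view
    (optionally masked to ``beam_mask_radius_mm`` about the isocenter).
    """
    if not 0 <= angle_index < len(spec.gantry_angles_deg):
        raise IndexError(
            f"angle_index {angle_index} out of range for "
            f"{len(spec.gantry_angles_deg)} gantry angles")
    x_mm, y_mm = _pixel_grid_mm(spec)
    p0, _, n = spec.beam_line_mm(angle_index)
    d_perp = (x_mm - p0[0]) * n[0] + (y_mm - p0[1]) * n[1]
    img = spec.beam_background + (spec.beam_peak - spec.beam_background) * np.exp(
        -0.5 * (d_perp / spec.beam_sigma_mm) ** 2)
    if spec.beam_mask_radius_mm is not None:
        iso = spec.true_isocenter_mm
        rr = np.hypot(x_mm - iso[0], y_mm - iso[1])
        img = np.where(rr <= spec.beam_mask_radius_mm, img, spec.beam_background)
    return _finalize(spec, img, _STREAM_BEAM0 + angle_index)


def render_ball_image(spec: PhantomSpec) -> GrayImage:
    """Render the steel ball: dark anti-aliased disk on a bright field.

    Edge anti-aliasing uses linear pixel-coverage ramping over one pixel,
    which keeps the disk's intensity-weighted centroid at the true center
    to well under a tenth of a pixel.
    """
    if spec.ball_radius_mm < 2.0 * spec.pixel_pitch_mm:
        raise GeometryError(
            "ball_radius_mm must be at least 2 pixels for reliable rendering")
    r_px = spec.ball_radius_mm / spec.pixel_pitch_mm
    cx, cy = spec.mm_to_px(spec.ball_center_mm)
    if not (r_px <= cx <= spec.image_width_px - 1 - r_px
            and r_px <= cy <= spec.image_height_px - 1 - r_px):
        raise GeometryError("ball extends outside the image bounds")
    x_mm, y_mm = _pixel_grid_mm(spec)
    dist_px = np.hypot(x_mm - spec.ball_center_mm[0],
                       y_mm - spec.ball_center_mm[1]) / spec.pixel_pitch_mm
    coverage = np.clip(r_px + 0.5 - dist_px, 0.0, 1.0)  # 1 inside, 0 outside
    img = spec.ambient_level + (spec.ball_level - spec.ambient_level) * coverage
    return _finalize(spec, img, _STREAM_BALL)


def _strip_response(dist_px: np.ndarray, width_px: float,
                    psf_sigma_px: float) -> np.ndarray:
    """Normalized intensity of a top-hat strip seen through a Gaussian
    camera PSF: erf-softened edges, FWHM exactly ``width_px`` (for widths
    well above the PSF scale the half-maximum sits at +-width/2)."""
    if psf_sigma_px <= 0:
        return np.clip(width_px / 2.0 + 0.5 - dist_px, 0.0, 1.0)
    s = psf_sigma_px * np.sqrt(2.0)
    half = width_px / 2.0
    return 0.5 * (erf((dist_px + half) / s) - erf((dist_px - half) / s))


def render_laser_image(spec: PhantomSpec) -> GrayImage:
    """Render the room-laser cross: two perpendicular bright strips.

    Strip full width is ``laser_width_px``; the pair crosses at
    ``laser_center_mm``, rotated by ``laser_angle_deg`` about it, with
    edges softened by the camera PSF (``psf_sigma_px``).  The background
    is dark (lasers are captured with the room lights off).
    """
    cx, cy = spec.mm_to_px(spec.laser_center_mm)
    if not (0 <= cx <= spec.image_width_px - 1 and 0 <= cy <= spec.image_height_px - 1):
        raise GeometryError("laser center outside the image bounds")
    x_mm, y_mm = _pixel_grid_mm(spec)
    dx = (x_mm - spec.laser_center_mm[0]) / spec.pixel_pitch_mm
    dy = (y_mm - spec.laser_center_mm[1]) / spec.pixel_pitch_mm
    a = np.deg2rad(spec.laser_angle_deg)
    # distances to the two strip axes (rotated x- and y-aligned lines)
    d1 = np.abs(-np.sin(a) * dx + np.cos(a) * dy)   # near-horizontal strip
    d2 = np.abs(np.cos(a) * dx + np.sin(a) * dy)    # near-vertical strip
    cov = np.maximum(_strip_response(d1, spec.laser_width_px, spec.psf_sigma_px),
                     _strip_response(d2, spec.laser_width_px, spec.psf_sigma_px))
    img = spec.laser_background + (spec.laser_peak - spec.laser_background) * cov
    return _finalize(spec, img, _STREAM_LASER)


def write_phantom_set(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Render and write the full set: ball, laser, one frame per angle.

    8-bit specs write PNG, 16-bit specs write TIFF, plus a ``truth.json``
    sidecar with the ground truth in px and mm.  Returns the truth dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".png" if spec.bit_depth == 8 else ".tiff"
    write_image(render_ball_image(spec), out / f"ball{ext}")
    write_image(render_laser_image(spec), out / f"laser{ext}")
    frames = []
    for i, ang in enumerate(spec.gantry_angles_deg):
        name = f"beam_{i:02d}_g{int(round(ang)) % 360:03d}{ext}"
        write_image(render_beam_frame(spec, i), out / name)
        frames.append(name)
    truth = spec.truth()
    truth["frames"] = frames
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
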