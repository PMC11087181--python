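"""Star-shot analysis: frame merging, star-line extraction, minimum circle.

A star-shot is produced by irradiating narrow beams at several gantry
angles into a plane parallel to the beam axis; each beam leaves a bright
line on the scintillator and all lines should nearly concur.  The analysis

1. merges the per-angle frames by per-pixel maximum into one composite,
2. samples the composite's intensity along a ring about a tentative
   center, locates each beam crossing as the sub-pixel midpoint of its
   angular FWHM, pairs diametrically opposite crossings into star-lines,
3. intersects every line pair and takes the minimum enclosing circle of
   the intersection points: its center is the radiation isocenter, its
   radius the beam-axis wobble.

Step 2 runs twice: the ring is re-centered once on the preliminary minimum
circle, which removes the (second-order) asymmetry a mis-centered ring
induces in the angular profiles.

An alternative isocenter definition — the point minimizing the maximum
distance to the star-*lines* rather than enclosing their intersection
points — is available behind a flag and reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates
from scipy.optimize import linprog
from scipy.signal import find_peaks

from .calibration import CameraModel, undistort_points
from .config import AnalysisConfig
from .errors import (BadInputError, ExtractionError, GeometryError,
                     InsufficientDataError)
from .geometry import (CircleResult, Line2D, angle_between_deg,
                       intersect_lines, min_enclosing_circle)
from .image import GrayImage

__all__ = [
    "StarShotImage",
    "StarLine",
    "StarShotResult",
    "merge_frames",
    "extract_star_lines",
    "pairwise_intersections",
    "analyze_starshot",
    "line_distance_isocenter",
]


@dataclass(frozen=True)
class StarShotImage:
    """Composite star-shot image: per-pixel maximum of the source frames."""

    image: GrayImage
    source_angles_deg: tuple[float, ...] = ()


@dataclass(frozen=True)
class StarLine:
    """One fitted beam axis in mm raster coordinates."""

    line: Line2D
    gantry_angle_deg: float
    peak_pair_quality: float


@dataclass(frozen=True)
class StarShotResult:
    """Full output of one star-shot analysis (mm raster frame)."""

    circle: CircleResult
    lines: tuple[StarLine, ...]
    intersections_mm: tuple[tuple[float, float], ...]
    pixel_pitch_mm: float
    tentative_center_px: tuple[float, float]
    line_distance_center_mm: tuple[float, float] | None = None
    line_distance_radius_mm: float | None = None

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.circle.center_mm[0] / self.pixel_pitch_mm,
                self.circle.center_mm[1] / self.pixel_pitch_mm)


def merge_frames(frames, source_angles_deg=()) -> StarShotImage:
    """Merge >= 2 single-beam frames into one composite by per-pixel max.

    The maximum (rather than the sum) is idempotent and saturation-safe:
    merging a frame with itself, or with an all-zero frame, is the
    identity, and frame order is irrelevant.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise BadInputError("merge_frames requires at least 2 frames")
    shape = frames[0].shape
    pitch = frames[0].pixel_pitch_mm
    for f in frames[1:]:
        if f.shape != shape:
            raise BadInputError(f"frame shape mismatch: {f.shape} vs {shape}")
        if abs(f.pixel_pitch_mm - pitch) > 1e-12:
            raise BadInputError("frame pixel pitch mismatch")
    stack = np.stack([f.data for f in frames])
    return StarShotImage(
        image=GrayImage(stack.max(axis=0), pixel_pitch_mm=pitch),
        source_angles_deg=tuple(float(a) for a in source_angles_deg),
    )


# --- ring-profile machinery -------------------------------------------------


def _ring_profile(img: np.ndarray, center_px, radius_px: float,
                  samples_per_px: float = 2.0, band_half_width_px: float = 3.0,
                  smooth_sigma_samples: float = 2.0):
    """Intensity profile along a circle; returns (profile, angles_deg).

    The profile is averaged over a narrow radial band (the stripe-crossing
    angle is radius-independent to first order, so the average is unbiased)
    and lightly smoothed with a circular Gaussian.  Both operations are
    symmetric about each peak and leave the FWHM midpoints in place while
    suppressing sensor noise.
    """
    n = max(int(round(2.0 * np.pi * radius_px * samples_per_px)), 360)
    ang = np.arange(n) * (360.0 / n)
    rad = np.deg2rad(ang)
    radii = radius_px + np.arange(-band_half_width_px, band_half_width_px + 0.5)
    cols = center_px[0] + radii[:, None] * np.cos(rad)[None, :]
    rows = center_px[1] + radii[:, None] * np.sin(rad)[None, :]
    prof = map_coordinates(img, np.stack([rows.ravel(), cols.ravel()]),
                           order=1, mode="nearest").reshape(len(radii), n)
    prof = prof.mean(axis=0)
    if smooth_sigma_samples > 0:
        prof = gaussian_filter1d(prof, smooth_sigma_samples, mode="wrap")
    return prof, ang


def _circular_fwhm_midpoints(profile: np.ndarray, min_separation_deg: float = 8.0):
    """Angular FWHM midpoints of every beam crossing on the ring.

    The profile is rolled so its global minimum sits at index 0, making all
    peaks interior; peaks are detected with a prominence floor of a quarter
    of the global span above the median background, then each peak's
    half-maximum crossings are located by linear interpolation and averaged.
    Returns midpoints in degrees of the *original* angular coordinate.
    """
    n = len(profile)
    step = 360.0 / n
    shift = int(np.argmin(profile))
    rolled = np.roll(profile, -shift)
    background = float(np.median(rolled))
    span = float(rolled.max()) - background
    if span <= 0:
        return np.array([])
    peaks, _ = find_peaks(
        rolled,
        height=background + 0.5 * span,
        prominence=0.25 * span,
        distance=max(int(min_separation_deg / step), 1),
    )
    mids = []
    from .fiducials import _half_crossing  # shared sub-pixel primitive
    for p in peaks:
        half = background + 0.5 * (rolled[p] - background)
        left = _half_crossing(rolled, p, -1, half)
        right = _half_crossing(rolled, p, +1, half)
        mids.append(((0.5 * (left + right) + shift) * step) % 360.0)
    return np.sort(np.asarray(mids))


def _pair_opposite(mid_deg: np.ndarray, tol_deg: float):
    """Greedily pair angles nearest to 180 deg apart.

    Candidate pairs are ordered by their mismatch from 180 deg (ties broken
    by angle), and accepted while both members are unused.  Any leftover
    peak means the composite is not a clean star pattern.
    """
    m = len(mid_deg)
    cand = []
    for i, j in itertools.combinations(range(m), 2):
        mism = abs(((mid_deg[j] - mid_deg[i]) % 360.0) - 180.0)
        if mism <= tol_deg:
            cand.append((mism, mid_deg[i], i, j))
    cand.sort()
    used = set()
    pairs = []
    for mism, _, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((i, j, mism))
    leftover = m - 2 * len(pairs)
    if leftover:
        raise ExtractionError(
            f"{leftover} of {m} ring peaks have no diametric partner within "
            f"{tol_deg} deg")
    return pairs


def _lines_from_ring(img, center_px, radius_px, pair_tol_deg, camera):
    """One extraction pass: ring profile → paired peaks → pixel lines."""
    prof, _ = _ring_profile(img, center_px, radius_px)
    mids = _circular_fwhm_midpoints(prof)
    pairs = _pair_opposite(mids, pair_tol_deg)
    lines = []
    for i, j, mism in pairs:
        rad = np.deg2rad([mids[i], mids[j]])
        pts = np.stack([center_px[0] + radius_px * np.cos(rad),
                        center_px[1] + radius_px * np.sin(rad)], axis=1)
        if camera is not None and not camera.is_identity:
            pts = undistort_points(camera, pts)
        quality = max(1.0 - mism / max(pair_tol_deg, 1e-9), 1e-6)
        lines.append((Line2D.through(pts[0], pts[1]), quality))
    return lines


def extract_star_lines(star: StarShotImage, tentative_center_px,
                       ring_radius_frac: float = 0.35,
                       pair_tolerance_deg: float = 10.0,
                       nominal_angles_deg=None,
                       orientation_tolerance_deg: float = 3.0,
                       camera: CameraModel | None = None) -> list[StarLine]:
    """Extract one :class:`StarLine` per beam from the composite image.

    Samples a ring of radius ``ring_radius_frac * min(image dims)`` about
    the tentative center, pairs opposite FWHM midpoints into lines, then
    repeats once with the ring re-centered on the preliminary minimum
    circle.  With ``nominal_angles_deg`` given, each fitted line must match
    a distinct nominal gantry orientation (mod 180) within
    ``orientation_tolerance_deg`` and is tagged with it; otherwise lines
    are tagged with their measured orientation.

    Coordinates are rectified through ``camera`` (when given) before line
    fitting; the returned lines are in mm.
    """
    img = star.image.as_float()
    h, w = img.shape
    cx, cy = float(tentative_center_px[0]), float(tentative_center_px[1])
    if not (0 <= cx < w and 0 <= cy < h):
        raise BadInputError("tentative center outside the image")
    radius_px = ring_radius_frac * min(h, w)
    if (cx - radius_px < 0 or cx + radius_px > w - 1
            or cy - radius_px < 0 or cy + radius_px > h - 1):
        raise BadInputError("sampling ring does not fit in the image")

    center = (cx, cy)
    pairs = _lines_from_ring(img, center, radius_px, pair_tolerance_deg, camera)
    if len(pairs) >= 3:
        # re-center once on the preliminary minimum circle and re-extract
        try:
            pts = _intersect_all([ln for ln, _ in pairs], 5.0)
            prelim = min_enclosing_circle(pts)
            new_center = (float(prelim.center_mm[0]), float(prelim.center_mm[1]))
            if (radius_px <= new_center[0] <= w - 1 - radius_px
                    and radius_px <= new_center[1] <= h - 1 - radius_px):
                pairs = _lines_from_ring(img, new_center, radius_px,
                                         pair_tolerance_deg, camera)
        except GeometryError:
            pass
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} star-lines found; >= 3 beams are required")

    pitch = star.image.pixel_pitch_mm
    nominals = list(star.source_angles_deg) if nominal_angles_deg is None \
        else list(nominal_angles_deg)
    out = []
    taken = set()
    for line_px, quality in pairs:
        line_mm = line_px.scaled(pitch)
        if nominals:
            diffs = [min(abs(line_mm.angle_deg - a % 180.0),
                         180.0 - abs(line_mm.angle_deg - a % 180.0))
                     for a in nominals]
            k = int(np.argmin(diffs))
            if diffs[k] > orientation_tolerance_deg:
                raise ExtractionError(
                    f"fitted line at {line_mm.angle_deg:.2f} deg is "
                    f"{diffs[k]:.2f} deg from the nearest nominal gantry "
                    f"angle (tolerance {orientation_tolerance_deg} deg)")
            if k in taken:
                raise ExtractionError(
                    f"two fitted lines match gantry angle {nominals[k]} deg")
            taken.add(k)
            tag = float(nominals[k])
        else:
            tag = line_mm.angle_deg
        out.append(StarLine(line=line_mm, gantry_angle_deg=tag,
                            peak_pair_quality=quality))
    out.sort(key=lambda s: s.line.angle_deg)
    return out


def _intersect_all(lines, min_angle_deg):
    pts = []
    for a, b in itertools.combinations(lines, 2):
        if angle_between_deg(a, b) >= min_angle_deg:
            pts.append(intersect_lines(a, b))
    if not pts:
        raise GeometryError("all line pairs are below the mutual-angle cutoff")
    return np.asarray(pts)


def pairwise_intersections(lines, min_angle_deg: float = 5.0) -> np.ndarray:
    """Intersection points of every line pair meeting the angle cutoff.

    With n mutually non-parallel lines this yields n(n-1)/2 points — 15 for
    the standard six-beam star-shot.  Near-parallel pairs (below
    ``min_angle_deg``) are skipped because their intersection is numerically
    meaningless.
    """
    ls = [s.line if isinstance(s, StarLine) else s for s in lines]
    if len(ls) < 3:
        raise InsufficientDataError("need >= 3 star-lines to intersect")
    return _intersect_all(ls, min_angle_deg)


def line_distance_isocenter(lines) -> tuple[np.ndarray, float]:
    """Chebyshev center of the star-lines: minimizes the maximum
    point-to-line distance (linear program).  Alternative isocenter
    definition to the intersection-point minimum circle."""
    ls = [s.line if isinstance(s, StarLine) else s for s in lines]
    if len(ls) < 3:
        raise InsufficientDataError("need >= 3 star-lines")
    # min t  s.t.  ±(n_i . p − n_i . q_i) <= t
    a_ub, b_ub = [], []
    for ln in ls:
        nx, ny = ln.normal
        off = nx * ln.point[0] + ny * ln.point[1]
        a_ub.append([nx, ny, -1.0]);  b_ub.append(off)
        a_ub.append([-nx, -ny, -1.0]); b_ub.append(-off)
    res = linprog(c=[0.0, 0.0, 1.0], A_ub=a_ub, b_ub=b_ub,
                  bounds=[(None, None), (None, None), (0, None)],
                  method="highs")
    if not res.success:
        raise GeometryError(f"line-distance isocenter LP failed: {res.message}")
    return np.asarray(res.x[:2]), float(res.x[2])


def _tentative_center(img: np.ndarray) -> tuple[float, float]:
    """Brightness centroid above background: a robust starting center."""
    w = np.clip(img - np.median(img), 0.0, None)
    total = w.sum()
    if total <= 0:
        return ((img.shape[1] - 1) / 2.0, (img.shape[0] - 1) / 2.0)
    ys, xs = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    return (float((w * xs).sum() / total), float((w * ys).sum() / total))


def _stage(name):
    """Decorator-free stage tagging: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception) \
                    and not str(exc).startswith("["):
                exc.args = (f"[{name}] {exc}",) + exc.args[1:]
            return False
    return _Ctx()


def analyze_starshot(frames_or_merged, config: AnalysisConfig | None = None,
                     tentative_center_px=None) -> StarShotResult:
    """Run the full star-shot pipeline on beam frames or a composite.

    Accepts a list of per-angle :class:`GrayImage` frames (merged here), a
    single composite :class:`GrayImage`, or a ready :class:`StarShotImage`.
    Coordinates are rectified through ``config.camera`` when provided.
    Errors are tagged with the pipeline stage that raised them.
    """
    cfg = config or AnalysisConfig()
    with _stage("merge"):
        if isinstance(frames_or_merged, StarShotImage):
            star = frames_or_merged
        elif isinstance(frames_or_merged, GrayImage):
            star = StarShotImage(image=frames_or_merged,
                                 source_angles_deg=tuple(cfg.gantry_angles_deg or ()))
        else:
            star = merge_frames(frames_or_merged,
                                source_angles_deg=tuple(cfg.gantry_angles_deg or ()))
    if abs(star.image.pixel_pitch_mm - cfg.pixel_pitch_mm) > 1e-12:
        star = StarShotImage(
            image=GrayImage(star.image.data, pixel_pitch_mm=cfg.pixel_pitch_mm),
            source_angles_deg=star.source_angles_deg)
    img = star.image.as_float()
    if tentative_center_px is None:
        tentative_center_px = _tentative_center(img)
    with _stage("extract"):
        lines = extract_star_lines(
            star, tentative_center_px,
            ring_radius_frac=cfg.ring_radius_frac,
            pair_tolerance_deg=cfg.pair_tolerance_deg,
            nominal_angles_deg=cfg.gantry_angles_deg,
            orientation_tolerance_deg=cfg.orientation_tolerance_deg,
            camera=cfg.camera)
    with _stage("intersect"):
        pts = pairwise_intersections(lines, cfg.min_intersection_angle_deg)
    with _stage("min_circle"):
        circle = min_enclosing_circle(pts)
    ld_center = ld_radius = None
    if cfg.line_distance_variant:
        with _stage("line_distance"):
            c, r = line_distance_isocenter(lines)
            ld_center, ld_radius = (float(c[0]), float(c[1])), r
    return StarShotResult(
        circle=circle,
        lines=tuple(lines),
        intersections_mm=tuple((float(x), float(y)) for x, y in pts),
        pixel_pitch_mm=cfg.pixel_pitch_mm,
        tentative_center_px=(float(tentative_center_px[0]),
                             float(tentative_center_px[1])),
        line_distance_center_mm=ld_center,
        line_distance_radius_mm=ld_radius,
    )
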