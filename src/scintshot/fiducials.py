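"""Locating the imaging isocenter (steel ball) and the laser marker.

The imaging isocenter is materialized by a small steel ball aligned to the
machine's kV imaging system; in the optical image it appears as a dark disk
on the ambient-lit scintillator.  Detection thresholds with Otsu's method,
keeps the most circular dark contour whose equivalent radius is plausible,
and returns its intensity-weighted (darkness-weighted) centroid — on
symmetric renders this coincides with the geometric center and under noise
it has lower variance.

The laser marker is the cross of the two room-laser strips, each 1-1.5 mm
(8-10 px) wide.  Strips are reduced to lines by sampling intensity profiles
every ``sample_interval_px``, locating each strip's sub-pixel center as the
midpoint of its two half-maximum crossings (FWHM midpoint — the same
primitive the star-line analysis uses), fitting a total-least-squares line
through the centers, and intersecting the two lines.  Samples falling near
the cross itself, where the strips overlap and the profile is ambiguous,
are excluded before the final fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import (AmbiguityError, BadInputError, DetectionError,
                     GeometryError, LowContrastError)
from .geometry import Line2D, angle_between_deg, intersect_lines
from .image import GrayImage

__all__ = [
    "BallDetection",
    "LaserDetection",
    "detect_ball",
    "profile_strip_center",
    "detect_laser_cross",
]


@dataclass(frozen=True)
class BallDetection:
    """Steel-ball detection result (raw pixel coordinates)."""

    center_px: tuple[float, float]
    radius_px: float
    contour_area_px2: float


@dataclass(frozen=True)
class LaserDetection:
    """Laser-cross detection: the marker and the two fitted laser lines.

    ``line_y`` is the y-directional (near-vertical) laser line obtained from
    horizontal profiles; ``line_x`` the near-horizontal one from vertical
    profiles.  ``marker_px`` is their intersection.
    """

    marker_px: tuple[float, float]
    line_x: Line2D
    line_y: Line2D
    strip_centers_px: tuple[tuple[float, float], ...]


def detect_ball(image: GrayImage, min_radius_px: float,
                max_radius_px: float) -> BallDetection:
    """Find the steel ball as the most circular dark contour.

    Otsu-thresholds the grayscale image, labels the dark regions, keeps
    candidates whose equivalent radius ``sqrt(area/pi)`` lies within
    ``[min_radius_px, max_radius_px]``, and selects the one maximizing the
    circularity score ``4*pi*A / P**2``.  Two candidates within 1% of each
    other's circularity raise :class:`AmbiguityError`.  The reported center
    is the darkness-weighted centroid, which is invariant to global linear
    intensity rescaling of the image.
    """
    if not (0 < min_radius_px < max_radius_px):
        raise BadInputError("need 0 < min_radius_px < max_radius_px")
    img = image.as_float()
    if img.size == 0:
        raise BadInputError("empty image")
    if np.ptp(img) == 0:
        raise DetectionError("no ball found: image is uniform")
    # Otsu operates on a lightly smoothed copy: the ball occupies a tiny
    # fraction of the frame, and without smoothing sensor noise dominates
    # the histogram and pulls the threshold inside the background mode.
    smoothed = gaussian_filter(img, 2.0)
    thr = threshold_otsu(smoothed)
    dark = smoothed < thr
    labels = label(dark)
    candidates = []
    for region in regionprops(labels):
        r_eq = np.sqrt(region.area / np.pi)
        if not (min_radius_px <= r_eq <= max_radius_px):
            continue
        perim = region.perimeter
        if perim <= 0:
            continue
        circ = min(4.0 * np.pi * region.area / perim ** 2, 1.0)
        candidates.append((circ, r_eq, region))
    if not candidates:
        raise DetectionError("no ball found: no circular dark contour in "
                             f"radius range [{min_radius_px}, {max_radius_px}] px")
    candidates.sort(key=lambda c: -c[0])
    if len(candidates) > 1 and candidates[0][0] - candidates[1][0] < 0.01 * candidates[0][0]:
        raise AmbiguityError("two equally circular ball candidates")
    circ, r_eq, region = candidates[0]

    # darkness-weighted centroid over the region (padded by 2 px so the
    # anti-aliased rim contributes); weights (background - I) make the
    # estimate affine-gain invariant and unbiased under zero-mean noise.
    background = float(np.median(img[~dark])) if np.any(~dark) else float(img.max())
    minr, minc, maxr, maxc = region.bbox
    minr, minc = max(minr - 2, 0), max(minc - 2, 0)
    maxr, maxc = min(maxr + 2, img.shape[0]), min(maxc + 2, img.shape[1])
    patch = img[minr:maxr, minc:maxc]
    w = np.clip(background - patch, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise DetectionError("no ball found: zero darkness weight")
    ys, xs = np.mgrid[minr:maxr, minc:maxc]
    cx = float((w * xs).sum() / total)
    cy = float((w * ys).sum() / total)
    return BallDetection(center_px=(cx, cy), radius_px=float(r_eq),
                         contour_area_px2=float(region.area))


def _half_crossing(profile: np.ndarray, start: int, step: int, half: float) -> float:
    """Fractional index of the first crossing below ``half`` walking from
    ``start`` in direction ``step`` (+1/-1), by linear interpolation."""
    i = start
    n = len(profile)
    while 0 <= i + step < n and profile[i + step] > half:
        i += step
    j = i + step
    if not 0 <= j < n:  # ran off the end: treat the edge as the crossing
        return float(i)
    a, b = profile[i], profile[j]
    frac = (a - half) / (a - b) if a != b else 0.5
    return float(i + step * frac)


def profile_strip_center(profile, contrast_factor: float = 3.0,
                         return_width: bool = False):
    """Sub-pixel center of the single dominant bright strip in a profile.

    Background is the profile median; the center is the midpoint of the two
    half-maximum crossings found by linear interpolation walking outward
    from the global peak.  A peak below ``contrast_factor`` times the
    background raises :class:`LowContrastError`.
    """
    prof = np.asarray(profile, dtype=float).ravel()
    if prof.size < 5:
        raise BadInputError("profile must have at least 5 samples")
    background = float(np.median(prof))
    peak_idx = int(np.argmax(prof))
    peak = float(prof[peak_idx])
    if peak < contrast_factor * max(background, 1e-9):
        raise LowContrastError(
            f"peak {peak:.3g} below {contrast_factor}x background {background:.3g}")
    half = background + 0.5 * (peak - background)
    left = _half_crossing(prof, peak_idx, -1, half)
    right = _half_crossing(prof, peak_idx, +1, half)
    center = 0.5 * (left + right)
    if return_width:
        return center, right - left
    return center


def _fit_tls_line(points: np.ndarray) -> Line2D:
    """Total-least-squares line through >= 2 points (principal direction)."""
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
    return Line2D(point=tuple(mean), direction=tuple(vt[0]))


def _strip_centers_along(img: np.ndarray, axis: int, interval: int, phase,
                         contrast_factor: float):
    """Sample profiles across ``axis`` and locate the strip in each.

    ``axis=0`` samples rows (horizontal profiles → near-vertical strip);
    ``axis=1`` samples columns.  Returns (points Nx2 in (x, y) px, widths).
    """
    extent = img.shape[axis]
    offset = interval // 2 if phase == "centered" else int(phase)
    positions = np.arange(offset, extent, interval)
    pts, widths = [], []
    for pos in positions:
        prof = img[pos, :] if axis == 0 else img[:, pos]
        try:
            c, w = profile_strip_center(prof, contrast_factor=contrast_factor,
                                        return_width=True)
        except LowContrastError:
            continue
        pts.append((c, float(pos)) if axis == 0 else (float(pos), c))
        widths.append(w)
    return np.asarray(pts, dtype=float).reshape(-1, 2), np.asarray(widths)


def detect_laser_cross(image: GrayImage, sample_interval_px: int = 100,
                       phase="centered", contrast_factor: float = 3.0,
                       min_cross_angle_deg: float = 45.0) -> LaserDetection:
    """Locate the laser cross by profile sampling and line fitting.

    Horizontal profiles every ``sample_interval_px`` rows give the centers
    of the near-vertical strip (→ ``line_y``); vertical profiles give the
    near-horizontal strip (→ ``line_x``).  After a preliminary fit, samples
    within two strip-widths of the preliminary intersection — where the two
    strips overlap — are discarded and each line refitted once.  The final
    marker is the intersection of the refitted lines.
    """
    img = image.as_float()
    if min(img.shape) < 3 * sample_interval_px:
        raise BadInputError(
            f"image must span >= 3 sample intervals ({3 * sample_interval_px} px)")
    pts_v, w_v = _strip_centers_along(img, 0, sample_interval_px, phase, contrast_factor)
    pts_h, w_h = _strip_centers_along(img, 1, sample_interval_px, phase, contrast_factor)
    # a profile grazing a near-parallel strip yields a far-too-wide "strip";
    # the laser has a well-defined width, so such samples are discarded
    if len(w_v) and len(w_h):
        width_med = float(np.median(np.concatenate([w_v, w_h])))
        ok_v = w_v <= 2.0 * width_med
        ok_h = w_h <= 2.0 * width_med
        pts_v, w_v = pts_v[ok_v], w_v[ok_v]
        pts_h, w_h = pts_h[ok_h], w_h[ok_h]
    if len(pts_v) < 3 or len(pts_h) < 3:
        raise DetectionError(
            f"laser cross not found: {len(pts_v)} vertical-strip and "
            f"{len(pts_h)} horizontal-strip centers (need >= 3 each)")
    line_y = _fit_tls_line(pts_v)
    line_x = _fit_tls_line(pts_h)
    if angle_between_deg(line_x, line_y) < min_cross_angle_deg:
        raise GeometryError("fitted laser lines are not perpendicular enough "
                            "for a cross")
    marker = intersect_lines(line_x, line_y)

    # exclude the ambiguous overlap region around the cross, refit once
    width = float(np.median(np.concatenate([w_v, w_h])))
    keep_v = np.hypot(*(pts_v - marker).T) > 2.0 * width
    keep_h = np.hypot(*(pts_h - marker).T) > 2.0 * width
    if keep_v.sum() >= 3 and keep_h.sum() >= 3:
        line_y = _fit_tls_line(pts_v[keep_v])
        line_x = _fit_tls_line(pts_h[keep_h])
        marker = intersect_lines(line_x, line_y)
        pts_used = np.vstack([pts_v[keep_v], pts_h[keep_h]])
    else:
        pts_used = np.vstack([pts_v, pts_h])
    return LaserDetection(
        marker_px=(float(marker[0]), float(marker[1])),
        line_x=line_x, line_y=line_y,
        strip_centers_px=tuple(map(tuple, pts_used)),
    )
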