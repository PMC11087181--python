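"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the minimum-circle
oracle enumerates every candidate circle (O(n^4)), stripe centers are
located by nonlinear Gaussian fits, and true star-line geometry is built
analytically from the phantom spec.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import curve_fit


def brute_force_min_circle(points, tol: float = 1e-9):
    """Smallest circle over all diameter-pair and triple circumcircles.

    Exhaustive O(n^4) enumeration; returns (center ndarray, radius).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 1:
        return pts[0].copy(), 0.0
    centers = []
    radii = []
    for i, j in itertools.combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2.0
        centers.append(c)
        radii.append(np.hypot(*(pts[i] - c)))
    for i, j, k in itertools.combinations(range(n), 3):
        (ax, ay), (bx, by), (cx, cy) = pts[i], pts[j], pts[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-14:
            continue
        a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
        ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
        uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
        centers.append(np.array([ux, uy]))
        radii.append(np.hypot(ax - ux, ay - uy))
    centers = np.asarray(centers)
    radii = np.asarray(radii)
    dists = np.hypot(centers[:, 0][:, None] - pts[None, :, 0],
                     centers[:, 1][:, None] - pts[None, :, 1])
    valid = np.all(dists <= radii[:, None] + tol, axis=1)
    best = np.flatnonzero(valid)[np.argmin(radii[valid])]
    return centers[best], float(radii[best])


def gaussian_fit_center(profile) -> float:
    """Sub-sample peak center by fitting A*exp(-(x-mu)^2/2s^2)+b."""
    y = np.asarray(profile, dtype=float)
    x = np.arange(len(y), dtype=float)
    b0 = float(np.median(y))
    mu0 = float(np.argmax(y))
    a0 = float(y.max() - b0)
    s0 = max(len(y) / 20.0, 2.0)
    popt, _ = curve_fit(
        lambda xx, a, mu, s, b: a * np.exp(-0.5 * ((xx - mu) / s) ** 2) + b,
        x, y, p0=[a0, mu0, s0, b0], maxfev=10000)
    return float(popt[1])


def true_star_lines(spec):
    """Analytic (point, direction) beam lines of a phantom spec, in mm."""
    lines = []
    for i in range(len(spec.gantry_angles_deg)):
        p0, u, _ = spec.beam_line_mm(i)
        lines.append((p0, u))
    return lines


def true_intersections(spec):
    """All pairwise intersection points of the analytic beam lines (mm)."""
    pts = []
    for (p1, u1), (p2, u2) in itertools.combinations(true_star_lines(spec), 2):
        mat = np.array([[u1[0], -u2[0]], [u1[1], -u2[1]]])
        t, _ = np.linalg.solve(mat, p2 - p1)
        pts.append(p1 + t * u1)
    return np.asarray(pts)


def mask_centroid(image_data, threshold=None, invert=True):
    """Intensity-weighted centroid of the (dark) region past a threshold."""
    img = np.asarray(image_data, dtype=float)
    if threshold is None:
        threshold = 0.5 * (img.min() + img.max())
    w = np.clip(threshold - img, 0, None) if invert else np.clip(img - threshold, 0, None)
    ys, xs = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    return np.array([(w * xs).sum() / w.sum(), (w * ys).sum() / w.sum()])
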