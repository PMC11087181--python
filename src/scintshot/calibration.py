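"""Lens-distortion correction and pixel-to-mm scale.

The camera model is the standard pinhole + Brown–Conrady distortion with two
radial (k1, k2) and two tangential (p1, p2) coefficients, acting on
normalized coordinates about the principal point:

    x' = x (1 + k1 r^2 + k2 r^4) + 2 p1 x y + p2 (r^2 + 2 x^2)
    y' = y (1 + k1 r^2 + k2 r^4) + p1 (r^2 + 2 y^2) + 2 p2 x y

Forward distortion is closed-form; undistortion inverts it by fixed-point
iteration to sub-1e-6-pixel residual.  Distortion is applied to *extracted
point coordinates*, never by resampling images, which keeps sub-pixel
centroids free of interpolation artifacts.

A model can be loaded from config (a ``camera:`` block) or fitted from
matched ideal/observed point pairs — e.g. checkerboard corners located by
any corner detector — via :func:`fit_distortion`; with all coefficients zero
the model is the identity on pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BadInputError, NumericalError

__all__ = [
    "CameraModel",
    "ScaleModel",
    "distort_points",
    "undistort_points",
    "fit_distortion",
    "scale_from_dpi",
    "scale_from_fiducial",
]

MM_PER_INCH = 25.4


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics + radial/tangential distortion coefficients."""

    focal_px: tuple[float, float] = (1.0, 1.0)
    principal_point_px: tuple[float, float] = (0.0, 0.0)
    radial_k1: float = 0.0
    radial_k2: float = 0.0
    tangential_p1: float = 0.0
    tangential_p2: float = 0.0

    def __post_init__(self) -> None:
        vals = (*self.focal_px, *self.principal_point_px, self.radial_k1,
                self.radial_k2, self.tangential_p1, self.tangential_p2)
        if not all(np.isfinite(vals)):
            raise BadInputError("camera model parameters must all be finite")
        if self.focal_px[0] == 0 or self.focal_px[1] == 0:
            raise BadInputError("focal lengths must be nonzero")

    @property
    def is_identity(self) -> bool:
        return (self.radial_k1 == self.radial_k2 == 0.0
                and self.tangential_p1 == self.tangential_p2 == 0.0)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            focal_px=(float(d.get("fx", 1.0)), float(d.get("fy", 1.0))),
            principal_point_px=(float(d.get("cx", 0.0)), float(d.get("cy", 0.0))),
            radial_k1=float(d.get("k1", 0.0)),
            radial_k2=float(d.get("k2", 0.0)),
            tangential_p1=float(d.get("p1", 0.0)),
            tangential_p2=float(d.get("p2", 0.0)),
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.focal_px[0], "fy": self.focal_px[1],
            "cx": self.principal_point_px[0], "cy": self.principal_point_px[1],
            "k1": self.radial_k1, "k2": self.radial_k2,
            "p1": self.tangential_p1, "p2": self.tangential_p2,
        }


@dataclass(frozen=True)
class ScaleModel:
    """Physical scale of the rectified image: mm per pixel."""

    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        if not self.pixel_pitch_mm > 0:
            raise BadInputError("pixel_pitch_mm must be positive")


def _normalize(model: CameraModel, pts: np.ndarray) -> np.ndarray:
    fx, fy = model.focal_px
    cx, cy = model.principal_point_px
    out = np.empty_like(pts)
    out[:, 0] = (pts[:, 0] - cx) / fx
    out[:, 1] = (pts[:, 1] - cy) / fy
    return out


def _denormalize(model: CameraModel, pts: np.ndarray) -> np.ndarray:
    fx, fy = model.focal_px
    cx, cy = model.principal_point_px
    out = np.empty_like(pts)
    out[:, 0] = pts[:, 0] * fx + cx
    out[:, 1] = pts[:, 1] * fy + cy
    return out


def _apply_distortion(model: CameraModel, xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + model.radial_k1 * r2 + model.radial_k2 * r2 * r2
    p1, p2 = model.tangential_p1, model.tangential_p2
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.stack([xd, yd], axis=1)


def distort_points(model: CameraModel, points_px) -> np.ndarray:
    """Map ideal (rectified) pixel coordinates to raw (distorted) ones."""
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    return _denormalize(model, _apply_distortion(model, _normalize(model, pts)))


def undistort_points(model: CameraModel, points_px, tol_px: float = 1e-6,
                     max_iter: int = 100) -> np.ndarray:
    """Map raw pixel coordinates to rectified ones (inverse distortion).

    Fixed-point iteration ``x <- x_d - (distort(x) - x)`` started at the raw
    coordinates; converges for physically small coefficients.  Raises
    :class:`NumericalError` if the residual is still above ``tol_px`` after
    ``max_iter`` iterations.
    """
    raw = np.atleast_2d(np.asarray(points_px, dtype=float))
    if model.is_identity:
        return raw.copy()
    xd = _normalize(model, raw)
    x = xd.copy()
    fmax = max(abs(model.focal_px[0]), abs(model.focal_px[1]))
    tol_n = tol_px / fmax
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_iter):
            err = _apply_distortion(model, x) - x  # distortion displacement at x
            x_new = xd - err
            if not np.all(np.isfinite(x_new)):
                raise NumericalError("undistortion diverged (non-physical model)")
            if np.max(np.abs(x_new - x)) < tol_n:
                x = x_new
                break
            x = x_new
        else:
            raise NumericalError(
                f"undistortion did not converge to {tol_px} px in {max_iter} iterations"
            )
    return _denormalize(model, x)


def fit_distortion(ideal_px, observed_px, focal_px, principal_point_px) -> CameraModel:
    """Least-squares fit of (k1, k2, p1, p2) from matched point pairs.

    ``ideal_px`` are the undistorted reference positions (e.g. a perfect
    checkerboard grid), ``observed_px`` the positions measured in the raw
    image.  The distortion equations are linear in the four coefficients, so
    the fit is a single ``lstsq`` solve.
    """
    ideal = np.atleast_2d(np.asarray(ideal_px, dtype=float))
    obs = np.atleast_2d(np.asarray(observed_px, dtype=float))
    if ideal.shape != obs.shape or len(ideal) < 4:
        raise BadInputError("need >= 4 matched point pairs of identical shape")
    base = CameraModel(focal_px=tuple(focal_px),
                       principal_point_px=tuple(principal_point_px))
    xy = _normalize(base, ideal)
    xy_obs = _normalize(base, obs)
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    # residual = A @ [k1, k2, p1, p2]
    ax = np.stack([x * r2, x * r2 * r2, 2 * x * y, r2 + 2 * x * x], axis=1)
    ay = np.stack([y * r2, y * r2 * r2, r2 + 2 * y * y, 2 * x * y], axis=1)
    a_mat = np.vstack([ax, ay])
    rhs = np.concatenate([xy_obs[:, 0] - x, xy_obs[:, 1] - y])
    coeffs, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    return CameraModel(
        focal_px=tuple(focal_px), principal_point_px=tuple(principal_point_px),
        radial_k1=float(coeffs[0]), radial_k2=float(coeffs[1]),
        tangential_p1=float(coeffs[2]), tangential_p2=float(coeffs[3]),
    )


def scale_from_dpi(dpi: float) -> ScaleModel:
    """Pixel pitch of a scanned image: 25.4 / dpi mm per pixel."""
    if not dpi > 0:
        raise BadInputError("dpi must be positive")
    return ScaleModel(pixel_pitch_mm=MM_PER_INCH / dpi)


def scale_from_fiducial(known_length_mm: float, endpoint_a_px, endpoint_b_px) -> ScaleModel:
    """Pixel pitch from a fiducial of known physical length in the image."""
    if not known_length_mm > 0:
        raise BadInputError("known_length_mm must be positive")
    a = np.asarray(endpoint_a_px, dtype=float)
    b = np.asarray(endpoint_b_px, dtype=float)
    dist = float(np.hypot(*(a - b)))
    if dist == 0:
        raise BadInputError("fiducial endpoints coincide")
    return ScaleModel(pixel_pitch_mm=known_length_mm / dist)
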