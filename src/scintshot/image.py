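"""The universal raster carrier.

A :class:`GrayImage` is a 2-D intensity grid plus the physical pixel pitch
(mm per pixel).  The coordinate convention shared by every module:

* pixel ``(0, 0)`` is the *center* of the top-left pixel;
* ``x`` grows rightward along columns, ``y`` grows downward along rows;
* millimetre coordinates are ``pixel * pixel_pitch_mm`` on the same axes.

The flip to report axes (y-up) happens only in :mod:`scintshot.report`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import BadInputError

__all__ = ["GrayImage", "read_image", "write_image"]


@dataclass
class GrayImage:
    """2-D grayscale image with physical scale.

    Parameters
    ----------
    data
        2-D array of intensities.  Stored as given; rendering produces
        uint8/uint16, analysis works in float64.
    pixel_pitch_mm
        Physical size of one pixel in millimetres.
    """

    data: np.ndarray
    pixel_pitch_mm: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # RGB(A) → luma
            self.data = self.data[..., :3].astype(np.float64).mean(axis=2)
        if self.data.ndim != 2:
            raise BadInputError(f"expected a 2-D image, got shape {self.data.shape}")
        if not self.pixel_pitch_mm > 0:
            raise BadInputError("pixel_pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def height(self) -> int:
        return int(self.data.shape[0])

    @property
    def width(self) -> int:
        return int(self.data.shape[1])

    def as_float(self) -> np.ndarray:
        return self.data.astype(np.float64, copy=False)

    def px_to_mm(self, points_px: np.ndarray) -> np.ndarray:
        """Scale (x, y) pixel coordinates to millimetres."""
        return np.asarray(points_px, dtype=float) * self.pixel_pitch_mm

    def mm_to_px(self, points_mm: np.ndarray) -> np.ndarray:
        return np.asarray(points_mm, dtype=float) / self.pixel_pitch_mm


def read_image(path: str | Path, pixel_pitch_mm: float = 1.0) -> GrayImage:
    """Read a PNG or TIFF file into a :class:`GrayImage`."""
    path = Path(path)
    if not path.exists():
        raise BadInputError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            data = tifffile.imread(path)
        else:
            data = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize I/O failures
        raise BadInputError(f"cannot read image {path}: {exc}") from exc
    return GrayImage(data, pixel_pitch_mm=pixel_pitch_mm)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write 8-bit data as PNG, 16-bit as TIFF (chosen by file suffix)."""
    path = Path(path)
    data = image.data
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        if data.dtype == np.uint16:
            iio.imwrite(path, data, extension=".png")
        else:
            iio.imwrite(path, data)
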