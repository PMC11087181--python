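"""Per-measurement deviations and multi-session summary statistics.

A measurement session yields, per day: the minimum-circle radius and the
signed deviation vectors of the radiation isocenter from the laser marker
and (for the camera system) from the imaging isocenter.  This module holds
the arithmetic over such records: per-axis means, the population SD of the
radii, per-record Euclidean norms with their mean and maximum, and the
calibrated-vs-uncalibrated comparison.

Axis convention: detections live in the raster frame (y down); report
vectors use y-up, so ``deviation`` negates the raster y difference.  All
statistics are kept at full precision internally and rounded half-away-
from-zero to 2 decimals only when rendered.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .errors import BadInputError, ParseError

__all__ = [
    "MeasurementRecord",
    "DeviationStats",
    "SessionSummary",
    "deviation",
    "summarize",
    "compare_calibration",
    "load_session_csv",
    "write_session_csv",
    "render_summary",
    "write_report",
    "round_half_away",
]

_CSV_COLUMNS = ["label", "radius_mm", "laser_dx_mm", "laser_dy_mm",
                "imaging_dx_mm", "imaging_dy_mm", "calibrated"]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (so 0.345 → 0.35, −0.345 → −0.35)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MeasurementRecord:
    """One star-shot measurement (one day, one detector, one calibration state)."""

    label: str
    min_circle_radius_mm: float
    dev_laser_mm: tuple[float, float]
    dev_imaging_mm: tuple[float, float] | None = None
    calibrated: bool = False

    def __post_init__(self) -> None:
        vals = [self.min_circle_radius_mm, *self.dev_laser_mm]
        if self.dev_imaging_mm is not None:
            vals += list(self.dev_imaging_mm)
        if not all(math.isfinite(v) for v in vals):
            raise BadInputError(f"record {self.label!r} has non-finite values")
        if self.min_circle_radius_mm < 0:
            raise BadInputError(f"record {self.label!r} has negative radius")


def deviation(radiation_iso_mm, reference_mm, flip_y: bool = True) -> tuple[float, float]:
    """Signed deviation vector radiation − reference, in report axes.

    Both points must be in the same rectified mm frame.  ``flip_y`` maps
    the raster y-down difference to the conventional y-up report axes.
    """
    r = np.asarray(radiation_iso_mm, dtype=float)
    q = np.asarray(reference_mm, dtype=float)
    d = r - q
    if flip_y:
        d = np.array([d[0], -d[1]])
    return (float(d[0]), float(d[1]))


@dataclass(frozen=True)
class DeviationStats:
    """Statistics of one deviation-vector column."""

    mean_mm: tuple[float, float]
    mean_magnitude_mm: float
    max_magnitude_mm: float
    n: int


@dataclass(frozen=True)
class SessionSummary:
    """Summary statistics over one set of measurement records."""

    n_records: int
    mean_radius_mm: float
    sd_radius_mm: float
    laser: DeviationStats
    imaging: DeviationStats | None


def _dev_stats(vectors) -> DeviationStats:
    v = np.asarray(vectors, dtype=float)
    norms = np.hypot(v[:, 0], v[:, 1])
    mean_vec = v.mean(axis=0)
    stats = DeviationStats(
        mean_mm=(float(mean_vec[0]), float(mean_vec[1])),
        mean_magnitude_mm=float(norms.mean()),
        max_magnitude_mm=float(norms.max()),
        n=len(v),
    )
    # triangle/Jensen sanity: ||mean|| <= mean of norms <= max of norms
    assert np.hypot(*stats.mean_mm) <= stats.mean_magnitude_mm + 1e-12
    assert stats.mean_magnitude_mm <= stats.max_magnitude_mm + 1e-12
    return stats


def summarize(records) -> SessionSummary:
    """Means, population SD, and per-record norm statistics.

    The radius SD uses the population divisor n.  Imaging statistics are
    computed over the records that carry an imaging deviation and omitted
    when none do.
    """
    records = list(records)
    if not records:
        raise BadInputError("summarize requires at least one record")
    radii = np.array([r.min_circle_radius_mm for r in records])
    laser = _dev_stats([r.dev_laser_mm for r in records])
    imaging_vecs = [r.dev_imaging_mm for r in records if r.dev_imaging_mm is not None]
    imaging = _dev_stats(imaging_vecs) if imaging_vecs else None
    return SessionSummary(
        n_records=len(records),
        mean_radius_mm=float(radii.mean()),
        sd_radius_mm=float(radii.std(ddof=0)),
        laser=laser,
        imaging=imaging,
    )


def compare_calibration(records) -> float:
    """Maximum absolute entrywise calibrated-vs-uncalibrated difference.

    Records are paired by label (each label must occur exactly once
    calibrated and once not); the maximum is over the radius and every
    deviation component of every pair.
    """
    by_label: dict[str, dict[bool, MeasurementRecord]] = {}
    for r in records:
        slot = by_label.setdefault(r.label, {})
        if r.calibrated in slot:
            raise BadInputError(
                f"duplicate {'calibrated' if r.calibrated else 'uncalibrated'} "
                f"record for label {r.label!r}")
        slot[r.calibrated] = r
    deltas = []
    for lab, slot in by_label.items():
        if set(slot) != {True, False}:
            raise BadInputError(f"label {lab!r} is not paired "
                                "(need one calibrated and one uncalibrated record)")
        a, b = slot[False], slot[True]
        deltas.append(abs(a.min_circle_radius_mm - b.min_circle_radius_mm))
        deltas += [abs(x - y) for x, y in zip(a.dev_laser_mm, b.dev_laser_mm)]
        if (a.dev_imaging_mm is None) != (b.dev_imaging_mm is None):
            raise BadInputError(f"label {lab!r}: imaging deviation present in "
                                "only one of the pair")
        if a.dev_imaging_mm is not None:
            deltas += [abs(x - y) for x, y in zip(a.dev_imaging_mm, b.dev_imaging_mm)]
    if not deltas:
        raise BadInputError("no paired records to compare")
    return float(max(deltas))


# --- I/O --------------------------------------------------------------------


def _parse_bool(s: str) -> bool:
    v = s.strip().lower()
    if v in {"1", "true", "yes", "y"}:
        return True
    if v in {"0", "false", "no", "n", ""}:
        return False
    raise ValueError(f"not a boolean: {s!r}")


def load_session_csv(path: str | Path) -> list[MeasurementRecord]:
    """Load measurement records from a session CSV.

    Columns: ``label, radius_mm, laser_dx_mm, laser_dy_mm, imaging_dx_mm,
    imaging_dy_mm, calibrated`` — the imaging columns (and ``calibrated``)
    may be absent or empty.  A malformed row raises :class:`ParseError`
    naming the row number.
    """
    path = Path(path)
    if not path.exists():
        raise BadInputError(f"session CSV not found: {path}")
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "label" not in reader.fieldnames:
            raise ParseError(f"{path}: missing header with a 'label' column")
        for rownum, row in enumerate(reader, start=2):
            try:
                dev_img = None
                ix = (row.get("imaging_dx_mm") or "").strip()
                iy = (row.get("imaging_dy_mm") or "").strip()
                if ix or iy:
                    dev_img = (float(ix), float(iy))
                records.append(MeasurementRecord(
                    label=row["label"].strip(),
                    min_circle_radius_mm=float(row["radius_mm"]),
                    dev_laser_mm=(float(row["laser_dx_mm"]),
                                  float(row["laser_dy_mm"])),
                    dev_imaging_mm=dev_img,
                    calibrated=_parse_bool(row.get("calibrated") or ""),
                ))
            except (KeyError, TypeError, ValueError, BadInputError) as exc:
                raise ParseError(f"{path} row {rownum}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no data rows")
    return records


def write_session_csv(records, path: str | Path) -> None:
    """Write records at full precision (round-trips through ``load``)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            img = r.dev_imaging_mm or ("", "")
            writer.writerow([
                r.label, repr(float(r.min_circle_radius_mm)),
                repr(float(r.dev_laser_mm[0])), repr(float(r.dev_laser_mm[1])),
                img[0] if img[0] == "" else repr(float(img[0])),
                img[1] if img[1] == "" else repr(float(img[1])),
                "true" if r.calibrated else "false",
            ])


def render_summary(summary: SessionSummary) -> dict:
    """Summary with every value rounded to 2 decimals for reporting.

    Formatting is locale-independent: plain decimal-point floats.
    """
    def r2(x):
        return round_half_away(x, 2)

    out = {
        "n_records": summary.n_records,
        "mean_radius_mm": r2(summary.mean_radius_mm),
        "sd_radius_mm": r2(summary.sd_radius_mm),
        "laser": {
            "mean_mm": [r2(summary.laser.mean_mm[0]), r2(summary.laser.mean_mm[1])],
            "mean_magnitude_mm": r2(summary.laser.mean_magnitude_mm),
            "max_magnitude_mm": r2(summary.laser.max_magnitude_mm),
        },
    }
    if summary.imaging is not None:
        out["imaging"] = {
            "mean_mm": [r2(summary.imaging.mean_mm[0]), r2(summary.imaging.mean_mm[1])],
            "mean_magnitude_mm": r2(summary.imaging.mean_magnitude_mm),
            "max_magnitude_mm": r2(summary.imaging.max_magnitude_mm),
        }
    return out


def write_report(path: str | Path, payload: dict) -> None:
    """Write an analysis/report payload as JSON (full precision)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False))
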