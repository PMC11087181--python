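"""Bundled example session data.

Two small CSV tables from a five-day proton-gantry isocenter-verification
campaign, one measured with the scintillator-camera system (with and
without camera calibration) and one with scanned radiochromic EBT3 film.
They serve as worked-example input for :mod:`scintshot.report` and as the
reference for its summary arithmetic.
"""

from __future__ import annotations

from importlib import resources

from .report import MeasurementRecord, load_session_csv

__all__ = ["load_scint_session", "load_film_session"]


def _load(name: str) -> list[MeasurementRecord]:
    with resources.as_file(resources.files("scintshot.data") / name) as path:
        return load_session_csv(path)


def load_scint_session() -> list[MeasurementRecord]:
    """Scintillator-system records: 5 days x {uncalibrated, calibrated}."""
    return _load("session_scint.csv")


def load_film_session() -> list[MeasurementRecord]:
    """EBT3-film records: 5 days, laser deviations only, uncalibrated."""
    return _load("session_film.csv")
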