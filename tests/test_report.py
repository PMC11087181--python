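import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scintshot import (BadInputError, MeasurementRecord, ParseError,
                       compare_calibration, deviation, load_session_csv,
                       render_summary, round_half_away, summarize,
                       write_session_csv)
from scintshot.datasets import load_film_session, load_scint_session

coord = st.floats(-5, 5, allow_nan=False, allow_infinity=False)


def rec(label="1", radius=0.3, laser=(0.1, -0.2), imaging=None, calibrated=False):
    return MeasurementRecord(label=label, min_circle_radius_mm=radius,
                             dev_laser_mm=laser, dev_imaging_mm=imaging,
                             calibrated=calibrated)


class TestDeviation:
    def test_identical_points_give_zero(self):
        assert deviation((1.0, 2.0), (1.0, 2.0)) == (0.0, 0.0)

    def test_sign_convention_flips_raster_y(self):
        # raster-mm inputs; report axes are y-up
        assert deviation((1.0, 2.0), (0.5, 2.5)) == (0.5, 0.5)

    @given(ax=coord, ay=coord, bx=coord, by=coord)
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, ax, ay, bx, by):
        d1 = deviation((ax, ay), (bx, by))
        d2 = deviation((bx, by), (ax, ay))
        assert d1[0] == -d2[0] and d1[1] == -d2[1]


class TestSummarize:
    def test_single_record_reproduces_itself(self):
        s = summarize([rec(radius=0.4, laser=(0.3, -0.4), imaging=(0.1, 0.2))])
        assert s.mean_radius_mm == 0.4
        assert s.sd_radius_mm == 0.0
        assert s.laser.mean_magnitude_mm == pytest.approx(0.5)
        assert s.laser.max_magnitude_mm == s.laser.mean_magnitude_mm
        assert s.imaging.mean_mm == (0.1, 0.2)

    def test_empty_rejected(self):
        with pytest.raises(BadInputError):
            summarize([])

    def test_population_sd(self):
        s = summarize([rec(radius=r) for r in (0.2, 0.4)])
        assert s.sd_radius_mm == pytest.approx(0.1)

    @given(st.lists(st.tuples(coord, coord), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=60)
    def test_norm_inequalities(self, vecs):
        s = summarize([rec(label=str(i), laser=v) for i, v in enumerate(vecs)])
        assert np.hypot(*s.laser.mean_mm) <= s.laser.mean_magnitude_mm + 1e-9
        assert s.laser.mean_magnitude_mm <= s.laser.max_magnitude_mm + 1e-9

    def test_bundled_scint_session_statistics(self):
        records = [r for r in load_scint_session() if not r.calibrated]
        out = render_summary(summarize(records))
        assert out["mean_radius_mm"] == 0.29
        assert out["sd_radius_mm"] == 0.14
        assert out["imaging"]["mean_mm"] == [-0.23, 0.14]
        assert out["imaging"]["mean_magnitude_mm"] == 0.35
        assert out["imaging"]["max_magnitude_mm"] == 0.54
        assert out["laser"]["max_magnitude_mm"] == 1.14

    def test_bundled_film_session_statistics(self):
        out = render_summary(summarize(load_film_session()))
        assert out["mean_radius_mm"] == 0.41
        assert out["sd_radius_mm"] == 0.10
        assert out["laser"]["mean_magnitude_mm"] == 1.10
        assert out["laser"]["max_magnitude_mm"] == 1.18


class TestCompareCalibration:
    def test_bundled_session_max_delta(self):
        assert compare_calibration(load_scint_session()) == pytest.approx(0.07)

    def test_identical_pairs_give_zero(self):
        pairs = [rec(label="a"), rec(label="a", calibrated=True)]
        assert compare_calibration(pairs) == 0.0

    def test_single_component_difference(self):
        pairs = [rec(label="a", laser=(0.10, 0.20)),
                 rec(label="a", laser=(0.10, 0.23), calibrated=True)]
        assert compare_calibration(pairs) == pytest.approx(0.03)

    def test_unpaired_label_rejected(self):
        with pytest.raises(BadInputError):
            compare_calibration([rec(label="a"), rec(label="b", calibrated=True)])


class TestSessionCsv:
    def test_round_trip_full_precision(self, tmp_path):
        records = [rec(label="d1", radius=0.123456789012, laser=(1 / 3, -2 / 7),
                       imaging=(0.1 + 1e-13, -0.2)),
                   rec(label="d2", radius=0.5, laser=(0.0, 0.0), calibrated=True)]
        path = tmp_path / "session.csv"
        write_session_csv(records, path)
        loaded = load_session_csv(path)
        for a, b in zip(records, loaded):
            assert abs(a.min_circle_radius_mm - b.min_circle_radius_mm) < 1e-12
            assert np.allclose(a.dev_laser_mm, b.dev_laser_mm, atol=1e-12)
            assert a.calibrated == b.calibrated

    def test_bundled_fixture_loads_ten_records(self):
        records = load_scint_session()
        assert len(records) == 10
        assert sum(r.calibrated for r in records) == 5

    def test_missing_imaging_columns_are_optional(self):
        records = load_film_session()
        assert all(r.dev_imaging_mm is None for r in records)

    def test_malformed_row_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("label,radius_mm,laser_dx_mm,laser_dy_mm\n"
                        "1,0.3,0.1,0.2\n"
                        "2,oops,0.1,0.2\n")
        with pytest.raises(ParseError, match="row 3"):
            load_session_csv(path)


class TestRounding:
    @pytest.mark.parametrize("value, expected", [
        (0.345, 0.35), (-0.345, -0.35), (0.144, 0.14),
        (0.286, 0.29), (0.075, 0.08), (-0.075, -0.08), (1.0, 1.0),
    ])
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected
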