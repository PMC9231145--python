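"""Sensor/annotation CSV dialects and four-stream synchronization."""

import numpy as np
import pandas as pd
import pytest

from dyskit import ingest, simulate
from dyskit.exceptions import (
    DataError,
    FormatError,
    UnsynchronizableRecordingError,
)
from dyskit.ingest import (
    SENSOR_CSV_COLUMNS,
    SensorStream,
    read_annotation_csv,
    read_sensor_csv,
    synchronize_streams,
    validate_recording,
    write_sensor_csv,
)


def make_stream(ts, value=0.0, location="arm_left"):
    ts = np.asarray(ts, dtype=float)
    n = ts.size
    block = np.full((n, 3), value, dtype=float)
    return SensorStream(location, ts, block.copy(), block.copy(), block.copy())


def uniform_stream(n=600, rate=60.0, location="arm_left", seed=0):
    rng = np.random.default_rng(seed)
    ts = np.arange(n) * (1000.0 / rate)
    return SensorStream(
        location, ts,
        rng.standard_normal((n, 3)),
        rng.standard_normal((n, 3)),
        ingest.wrap_degrees(rng.uniform(-180, 180, (n, 3))),
    )


class TestSensorCsv:
    def test_three_row_file(self, tmp_path):
        p = tmp_path / "arm_left.csv"
        pd.DataFrame(
            [[0.0] + [1.0] * 9, [16.7] + [2.0] * 9, [33.3] + [3.0] * 9],
            columns=list(SENSOR_CSV_COLUMNS),
        ).to_csv(p, index=False)
        s = read_sensor_csv(p)
        assert s.n == 3 and s.location == "arm_left"

    def test_duplicate_timestamps_averaged_with_warning(self, tmp_path):
        p = tmp_path / "arm_left.csv"
        pd.DataFrame(
            [[0.0] + [1.0] * 9, [0.0] + [3.0] * 9, [16.7] + [5.0] * 9],
            columns=list(SENSOR_CSV_COLUMNS),
        ).to_csv(p, index=False)
        with pytest.warns(UserWarning, match="duplicate"):
            s = read_sensor_csv(p)
        assert s.n == 2
        assert s.acc[0, 0] == pytest.approx(2.0)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "arm_left.csv"
        p.write_text("time,ax\n0,1\n")
        with pytest.raises(FormatError):
            read_sensor_csv(p)

    def test_decreasing_timestamps_rejected(self, tmp_path):
        p = tmp_path / "arm_left.csv"
        pd.DataFrame(
            [[10.0] + [0.0] * 9, [5.0] + [0.0] * 9],
            columns=list(SENSOR_CSV_COLUMNS),
        ).to_csv(p, index=False)
        with pytest.raises(DataError):
            read_sensor_csv(p)

    def test_round_trip_exact(self, tmp_path):
        stream = uniform_stream(seed=3)
        p = tmp_path / "arm_left.csv"
        write_sensor_csv(stream, p)
        back = read_sensor_csv(p)
        assert np.array_equal(back.timestamps_ms, stream.timestamps_ms)
        assert np.array_equal(back.acc, stream.acc)
        assert np.array_equal(back.euler, stream.euler)


class TestAnnotationCsv:
    def _write(self, tmp_path, rows):
        p = tmp_path / "ann.csv"
        pd.DataFrame(
            rows, columns=list(ingest.ANNOTATION_CSV_COLUMNS)
        ).to_csv(p, index=False)
        return p

    def test_out_of_range_score_names_row(self, tmp_path):
        p = self._write(tmp_path, [["r1", 0, "rater_1", "arm_left", 5, 0]])
        with pytest.raises(DataError, match="row 2"):
            read_annotation_csv(p)

    def test_missing_marker_rows_retained(self, tmp_path):
        p = self._write(tmp_path, [["r1", 0, "rater_1", "arm_left", "", 1]])
        recs = read_annotation_csv(p)
        assert len(recs) == 1 and recs[0].score is None

    def test_unknown_limb_rejected(self, tmp_path):
        p = self._write(tmp_path, [["r1", 0, "rater_1", "torso", 2, 0]])
        with pytest.raises(FormatError):
            read_annotation_csv(p)

    def test_full_grid_count(self, tmp_path):
        rows = [
            [f"r1", w, f"rater_{k}", limb, 2, 0]
            for w in range(12)
            for limb in ingest.SENSOR_LOCATIONS
            for k in range(1, 4)
        ]
        recs = read_annotation_csv(self._write(tmp_path, rows))
        assert len(recs) == 144


class TestSynchronization:
    def test_identity_on_complete_uniform_streams(self):
        streams = {
            loc: uniform_stream(location=loc, seed=i)
            for i, loc in enumerate(ingest.SENSOR_LOCATIONS)
        }
        rec = synchronize_streams(streams)
        assert rec.n == 600 and not rec.degraded
        for loc, s in streams.items():
            assert np.max(np.abs(rec.data[loc][:, :3] - s.acc)) < 1e-9
            assert not rec.interpolated[loc].any()

    def test_interior_gap_linear_midpoint(self):
        step = 1000.0 / 60.0
        full = np.arange(10) * step
        gapped = np.delete(full, 5)
        a = make_stream(full, 0.0, "arm_left")
        b = make_stream(gapped, 0.0, "arm_right")
        b.acc[:, 0] = np.where(gapped < full[5], 1.0, 2.0)
        rec = synchronize_streams(
            {"arm_left": a, "arm_right": b,
             "leg_left": make_stream(full, 0, "leg_left"),
             "leg_right": make_stream(full, 0, "leg_right")}
        )
        assert rec.data["arm_right"][5, 0] == pytest.approx(1.5)
        assert rec.interpolated["arm_right"][5]

    def test_yaw_seam_interpolates_near_180(self):
        step = 1000.0 / 60.0
        ts = np.arange(3) * step
        s = make_stream(np.array([ts[0], ts[2]]), 0.0, "arm_left")
        s.euler[:, 2] = [179.0, -179.0]
        others = {
            loc: make_stream(ts, 0.0, loc)
            for loc in ("arm_right", "leg_left", "leg_right")
        }
        rec = synchronize_streams({"arm_left": s, **others})
        yaw_mid = rec.data["arm_left"][1, 8]
        assert abs(abs(yaw_mid) - 180.0) < 1.0  # near the seam, not near 0

    def test_empty_overlap_raises(self):
        a = make_stream([0.0, 100.0], 0.0, "arm_left")
        b = make_stream([5000.0, 5100.0], 0.0, "arm_right")
        with pytest.raises(UnsynchronizableRecordingError):
            synchronize_streams({"arm_left": a, "arm_right": b})

    def test_early_sensor_failure_truncates_and_flags(self):
        streams = {
            loc: uniform_stream(location=loc, seed=i)
            for i, loc in enumerate(ingest.SENSOR_LOCATIONS)
        }
        s = streams["leg_left"]
        streams["leg_left"] = SensorStream(
            "leg_left", s.timestamps_ms[:300], s.acc[:300], s.gyro[:300],
            s.euler[:300],
        )
        rec = synchronize_streams(streams)
        assert rec.degraded and rec.n <= 300

    def test_grid_uniformity(self):
        streams = {
            loc: uniform_stream(location=loc, seed=i)
            for i, loc in enumerate(ingest.SENSOR_LOCATIONS)
        }
        rec = synchronize_streams(streams)
        diffs = np.diff(rec.timestamps_ms)
        assert np.max(np.abs(diffs - 1000.0 / 60.0)) < 1e-6

    def test_interpolation_betweenness(self):
        """Every interpolated non-angle value lies between its bracketing
        observations (linear interpolation invents no data)."""
        rng = np.random.default_rng(0)
        full = np.sort(rng.uniform(0, 5000, 200))
        streams = {}
        for i, loc in enumerate(ingest.SENSOR_LOCATIONS):
            keep = np.sort(
                rng.choice(200, size=150, replace=False)
            )
            s = uniform_stream(n=200, location=loc, seed=i)
            streams[loc] = SensorStream(
                loc, full[keep], s.acc[keep], s.gyro[keep], s.euler[keep]
            )
        rec = synchronize_streams(streams)
        for loc, s in streams.items():
            for c in range(6):  # acc + gyro channels
                raw = s.acc[:, c] if c < 3 else s.gyro[:, c - 3]
                lo_idx = np.searchsorted(s.timestamps_ms, rec.timestamps_ms,
                                         side="right") - 1
                lo_idx = np.clip(lo_idx, 0, s.n - 1)
                hi_idx = np.clip(lo_idx + 1, 0, s.n - 1)
                lo = np.minimum(raw[lo_idx], raw[hi_idx]) - 1e-12
                hi = np.maximum(raw[lo_idx], raw[hi_idx]) + 1e-12
                v = rec.data[loc][:, c]
                assert np.all((v >= lo) & (v <= hi))


class TestValidation:
    def test_usable_and_unusable_by_duration(self):
        streams = {
            loc: uniform_stream(n=3600, location=loc, seed=i)
            for i, loc in enumerate(ingest.SENSOR_LOCATIONS)
        }
        rec = synchronize_streams(streams)
        assert validate_recording(rec, min_seconds=5.0).usable
        short = synchronize_streams(
            {loc: uniform_stream(n=180, location=loc, seed=i)
             for i, loc in enumerate(ingest.SENSOR_LOCATIONS)}
        )
        assert not validate_recording(short, min_seconds=5.0).usable

    def test_interpolated_fraction_tracks_missingness(self):
        cfg = simulate.CohortConfig(
            n_subjects=1, recordings_per_subject=1, recording_seconds=170.0,
            missing_rate=0.1, sensor_failure_prob=0.0, seed=9,
        )
        cohort = simulate.generate_cohort(cfg)
        rec = synchronize_streams(cohort.recordings[0].streams)
        report = validate_recording(rec)
        for frac in report.interpolated_fraction.values():
            assert abs(frac - 0.1) < 0.02
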