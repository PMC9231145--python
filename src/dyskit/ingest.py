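"""Reading, validation and synchronization of per-sensor inertial recordings.

Four inertial measurement units (IMUs) are worn on the left and right forearm
and left and right lower leg. Each sensor streams timestamped free
acceleration (m/s^2, gravity removed by the sensor's fusion algorithm),
angular velocity (deg/s) and ZYX Euler orientation angles (deg) at a nominal
60 Hz. In home recordings individual sensors drop timestamps and occasionally
fail mid-recording, so before windowing the four streams are resampled by
linear interpolation onto one uniform grid spanning their common time
overlap. Orientation angles are interpolated on the unwrapped angle and
rewrapped to [-180, 180) so that interpolation across the seam does not
invent spurious mid-range values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError, UnsynchronizableRecordingError

#: Sensor locations; limb labels in annotations use the same vocabulary.
SENSOR_LOCATIONS = ("arm_left", "arm_right", "leg_left", "leg_right")

#: Column dialect of one sensor's CSV file.
SENSOR_CSV_COLUMNS = (
    "timestamp_ms",
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "roll", "pitch", "yaw",
)

#: Column dialect of the per-window clinician annotation CSV.
ANNOTATION_CSV_COLUMNS = (
    "recording_id", "window_index", "rater_id", "limb", "score", "missing",
)

#: Nominal sampling rate of the sensors, Hz.
NOMINAL_RATE_HZ = 60.0

#: A grid point within this distance (ms) of a raw timestamp counts as observed.
OBSERVED_TOLERANCE_MS = 1.0


def wrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Wrap angles (deg) into [-180, 180)."""
    return (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class SensorStream:
    """One sensor's timestamped 9-channel inertial record.

    Attributes
    ----------
    location : str
        One of :data:`SENSOR_LOCATIONS`.
    timestamps_ms : ndarray, shape (n,)
        Strictly increasing timestamps in milliseconds.
    acc : ndarray, shape (n, 3)
        Free acceleration, m/s^2.
    gyro : ndarray, shape (n, 3)
        Angular velocity, deg/s.
    euler : ndarray, shape (n, 3)
        Roll, pitch, yaw in degrees (ZYX sequence), wrapped to [-180, 180).
    """

    location: str
    timestamps_ms: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    euler: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        for name in ("acc", "gyro", "euler"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise DataError(f"{name} must have shape (n, 3), got {arr.shape}")
            if arr.shape[0] != self.timestamps_ms.shape[0]:
                raise DataError(f"{name} length does not match timestamps")
            setattr(self, name, arr)
        if self.location not in SENSOR_LOCATIONS:
            raise DataError(f"unknown sensor location {self.location!r}")
        if self.n > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise DataError(f"timestamps of {self.location} not strictly increasing")
        if not (np.isfinite(self.timestamps_ms).all() and np.isfinite(self.acc).all()
                and np.isfinite(self.gyro).all() and np.isfinite(self.euler).all()):
            raise DataError(f"non-finite values in stream {self.location}")

    @property
    def n(self) -> int:
        return int(self.timestamps_ms.shape[0])

    def channels(self) -> np.ndarray:
        """All nine channels as an (n, 9) matrix, column order as in the CSV."""
        return np.hstack([self.acc, self.gyro, self.euler])

    def to_frame(self) -> pd.DataFrame:
        data = np.column_stack([self.timestamps_ms, self.channels()])
        return pd.DataFrame(data, columns=list(SENSOR_CSV_COLUMNS))


@dataclass
class AnnotationRecord:
    """One rater's dystonia score for one limb in one 5-s window (or missing)."""

    recording_id: str
    window_index: int
    rater_id: str
    limb: str
    score: int | None  # None = unscorable window (limb not visible)


@dataclass
class SynchronizedRecording:
    """Four sensors resampled onto one uniform common grid.

    ``data`` maps sensor location to an (n, 9) channel matrix aligned to
    ``timestamps_ms``; ``interpolated`` maps location to a boolean mask that is
    True where the grid point was filled by interpolation rather than
    coinciding (within 1 ms) with a raw sample.
    """

    recording_id: str
    subject_id: str
    timestamps_ms: np.ndarray
    nominal_rate: float
    data: dict = field(default_factory=dict)
    interpolated: dict = field(default_factory=dict)
    degraded: bool = False
    notes: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.timestamps_ms.shape[0])

    @property
    def duration_s(self) -> float:
        if self.n < 2:
            return 0.0
        return float(self.timestamps_ms[-1] - self.timestamps_ms[0]) / 1000.0


@dataclass
class ValidityReport:
    recording_id: str
    duration_s: float
    usable: bool
    degraded: bool
    interpolated_fraction: dict
    notes: list


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def read_sensor_csv(path, location: str | None = None) -> SensorStream:
    """Read one sensor CSV into a :class:`SensorStream`.

    Duplicate timestamps are collapsed to their channel-wise mean with a
    warning; timestamps that decrease raise :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != list(SENSOR_CSV_COLUMNS):
        raise FormatError(
            f"{path}: header {list(df.columns)} does not match sensor dialect"
        )
    if location is None:
        location = path.stem
    ts = df["timestamp_ms"].to_numpy(dtype=float)
    if ts.size > 1 and np.any(np.diff(ts) < 0):
        raise DataError(f"{path}: timestamps decrease")
    if ts.size != np.unique(ts).size:
        warnings.warn(f"{path}: duplicate timestamps collapsed to their mean")
        df = df.groupby("timestamp_ms", as_index=False, sort=True).mean()
    return SensorStream(
        location=location,
        timestamps_ms=df["timestamp_ms"].to_numpy(dtype=float),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float),
        euler=df[["roll", "pitch", "yaw"]].to_numpy(dtype=float),
    )


def write_sensor_csv(stream: SensorStream, path) -> None:
    stream.to_frame().to_csv(path, index=False)


def read_annotation_csv(path) -> list[AnnotationRecord]:
    """Read per-window clinician scores.

    Rows with a blank score must carry ``missing=1`` and become records with
    ``score=None``; scores outside 0-4 and unknown limb labels are rejected
    with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != list(ANNOTATION_CSV_COLUMNS):
        raise FormatError(
            f"{path}: header {list(df.columns)} does not match annotation dialect"
        )
    records: list[AnnotationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # header is line 1
        limb = str(row.limb)
        if limb not in SENSOR_LOCATIONS:
            raise FormatError(f"{path} row {rownum}: unknown limb {limb!r}")
        missing = int(row.missing) if not pd.isna(row.missing) else 0
        if pd.isna(row.score):
            if not missing:
                raise DataError(
                    f"{path} row {rownum}: blank score without missing marker"
                )
            score: int | None = None
        else:
            score = int(row.score)
            if score not in (0, 1, 2, 3, 4):
                raise DataError(f"{path} row {rownum}: score {score} outside 0-4")
        records.append(
            AnnotationRecord(
                recording_id=str(row.recording_id),
                window_index=int(row.window_index),
                rater_id=str(row.rater_id),
                limb=limb,
                score=score,
            )
        )
    return records


def annotations_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    rows = [
        {
            "recording_id": r.recording_id,
            "window_index": r.window_index,
            "rater_id": r.rater_id,
            "limb": r.limb,
            "score": "" if r.score is None else r.score,
            "missing": 1 if r.score is None else 0,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(ANNOTATION_CSV_COLUMNS))


def write_annotation_csv(records: list[AnnotationRecord], path) -> None:
    annotations_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def synchronize_streams(
    streams: dict,
    nominal_rate: float = NOMINAL_RATE_HZ,
    recording_id: str = "",
    subject_id: str = "",
) -> SynchronizedRecording:
    """Resample sensor streams onto a uniform grid over their common overlap.

    The grid starts at the latest stream start, steps by ``1000/nominal_rate``
    ms and ends at the earliest stream end; each channel is linearly
    interpolated, never extrapolated. Euler angles are unwrapped (period 360)
    before interpolation and rewrapped afterwards. If a sensor ends early
    (failure) the whole recording is truncated to the overlap and flagged
    degraded; fewer than four sensors also flags the recording degraded.
    """
    streams = {loc: s for loc, s in streams.items() if s is not None and s.n > 0}
    if not streams:
        raise UnsynchronizableRecordingError(f"{recording_id}: no sensor data")
    starts = [s.timestamps_ms[0] for s in streams.values()]
    ends = [s.timestamps_ms[-1] for s in streams.values()]
    t0, t1 = max(starts), min(ends)
    step = 1000.0 / float(nominal_rate)
    if t1 - t0 < step:
        raise UnsynchronizableRecordingError(
            f"{recording_id}: empty overlap across sensors"
        )
    n_grid = int(np.floor((t1 - t0) / step)) + 1
    grid = t0 + step * np.arange(n_grid)

    notes: list[str] = []
    degraded = False
    if len(streams) < len(SENSOR_LOCATIONS):
        degraded = True
        missing = sorted(set(SENSOR_LOCATIONS) - set(streams))
        notes.append(f"missing sensors: {','.join(missing)}")
    if min(ends) < max(ends) - step:
        degraded = True
        notes.append("truncated to common overlap (sensor ended early)")

    data: dict = {}
    interpolated: dict = {}
    for loc, s in streams.items():
        cols = []
        for j in range(3):
            cols.append(np.interp(grid, s.timestamps_ms, s.acc[:, j]))
        for j in range(3):
            cols.append(np.interp(grid, s.timestamps_ms, s.gyro[:, j]))
        for j in range(3):
            unwrapped = np.unwrap(s.euler[:, j], period=360.0)
            cols.append(wrap_degrees(np.interp(grid, s.timestamps_ms, unwrapped)))
        data[loc] = np.column_stack(cols)
        # a grid point is "observed" when it lands within 1 ms of a raw sample
        idx = np.searchsorted(s.timestamps_ms, grid)
        idx_lo = np.clip(idx - 1, 0, s.n - 1)
        idx_hi = np.clip(idx, 0, s.n - 1)
        dist = np.minimum(
            np.abs(grid - s.timestamps_ms[idx_lo]),
            np.abs(s.timestamps_ms[idx_hi] - grid),
        )
        interpolated[loc] = dist > OBSERVED_TOLERANCE_MS

    return SynchronizedRecording(
        recording_id=recording_id,
        subject_id=subject_id,
        timestamps_ms=grid,
        nominal_rate=float(nominal_rate),
        data=data,
        interpolated=interpolated,
        degraded=degraded,
        notes=notes,
    )


def validate_recording(rec: SynchronizedRecording, min_seconds: float = 5.0) -> ValidityReport:
    """Report duration, per-sensor interpolated fraction and usability."""
    frac = {
        loc: float(np.mean(mask)) for loc, mask in rec.interpolated.items()
    }
    duration = rec.duration_s
    return ValidityReport(
        recording_id=rec.recording_id,
        duration_s=duration,
        usable=duration >= float(min_seconds),
        degraded=rec.degraded,
        interpolated_fraction=frac,
        notes=list(rec.notes),
    )
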