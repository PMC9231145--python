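"""Resultant channels, 5-s windowing and labelled extremity tables.

Each synchronized sensor contributes 11 signals per timestamp: the three
free-acceleration axes plus their resultant (Euclidean norm), the three
angular-velocity axes plus their resultant, and the three Euler angles —
44 signals across the four sensors. Recordings are cut into consecutive
non-overlapping 5-s windows (300 samples at 60 Hz) whose indices match the
clinicians' annotation windows; the median of the three rater scores is the
window's label. One sample is one (window, limb) pair, featurized from that
limb's own sensor only; samples from the left and right limbs of an
extremity are pooled into upper/lower tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .ingest import SENSOR_LOCATIONS, SynchronizedRecording

#: Names and order of the 11 per-sensor signals.
SIGNAL_NAMES = (
    "acc_x", "acc_y", "acc_z", "acc_resultant",
    "gyro_x", "gyro_y", "gyro_z", "gyro_resultant",
    "roll", "pitch", "yaw",
)

DEFAULT_WINDOW_SECONDS = 5.0

#: Limb -> extremity; limb labels coincide with sensor locations.
EXTREMITY_OF_LIMB = {
    "arm_left": "upper",
    "arm_right": "upper",
    "leg_left": "lower",
    "leg_right": "lower",
}

#: Windows whose sensor had more than this interpolated fraction are flagged.
HIGH_INTERPOLATION_FRACTION = 0.5


def compute_resultants(x, y, z) -> np.ndarray:
    """Euclidean norm sqrt(x^2 + y^2 + z^2), elementwise."""
    return np.sqrt(np.square(x) + np.square(y) + np.square(z))


@dataclass
class WindowedRecording:
    """A recording cut into fixed-length windows of 11-signal blocks.

    ``signals[location]`` has shape (n_windows, 11, samples_per_window) in
    :data:`SIGNAL_NAMES` order; ``interpolated_fraction[location]`` gives the
    per-window fraction of interpolated grid points for that sensor.
    """

    recording_id: str
    subject_id: str
    window_seconds: float
    samples_per_window: int
    n_windows: int
    signals: dict = field(default_factory=dict)
    interpolated_fraction: dict = field(default_factory=dict)


def segment_windows(
    rec: SynchronizedRecording, window_seconds: float = DEFAULT_WINDOW_SECONDS
) -> WindowedRecording:
    """Cut a synchronized recording into consecutive non-overlapping windows.

    Windows start at the recording start; a trailing remainder shorter than
    one window is dropped. At 60 Hz a 5-s window holds exactly 300 samples.
    """
    n_per = int(round(rec.nominal_rate * window_seconds))
    n_windows = rec.n // n_per
    if n_windows == 0:
        warnings.warn(
            f"{rec.recording_id}: recording shorter than one "
            f"{window_seconds}-s window; no windows produced"
        )
    signals: dict = {}
    frac: dict = {}
    for loc, mat in rec.data.items():
        m = mat[: n_windows * n_per]
        acc = m[:, 0:3]
        gyro = m[:, 3:6]
        euler = m[:, 6:9]
        stacked = np.column_stack(
            [
                acc,
                compute_resultants(acc[:, 0], acc[:, 1], acc[:, 2])[:, None],
                gyro,
                compute_resultants(gyro[:, 0], gyro[:, 1], gyro[:, 2])[:, None],
                euler,
            ]
        )  # (n, 11)
        signals[loc] = (
            stacked.reshape(n_windows, n_per, len(SIGNAL_NAMES))
            .transpose(0, 2, 1)
            .copy()
        )
        mask = rec.interpolated[loc][: n_windows * n_per].reshape(n_windows, n_per)
        frac[loc] = mask.mean(axis=1)
    return WindowedRecording(
        recording_id=rec.recording_id,
        subject_id=rec.subject_id,
        window_seconds=float(window_seconds),
        samples_per_window=n_per,
        n_windows=n_windows,
        signals=signals,
        interpolated_fraction=frac,
    )


def median_rater_score(scores) -> int:
    """Middle order statistic of exactly three integer scores."""
    scores = [s for s in scores if s is not None]
    if len(scores) != 3:
        raise DataError("median_rater_score needs exactly three non-missing scores")
    return int(sorted(int(s) for s in scores)[1])


@dataclass
class ExtremityTable:
    """Pooled labelled windows of one extremity (ML-ready signal table).

    ``signals`` has shape (n_rows, 11, samples_per_window); ``meta`` carries
    subject_id, limb, recording_id, window_index, the three rater scores,
    the median ``label`` and interpolation bookkeeping, row-aligned with
    ``signals``.
    """

    extremity: str
    signals: np.ndarray
    meta: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return int(self.meta.shape[0])

    def subset(self, idx) -> "ExtremityTable":
        idx = np.asarray(idx)
        return ExtremityTable(
            extremity=self.extremity,
            signals=self.signals[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def for_subject(self, subject_id: str) -> "ExtremityTable":
        return self.subset(np.flatnonzero(self.meta["subject_id"] == subject_id))


def align_labels(
    windowed: WindowedRecording,
    annotations,
    strict: bool = True,
):
    """Attach three rater scores and the median label to each (window, limb).

    Returns ``(rows, exclusions)`` where each row dict carries the limb's
    11-signal block and metadata. (window, limb) pairs lacking any rater's
    score are dropped and counted. Annotations addressing a window index the
    recording does not have raise :class:`DataError` when ``strict`` (the
    default); with ``strict=False`` they are dropped and counted as data loss
    (a truncated sensor legitimately loses tail windows).
    """
    by_pair: dict = {}
    for a in annotations:
        if a.recording_id != windowed.recording_id:
            continue
        if a.window_index >= windowed.n_windows or a.window_index < 0:
            if strict:
                raise DataError(
                    f"annotation addresses nonexistent window {a.window_index} "
                    f"of {windowed.recording_id}"
                )
            by_pair.setdefault(("__lost__", a.limb), []).append(a.score)
            continue
        by_pair.setdefault((a.window_index, a.limb), []).append(a.score)

    rows = []
    exclusions = {"missing_scores": 0, "missing_sensor": 0, "out_of_range": 0}
    def _order(key):
        w, limb = key
        lost = w == "__lost__"
        return (lost, -1 if lost else int(w), limb)

    for (w, limb), scores in sorted(by_pair.items(), key=lambda kv: _order(kv[0])):
        if w == "__lost__":
            exclusions["out_of_range"] += 1
            continue
        if len(scores) != 3 or any(s is None for s in scores):
            exclusions["missing_scores"] += 1
            continue
        if limb not in windowed.signals:
            exclusions["missing_sensor"] += 1
            continue
        rows.append(
            {
                "recording_id": windowed.recording_id,
                "subject_id": windowed.subject_id,
                "window_index": int(w),
                "limb": limb,
                "rater_1": int(scores[0]),
                "rater_2": int(scores[1]),
                "rater_3": int(scores[2]),
                "label": median_rater_score(scores),
                "interpolated_fraction": float(
                    windowed.interpolated_fraction[limb][int(w)]
                ),
                "signals": windowed.signals[limb][int(w)],
            }
        )
    return rows, exclusions


def build_extremity_tables(labelled_rows):
    """Pool labelled (window, limb) rows into upper and lower tables."""
    tables = {}
    for extremity in ("upper", "lower"):
        rows = [r for r in labelled_rows if EXTREMITY_OF_LIMB[r["limb"]] == extremity]
        if rows:
            signals = np.stack([r["signals"] for r in rows])
            meta = pd.DataFrame(
                [{k: v for k, v in r.items() if k != "signals"} for r in rows]
            )
            meta["high_interpolation"] = (
                meta["interpolated_fraction"] > HIGH_INTERPOLATION_FRACTION
            )
        else:
            signals = np.zeros((0, len(SIGNAL_NAMES), 0))
            meta = pd.DataFrame(
                columns=[
                    "recording_id", "subject_id", "window_index", "limb",
                    "rater_1", "rater_2", "rater_3", "label",
                    "interpolated_fraction", "high_interpolation",
                ]
            )
        tables[extremity] = ExtremityTable(
            extremity=extremity, signals=signals, meta=meta
        )
    return tables["upper"], tables["lower"]


def windowed_tables_from_recordings(
    recordings,
    annotations,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    strict: bool = False,
):
    """Segment + label a list of synchronized recordings into the two tables.

    Returns ``(upper, lower, exclusions)``; exclusions aggregate the per-
    recording drop counts.
    """
    all_rows = []
    totals = {"missing_scores": 0, "missing_sensor": 0, "out_of_range": 0}
    for rec in recordings:
        windowed = segment_windows(rec, window_seconds)
        rows, excl = align_labels(windowed, annotations, strict=strict)
        all_rows.extend(rows)
        for k, v in excl.items():
            totals[k] += v
    upper, lower = build_extremity_tables(all_rows)
    return upper, lower, totals
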