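"""Synthetic cohorts of labelled four-sensor recordings.

The generator emulates the statistical structure the downstream analysis
assumes: per-limb severity scores (0-4) that evolve as a first-order Markov
chain over consecutive 5-s windows, limb movement whose oscillatory amplitude
grows with the true score (two sinusoids in the 0.5-3 Hz dystonia band on
every acceleration and angular-velocity channel, plus baseline sensor noise),
multiplicative between-subject amplitude heterogeneity, three noisy integer
raters per window, occasional missing timestamps, whole-sensor failures and
unscorable windows. Orientation channels are the integral of angular
velocity wrapped to [-180, 180).

Everything is driven by a single seed through named substreams (per subject,
recording, limb and purpose), so any part of a cohort regenerates stably.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .ingest import (
    SENSOR_LOCATIONS,
    AnnotationRecord,
    SensorStream,
    wrap_degrees,
    write_annotation_csv,
    write_sensor_csv,
)

#: Baseline (score-independent) Gaussian sensor noise, channel units.
BASELINE_NOISE_SD = 0.05

#: Frequency band of the oscillatory dystonia component, Hz.
DYSTONIA_BAND_HZ = (0.5, 3.0)

#: Number of sinusoids summed per channel per window.
N_SINUSOIDS = 2

#: Scored window length, s (matches the clinical scoring window).
WINDOW_SECONDS = 5.0


def default_score_transition(stay: float = 0.6) -> np.ndarray:
    """Sticky random-walk transition matrix over scores 0-4.

    Each window keeps its score with probability ``stay`` and otherwise moves
    to a neighbouring score (split evenly where two neighbours exist). The
    stationary distribution puts less mass on the extreme scores, mimicking
    the skew of clinical score distributions.
    """
    P = np.zeros((5, 5))
    for i in range(5):
        P[i, i] = stay
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j <= 4]
        for j in nbrs:
            P[i, j] = (1.0 - stay) / len(nbrs)
    return P


@dataclass
class CohortConfig:
    """Parameters of a synthetic home-measurement cohort."""

    n_subjects: int = 12
    recordings_per_subject: int = 3
    recording_seconds: float = 60.0
    sample_rate: float = 60.0
    score_transition: np.ndarray = field(default_factory=default_score_transition)
    amplitude_per_score: tuple = (0.0, 0.5, 1.0, 2.0, 4.0)
    subject_heterogeneity_sd: float = 0.0
    rater_noise_sd: float = 0.3
    missing_rate: float = 0.02
    sensor_failure_prob: float = 0.02
    unscorable_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.score_transition = np.asarray(self.score_transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        P = self.score_transition
        if P.shape != (5, 5) or np.any(P < 0) or np.any(
            np.abs(P.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ConfigurationError("score_transition must be 5x5 row-stochastic")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if len(self.amplitude_per_score) != 5 or any(
            a < 0 for a in self.amplitude_per_score
        ):
            raise ConfigurationError("amplitude_per_score needs 5 nonnegative values")
        for name in ("missing_rate", "sensor_failure_prob", "unscorable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.subject_heterogeneity_sd < 0 or self.rater_noise_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["score_transition"] = self.score_transition.tolist()
        d["amplitude_per_score"] = list(self.amplitude_per_score)
        return d

    @property
    def windows_per_recording(self) -> int:
        return int(np.floor(self.recording_seconds / WINDOW_SECONDS))


@dataclass
class RecordingBundle:
    recording_id: str
    subject_id: str
    streams: dict  # location -> SensorStream


@dataclass
class Cohort:
    """A generated cohort with its ground truth.

    ``ground_truth`` has one row per (recording, window, limb) with the true
    score; ``subject_factors`` holds each subject's multiplicative amplitude
    factor; ``annotations`` are the three simulated raters' integer scores.
    """

    config: CohortConfig
    recordings: list
    annotations: list  # AnnotationRecord
    ground_truth: pd.DataFrame
    subject_factors: dict


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_score_sequence(
    config: CohortConfig, n_windows: int, rng: np.random.Generator
) -> np.ndarray:
    """Markov-chain severity scores, initial state from the stationary law."""
    if n_windows < 1:
        raise ConfigurationError("n_windows must be >= 1")
    config.validate()
    P = config.score_transition
    pi = stationary_distribution(P)
    scores = np.empty(n_windows, dtype=int)
    scores[0] = rng.choice(5, p=pi)
    for t in range(1, n_windows):
        scores[t] = rng.choice(5, p=P[scores[t - 1]])
    return scores


def synthesize_limb_signal(
    true_scores: np.ndarray,
    config: CohortConfig,
    subject_factor: float,
    rng: np.random.Generator,
    location: str = "arm_left",
    noise_sd: float = BASELINE_NOISE_SD,
) -> SensorStream:
    """Synthesize one limb sensor's 9-channel stream from window scores.

    Per window and channel the signal is baseline Gaussian noise plus a sum
    of two sinusoids with frequencies drawn uniformly in the dystonia band,
    random phases and amplitude ``amplitude_per_score[score] * subject_factor``
    (acceleration and angular-velocity channels). Orientation channels are the
    cumulative integral of angular velocity, wrapped to [-180, 180).
    """
    true_scores = np.asarray(true_scores, dtype=int)
    if true_scores.min() < 0 or true_scores.max() > 4:
        raise ConfigurationError("scores must lie in 0-4")
    rate = float(config.sample_rate)
    n_per = int(round(rate * WINDOW_SECONDS))
    n = n_per * len(true_scores)
    t_sec = np.arange(n) / rate
    amp = np.asarray(config.amplitude_per_score, dtype=float)

    motion = np.zeros((n, 6))  # 3 acc + 3 gyro channels
    for w, s in enumerate(true_scores):
        a = amp[s] * float(subject_factor)
        sl = slice(w * n_per, (w + 1) * n_per)
        tw = t_sec[sl]
        for c in range(6):
            f = rng.uniform(*DYSTONIA_BAND_HZ, size=N_SINUSOIDS)
            phi = rng.uniform(0.0, 2.0 * np.pi, size=N_SINUSOIDS)
            motion[sl, c] += (
                a * np.sin(2.0 * np.pi * f[:, None] * tw[None, :] + phi[:, None])
            ).sum(axis=0)
    noise = (
        rng.normal(0.0, noise_sd, size=(n, 6)) if noise_sd > 0 else np.zeros((n, 6))
    )
    motion += noise
    acc = motion[:, :3]
    gyro = motion[:, 3:]
    euler = wrap_degrees(np.cumsum(gyro, axis=0) / rate)
    return SensorStream(
        location=location,
        timestamps_ms=np.arange(n) * (1000.0 / rate),
        acc=acc,
        gyro=gyro,
        euler=euler,
    )


def simulate_raters(
    true_score: int, rater_noise_sd: float, rng: np.random.Generator
) -> tuple:
    """Three clinicians: round(true + N(0, sd)) clipped to [0, 4]."""
    if not 0 <= int(true_score) <= 4:
        raise ConfigurationError("true_score must lie in 0-4")
    noisy = true_score + rng.normal(0.0, rater_noise_sd, size=3)
    return tuple(int(v) for v in np.clip(np.rint(noisy), 0, 4))


def inject_artifacts(
    stream: SensorStream, config: CohortConfig, rng: np.random.Generator
) -> SensorStream:
    """Drop timestamps independently and occasionally truncate (failure)."""
    n = stream.n
    keep = np.ones(n, dtype=bool)
    if config.missing_rate > 0:
        keep = rng.random(n) >= config.missing_rate
        if keep.sum() < 2:
            keep[:2] = True
    if config.sensor_failure_prob > 0 and rng.random() < config.sensor_failure_prob:
        cut = int(rng.integers(1, n))
        keep[cut:] = False
        if keep.sum() < 2:
            keep[: min(2, n)] = True
    return SensorStream(
        location=stream.location,
        timestamps_ms=stream.timestamps_ms[keep],
        acc=stream.acc[keep],
        gyro=stream.gyro[keep],
        euler=stream.euler[keep],
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort; deterministic given ``config.seed``."""
    config.validate()
    recordings: list[RecordingBundle] = []
    annotations: list[AnnotationRecord] = []
    gt_rows: list[dict] = []
    subject_factors: dict = {}
    n_windows = config.windows_per_recording

    for si in range(config.n_subjects):
        subject_id = f"subject_{si + 1:02d}"
        factor = float(
            np.exp(
                config.subject_heterogeneity_sd
                * _rng(config.seed, 9000, si).standard_normal()
            )
        )
        subject_factors[subject_id] = factor
        for ri in range(config.recordings_per_subject):
            recording_id = f"{subject_id}_rec_{ri:03d}"
            streams: dict = {}
            for li, limb in enumerate(SENSOR_LOCATIONS):
                score_rng = _rng(config.seed, si, ri, li)
                scores = sample_score_sequence(config, n_windows, score_rng)
                stream = synthesize_limb_signal(
                    scores, config, factor, _rng(config.seed, si, ri, 10 + li),
                    location=limb,
                )
                stream = inject_artifacts(
                    stream, config, _rng(config.seed, si, ri, 20 + li)
                )
                streams[limb] = stream
                rater_rng = _rng(config.seed, si, ri, 30 + li)
                for w, s in enumerate(scores):
                    gt_rows.append(
                        {
                            "recording_id": recording_id,
                            "window_index": w,
                            "limb": limb,
                            "true_score": int(s),
                        }
                    )
                    unscorable = rater_rng.random() < config.unscorable_rate
                    ratings = simulate_raters(int(s), config.rater_noise_sd, rater_rng)
                    for k in range(3):
                        annotations.append(
                            AnnotationRecord(
                                recording_id=recording_id,
                                window_index=w,
                                rater_id=f"rater_{k + 1}",
                                limb=limb,
                                score=None if unscorable else ratings[k],
                            )
                        )
            recordings.append(
                RecordingBundle(
                    recording_id=recording_id,
                    subject_id=subject_id,
                    streams=streams,
                )
            )
    ground_truth = pd.DataFrame(
        gt_rows, columns=["recording_id", "window_index", "limb", "true_score"]
    )
    return Cohort(
        config=config,
        recordings=recordings,
        annotations=annotations,
        ground_truth=ground_truth,
        subject_factors=subject_factors,
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write sensor CSVs, annotations, ground truth and a manifest.

    Returns the manifest path. The layout round-trips through the ingest
    readers with identical numeric content.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_recs = []
    for rec in cohort.recordings:
        rec_dir = out / rec.subject_id / rec.recording_id
        rec_dir.mkdir(parents=True, exist_ok=True)
        sensor_paths = {}
        for loc, stream in rec.streams.items():
            p = rec_dir / f"{loc}.csv"
            write_sensor_csv(stream, p)
            sensor_paths[loc] = str(p.relative_to(out))
        manifest_recs.append(
            {
                "recording_id": rec.recording_id,
                "subject_id": rec.subject_id,
                "sensors": sensor_paths,
                "nominal_rate": cohort.config.sample_rate,
            }
        )
    write_annotation_csv(cohort.annotations, out / "annotations.csv")
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    factors = pd.DataFrame(
        sorted(cohort.subject_factors.items()),
        columns=["subject_id", "amplitude_factor"],
    )
    factors.to_csv(out / "subject_factors.csv", index=False)
    manifest = {
        "subjects": sorted({r.subject_id for r in cohort.recordings}),
        "recordings": manifest_recs,
        "annotations": "annotations.csv",
        "ground_truth": "ground_truth.csv",
        "config": cohort.config.to_dict(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
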