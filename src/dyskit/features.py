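"""Window features: ten time/frequency-domain classes and 0-1 normalization.

For every (window, limb) sample, each of the ten feature classes is computed
on each of the limb sensor's 11 signals, giving a 110-dimensional feature
vector per sample. The classes (n = samples per window, s_i the signal,
eps = 1e-12 a totality guard):

==========================  =================================================
absolute harmonic mean      n / sum(1 / max(|s_i|, eps))
absolute maximum            max |s_i|
bandpower                   mean periodogram power over (0, Nyquist] of the
                            mean-removed signal, via the FFT; by Parseval this
                            equals the average AC power mean((s - mean(s))^2)
geometric mean              exp(mean(ln max(|s_i|, eps)))
maximum / median / minimum  order statistics
root-mean-square            sqrt(mean(s_i^2))
root-sum-of-squares         sqrt(sum(s_i^2))
Shannon entropy             -sum(s_i^2 ln(s_i^2)) with 0 ln 0 := 0
                            (signal-energy entropy)
==========================  =================================================

Normalization rescales every feature column to [0, 1] using the minimum and
maximum observed on the fitting (training) partition; constant columns map
to 0 and out-of-partition values are clipped into [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, SchemaError
from .preprocess import SIGNAL_NAMES, ExtremityTable

EPS = 1e-12

#: Metadata columns of a feature table, in order.
METADATA_COLUMNS = (
    "subject_id", "limb", "recording_id", "window_index", "label",
)


def _abs_clipped(s: np.ndarray) -> np.ndarray:
    return np.maximum(np.abs(s), EPS)


def absolute_harmonic_mean(s: np.ndarray, axis: int = -1) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    n = s.shape[axis]
    return n / np.sum(1.0 / _abs_clipped(s), axis=axis)


def absolute_maximum(s: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.max(np.abs(s), axis=axis)


def bandpower(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Mean spectral power over (0, Nyquist] of the mean-removed signal."""
    s = np.asarray(s, dtype=float)
    n = s.shape[axis]
    s0 = s - np.mean(s, axis=axis, keepdims=True)
    spec = np.square(np.abs(np.fft.rfft(s0, axis=axis)))
    # one-sided periodogram weights: interior bins count twice, DC excluded,
    # the Nyquist bin (present only for even n) counts once
    mult = np.full(n // 2 + 1, 2.0)
    mult[0] = 0.0
    if n % 2 == 0:
        mult[-1] = 1.0
    spec = np.moveaxis(spec, axis, -1)
    return (spec @ mult) / (n * n)


def geometric_mean(s: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.exp(np.mean(np.log(_abs_clipped(s)), axis=axis))


def maximum(s: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.max(s, axis=axis)


def median(s: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.median(s, axis=axis)


def minimum(s: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.min(s, axis=axis)


def root_mean_square(s: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.sqrt(np.mean(np.square(s), axis=axis))


def root_sum_of_squares(s: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.sqrt(np.sum(np.square(s), axis=axis))


def shannon_entropy(s: np.ndarray, axis: int = -1) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    e = np.square(s)
    term = np.where(e > 0, e * np.log(np.where(e > 0, e, 1.0)), 0.0)
    return -np.sum(term, axis=axis)


#: The default post-screening feature-class catalogue, alphabetical.
FEATURE_CLASSES = {
    "absolute_harmonic_mean": absolute_harmonic_mean,
    "absolute_maximum": absolute_maximum,
    "bandpower": bandpower,
    "geometric_mean": geometric_mean,
    "maximum": maximum,
    "median": median,
    "minimum": minimum,
    "root_mean_square": root_mean_square,
    "root_sum_of_squares": root_sum_of_squares,
    "shannon_entropy": shannon_entropy,
}

#: Domain of each class; bandpower is the FFT-based frequency-domain class.
FEATURE_DOMAINS = {
    name: ("frequency" if name == "bandpower" else "time")
    for name in FEATURE_CLASSES
}


def default_feature_classes() -> tuple:
    """Names of the default feature-class catalogue, in stable order."""
    return tuple(FEATURE_CLASSES)


def feature_column_name(feature_class: str, signal: str) -> str:
    return f"{feature_class}__{signal}"


def extract_feature(feature_class: str, signal, sample_rate: float = 60.0) -> float:
    """One feature value from one window signal (length >= 2)."""
    if feature_class not in FEATURE_CLASSES:
        raise KeyError(f"unknown feature class {feature_class!r}")
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 2:
        raise DataError("signal must be 1-D with at least two samples")
    if not np.isfinite(signal).all():
        raise DataError("signal contains non-finite values")
    return float(FEATURE_CLASSES[feature_class](signal))


@dataclass
class FeatureTable:
    """Samples x named features, plus subject/limb/label metadata.

    ``data`` holds the metadata columns, the feature columns and an internal
    ``_row_id`` provenance token (unique per physical sample; duplicated by
    oversampling) used to audit leakage freedom.
    """

    data: pd.DataFrame
    feature_columns: list

    def __post_init__(self) -> None:
        if "_row_id" not in self.data.columns:
            self.data = self.data.copy()
            self.data["_row_id"] = np.arange(len(self.data))

    @property
    def n(self) -> int:
        return int(len(self.data))

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    @property
    def row_ids(self) -> np.ndarray:
        return self.data["_row_id"].to_numpy()

    @property
    def meta(self) -> pd.DataFrame:
        return self.data.drop(columns=self.feature_columns)

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            data=self.data.iloc[idx].reset_index(drop=True),
            feature_columns=list(self.feature_columns),
        )

    def restrict(self, columns) -> "FeatureTable":
        columns = list(columns)
        missing = [c for c in columns if c not in self.feature_columns]
        if missing:
            raise SchemaError(f"unknown feature columns: {missing}")
        keep = [c for c in self.data.columns if c not in self.feature_columns]
        return FeatureTable(
            data=self.data[keep + columns].copy(), feature_columns=columns
        )

    def to_csv(self, path) -> None:
        self.data.drop(columns=["_row_id"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, feature_columns=None) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        if feature_columns is None:
            feature_columns = [c for c in df.columns if "__" in c]
        return cls(data=df, feature_columns=list(feature_columns))


def extract_feature_matrix(
    table: ExtremityTable, classes=None, sample_rate: float = 60.0
) -> FeatureTable:
    """Featurize every row of an extremity table (row order preserved)."""
    if table.n_rows == 0:
        raise DataError("cannot featurize an empty table")
    if classes is None:
        classes = default_feature_classes()
    cols = {}
    for ci, cname in enumerate(classes):
        fn = FEATURE_CLASSES[cname]
        # table.signals: (n_rows, 11, samples) -> one value per row per signal
        vals = fn(table.signals, axis=-1)  # (n_rows, 11)
        for si, sname in enumerate(SIGNAL_NAMES):
            cols[feature_column_name(cname, sname)] = vals[:, si]
    feats = pd.DataFrame(cols)
    if not np.isfinite(feats.to_numpy()).all():
        bad = feats.columns[~np.isfinite(feats.to_numpy()).all(axis=0)]
        raise DataError(f"non-finite feature values in columns {list(bad)}")
    meta_cols = [c for c in METADATA_COLUMNS if c in table.meta.columns]
    data = pd.concat(
        [table.meta[meta_cols].reset_index(drop=True), feats], axis=1
    )
    return FeatureTable(data=data, feature_columns=list(feats.columns))


@dataclass
class NormalizationParams:
    """Per-column min/max observed on the fitting (training) partition."""

    minima: dict = field(default_factory=dict)
    maxima: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            c: {"min": self.minima[c], "max": self.maxima[c]} for c in self.minima
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            minima={c: v["min"] for c, v in payload.items()},
            maxima={c: v["max"] for c, v in payload.items()},
        )


def fit_normalization(features: FeatureTable) -> NormalizationParams:
    """Observe per-column min/max on the (training) partition."""
    X = features.X
    return NormalizationParams(
        minima={c: float(v) for c, v in zip(features.feature_columns, X.min(axis=0))},
        maxima={c: float(v) for c, v in zip(features.feature_columns, X.max(axis=0))},
    )


def apply_normalization(
    features: FeatureTable, params: NormalizationParams
) -> FeatureTable:
    """Map each column through (x - min)/(max - min), clipped to [0, 1].

    Constant training columns (max == min) map to 0 everywhere.
    """
    unknown = [c for c in features.feature_columns if c not in params.minima]
    if unknown:
        raise SchemaError(f"normalization params lack columns: {unknown}")
    data = features.data.copy()
    for c in features.feature_columns:
        lo, hi = params.minima[c], params.maxima[c]
        span = hi - lo
        if span == 0:
            data[c] = 0.0
        else:
            data[c] = np.clip((data[c].to_numpy(dtype=float) - lo) / span, 0.0, 1.0)
    return FeatureTable(data=data, feature_columns=list(features.feature_columns))
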