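"""Feature definitions against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyskit import features
from dyskit.exceptions import SchemaError
from dyskit.features import (
    FeatureTable,
    apply_normalization,
    default_feature_classes,
    extract_feature,
    extract_feature_matrix,
    fit_normalization,
)

EPS = 1e-12


# ---------------------------------------------------------------------------
# Independent scalar oracles (plain Python, no numpy vectorization)
# ---------------------------------------------------------------------------

def oracle(name, s):
    s = [float(v) for v in s]
    n = len(s)
    if name == "absolute_harmonic_mean":
        return n / sum(1.0 / max(abs(v), EPS) for v in s)
    if name == "absolute_maximum":
        return max(abs(v) for v in s)
    if name == "bandpower":
        m = sum(s) / n
        return sum((v - m) ** 2 for v in s) / n  # Parseval: mean AC power
    if name == "geometric_mean":
        return math.exp(sum(math.log(max(abs(v), EPS)) for v in s) / n)
    if name == "maximum":
        return max(s)
    if name == "median":
        t = sorted(s)
        return t[n // 2] if n % 2 else (t[n // 2 - 1] + t[n // 2]) / 2.0
    if name == "minimum":
        return min(s)
    if name == "root_mean_square":
        return math.sqrt(sum(v * v for v in s) / n)
    if name == "root_sum_of_squares":
        return math.sqrt(sum(v * v for v in s))
    if name == "shannon_entropy":
        return -sum(v * v * math.log(v * v) for v in s if v != 0.0)
    raise KeyError(name)


class TestFeatureExamples:
    @pytest.mark.parametrize(
        "name, signal, expected",
        [
            ("maximum", [1, 2, 3, 4], 4.0),
            ("minimum", [1, 2, 3, 4], 1.0),
            ("median", [1, 2, 3, 4], 2.5),
            ("absolute_maximum", [-5, 2], 5.0),
            ("root_mean_square", [1, 2, 3, 4], math.sqrt(7.5)),
            ("root_sum_of_squares", [1, 2, 3, 4], math.sqrt(30.0)),
            ("geometric_mean", [1, 4], 2.0),
            ("absolute_harmonic_mean", [1, 1 / 3], 0.5),
            ("shannon_entropy", [1, 2], -4.0 * math.log(4.0)),
        ],
    )
    def test_hand_values(self, name, signal, expected):
        assert extract_feature(name, signal) == pytest.approx(expected, rel=1e-12)

    def test_bandpower_unit_sine_half(self):
        t = np.arange(300) / 60.0
        s = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz: 10 full cycles in 5 s
        assert extract_feature("bandpower", s) == pytest.approx(0.5, abs=1e-6)

    def test_bandpower_constant_zero(self):
        assert extract_feature("bandpower", np.full(300, 7.3)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_catalogue_has_ten_classes(self):
        assert len(default_feature_classes()) == 10


class TestBruteForceOracle:
    def test_all_classes_match_oracle_on_random_signals(self):
        rng = np.random.default_rng(123)
        signals = rng.standard_normal((1000, 300)) * rng.lognormal(
            0, 1, (1000, 1)
        )
        for name in default_feature_classes():
            fn = features.FEATURE_CLASSES[name]
            got = fn(signals, axis=-1)
            for i in range(0, 1000, 7):  # dense spot-check of the vector path
                expected = oracle(name, signals[i])
                assert got[i] == pytest.approx(expected, rel=1e-9, abs=1e-12), name

    def test_parseval_identity(self):
        rng = np.random.default_rng(7)
        signals = rng.standard_normal((1000, 300))
        bp = features.bandpower(signals, axis=-1)
        ac = np.mean(
            (signals - signals.mean(axis=-1, keepdims=True)) ** 2, axis=-1
        )
        assert np.max(np.abs(bp - ac) / np.maximum(ac, 1e-300)) < 1e-9

    def test_parseval_odd_length(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal(299)
        assert features.bandpower(s) == pytest.approx(
            np.mean((s - s.mean()) ** 2), rel=1e-12
        )


class TestScaleBehaviour:
    HOMOGENEOUS_1 = (
        "maximum", "minimum", "median", "absolute_maximum",
        "root_mean_square", "root_sum_of_squares", "geometric_mean",
        "absolute_harmonic_mean",
    )

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    def test_degree_one_homogeneity(self, c, seed):
        s = np.random.default_rng(seed).standard_normal(64)
        for name in self.HOMOGENEOUS_1:
            fn = features.FEATURE_CLASSES[name]
            assert fn(c * s) == pytest.approx(c * fn(s), rel=1e-7, abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    def test_bandpower_degree_two(self, c, seed):
        s = np.random.default_rng(seed).standard_normal(64)
        assert features.bandpower(c * s) == pytest.approx(
            c * c * features.bandpower(s), rel=1e-7
        )


class TestFeatureMatrix:
    def test_default_matrix_is_110_columns(self, small_tables):
        ft = extract_feature_matrix(small_tables[0])
        assert len(ft.feature_columns) == 110
        assert ft.X.shape == (small_tables[0].n_rows, 110)

    def test_single_class_gives_11_columns(self, small_tables):
        ft = extract_feature_matrix(small_tables[0], ["root_mean_square"])
        assert len(ft.feature_columns) == 11

    def test_duplicated_row_duplicates_features(self, small_tables):
        table = small_tables[0]
        dup = table.subset([0, 0, 1])
        ft = extract_feature_matrix(dup)
        assert np.array_equal(ft.X[0], ft.X[1])

    def test_metadata_invariance(self, small_tables):
        """Features depend only on the signal block, not on metadata."""
        table = small_tables[0]
        ft1 = extract_feature_matrix(table)
        renamed = table.subset(np.arange(table.n_rows))
        renamed.meta["subject_id"] = "someone_else"
        ft2 = extract_feature_matrix(renamed)
        assert np.array_equal(ft1.X, ft2.X)


class TestNormalization:
    def _table(self, cols):
        import pandas as pd

        data = pd.DataFrame(cols)
        data["label"] = 0
        return FeatureTable(data=data, feature_columns=list(cols))

    def test_min_max_mapping(self):
        ft = self._table({"a__s": [2.0, 4.0, 6.0]})
        norm = fit_normalization(ft)
        out = apply_normalization(ft, norm)
        assert np.allclose(out.X[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        ft = self._table({"a__s": [7.0, 7.0, 7.0]})
        out = apply_normalization(ft, fit_normalization(ft))
        assert np.all(out.X == 0.0)

    def test_out_of_range_clipped(self):
        train = self._table({"a__s": [0.0, 10.0]})
        test = self._table({"a__s": [-5.0, 15.0]})
        out = apply_normalization(test, fit_normalization(train))
        assert np.allclose(out.X[:, 0], [0.0, 1.0])

    def test_unknown_columns_rejected(self):
        train = self._table({"a__s": [0.0, 1.0]})
        test = self._table({"b__s": [0.0, 1.0]})
        with pytest.raises(SchemaError):
            apply_normalization(test, fit_normalization(train))

    def test_training_columns_land_in_unit_interval(self, small_feature_table):
        norm = fit_normalization(small_feature_table)
        out = apply_normalization(small_feature_table, norm)
        assert out.X.min() >= 0.0 and out.X.max() <= 1.0
        # fitted extremes map exactly to the interval ends
        assert np.allclose(out.X.max(axis=0)[out.X.std(axis=0) > 0], 1.0)

    def test_params_json_round_trip(self, tmp_path, small_feature_table):
        norm = fit_normalization(small_feature_table)
        p = tmp_path / "norm.json"
        norm.to_json(p)
        back = features.NormalizationParams.from_json(p)
        assert back.minima == norm.minima and back.maxima == norm.maxima
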