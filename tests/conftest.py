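import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")

import dyskit
from dyskit import features, simulate
from dyskit.features import FeatureTable


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects, one 30-s recording each — cheap shared fixture."""
    cfg = simulate.CohortConfig(
        n_subjects=2, recordings_per_subject=1, recording_seconds=30.0, seed=42
    )
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    upper, lower = dyskit.tables_from_cohort(small_cohort)
    return upper, lower


@pytest.fixture(scope="session")
def small_feature_table(small_tables):
    return features.extract_feature_matrix(small_tables[0])


def make_toy_feature_table(
    n: int = 60,
    n_noise: int = 3,
    n_classes: int = 3,
    seed: int = 0,
    subjects: int = 1,
    informative_name: str = "root_mean_square__acc_resultant",
) -> FeatureTable:
    """A feature table with one label-determining column among noise columns."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), -(-n // n_classes))[:n]
    cols = {informative_name: y + 0.05 * rng.standard_normal(n)}
    for i in range(n_noise):
        cols[f"noise__col{i}"] = rng.standard_normal(n)
    data = pd.DataFrame(cols)
    data["label"] = y
    data["subject_id"] = [f"subject_{i % subjects + 1:02d}" for i in range(n)]
    return FeatureTable(data=data, feature_columns=list(cols))
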