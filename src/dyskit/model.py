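"""Model/Results front end for severity-classification experiments.

``SeverityModel`` wraps a labelled feature table together with a
cross-validation scheme and an experiment grid; ``fit()`` runs the grid and
returns a ``SeverityResults`` carrying every variant's validation and test
metrics, the winning model, a leaderboard and a text ``summary()``.

Example
-------
>>> from dyskit import simulate, model
>>> cohort = simulate.generate_cohort(simulate.CohortConfig(n_subjects=2, seed=1))
>>> upper, lower = model.tables_from_cohort(cohort)
>>> m = model.SeverityModel.from_extremity_table(
...     upper.for_subject("subject_01"), scheme="kfold5")
>>> res = m.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import BestModelRecord
from .exceptions import DataError
from .features import FeatureTable, extract_feature_matrix
from .ingest import synchronize_streams
from .preprocess import ExtremityTable, windowed_tables_from_recordings
from .training import (
    ExperimentConfig,
    ExperimentResult,
    run_generalized_experiment,
    run_individual_experiment,
)


def tables_from_cohort(cohort, window_seconds: float = 5.0):
    """Synchronize, window and label a generated cohort into the two
    extremity tables (upper, lower)."""
    recs = []
    for rec in cohort.recordings:
        recs.append(
            synchronize_streams(
                rec.streams,
                nominal_rate=cohort.config.sample_rate,
                recording_id=rec.recording_id,
                subject_id=rec.subject_id,
            )
        )
    upper, lower, _ = windowed_tables_from_recordings(
        recs, cohort.annotations, window_seconds=window_seconds, strict=False
    )
    return upper, lower


class SeverityModel:
    """A cross-validated dystonia-severity classification experiment.

    Parameters
    ----------
    features : FeatureTable
        Samples x features with a 0-4 ``label`` column and subject metadata.
    scheme : {'kfold5', 'leave_two_subjects_out'}
        Individual (within-subject 5-fold) or generalized
        (leave-two-subjects-out) evaluation.
    config : ExperimentConfig, optional
        Grid of algorithm families / settings, budgets and the seed.
    """

    def __init__(
        self,
        features: FeatureTable,
        scheme: str = "kfold5",
        config: ExperimentConfig | None = None,
        dataset_id: str = "dataset",
    ):
        if scheme not in ("kfold5", "leave_two_subjects_out"):
            raise DataError(f"unknown scheme {scheme!r}")
        self.features = features
        self.scheme = scheme
        self.config = config or ExperimentConfig()
        self.dataset_id = dataset_id

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_columns=None,
        label: str = "label",
        **kwargs,
    ) -> "SeverityModel":
        """Build from a flat DataFrame; feature columns default to every
        ``class__signal``-style column."""
        data = df.copy()
        if label != "label":
            data = data.rename(columns={label: "label"})
        if feature_columns is None:
            feature_columns = [c for c in data.columns if "__" in c]
        if not feature_columns:
            raise DataError("no feature columns identified")
        return cls(FeatureTable(data=data, feature_columns=list(feature_columns)),
                   **kwargs)

    @classmethod
    def from_extremity_table(
        cls, table: ExtremityTable, classes=None, sample_rate: float = 60.0, **kwargs
    ) -> "SeverityModel":
        ft = extract_feature_matrix(table, classes, sample_rate=sample_rate)
        kwargs.setdefault("dataset_id", table.extremity)
        return cls(ft, **kwargs)

    # -- estimation -------------------------------------------------------
    def fit(self) -> "SeverityResults":
        if self.scheme == "kfold5":
            raw = run_individual_experiment(
                self.features, self.config, dataset_id=self.dataset_id
            )
        else:
            raw = run_generalized_experiment(
                self.features, self.config, dataset_id=self.dataset_id
            )
        return SeverityResults(model=self, experiment=raw)


@dataclass
class SeverityResults:
    """Fitted experiment: per-variant metrics, the winner and diagnostics."""

    model: SeverityModel
    experiment: ExperimentResult
    _leaderboard: pd.DataFrame = field(default=None, repr=False)

    @property
    def skipped(self) -> str | None:
        return self.experiment.skipped

    @property
    def variants(self) -> list:
        return self.experiment.variants

    @property
    def best(self) -> BestModelRecord:
        return self.experiment.best

    @property
    def report(self):
        """Test-set evaluation report of the winning variant."""
        return None if self.best is None else self.best.report

    @property
    def leaderboard(self) -> pd.DataFrame:
        """All variants sorted by validation F1 (descending)."""
        if self._leaderboard is None:
            rows = [
                {
                    "dataset": self.experiment.dataset_id,
                    "algorithm": v.spec.algorithm,
                    "model": v.spec.setting,
                    "f1_validation": v.validation_f1,
                    "f1_test": v.test_report.f1,
                    "precision_test": v.test_report.precision,
                    "recall_test": v.test_report.recall,
                    "rmse_test": v.test_report.rmse,
                }
                for v in self.variants
            ]
            self._leaderboard = (
                pd.DataFrame(rows)
                .sort_values("f1_validation", ascending=False)
                .reset_index(drop=True)
            )
        return self._leaderboard

    def summary(self) -> str:
        """Human-readable experiment summary."""
        e = self.experiment
        lines = [
            "Dystonia severity classification experiment",
            "=" * 60,
            f"dataset:        {e.dataset_id}",
            f"scheme:         {e.scheme}",
            f"n samples:      {e.n_samples}",
        ]
        if e.skipped:
            lines.append(f"skipped:        {e.skipped}")
            return "\n".join(lines)
        lines.append(f"variants:       {len(self.variants)}")
        lines.append("-" * 60)
        lb = self.leaderboard
        lines.append(
            lb.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
                columns=[
                    "algorithm", "model", "f1_validation", "f1_test",
                    "precision_test", "recall_test", "rmse_test",
                ],
            )
        )
        b = self.best
        lines += [
            "-" * 60,
            f"best model:     {b.algorithm} ({b.setting})",
            f"validation F1:  {b.validation_f1:.3f}",
            f"test F1:        {b.test_f1:.3f}   precision: {b.test_precision:.3f}"
            f"   recall: {b.test_recall:.3f}",
            f"test RMSE:      {b.report.rmse:.3f}",
        ]
        adj = b.report.adjacent_error_fraction
        if adj is not None:
            lines.append(f"adjacent-error fraction: {adj:.3f}")
        return "\n".join(lines)

    def plot_confusion(self, ax=None, title: str | None = None):
        """Heatmap of the winning variant's pooled test confusion matrix."""
        from .plotting import plot_confusion_matrix

        if self.report is None:
            raise DataError("experiment was skipped; nothing to plot")
        if title is None:
            title = (
                f"{self.experiment.dataset_id}: {self.best.algorithm} "
                f"({self.best.setting})"
            )
        return plot_confusion_matrix(self.report.confusion, ax=ax, title=title)
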