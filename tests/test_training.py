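"""Oversampling, fold plans, estimators, tuning and the experiment engines."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_toy_feature_table
from dyskit import bayesopt, training
from dyskit.exceptions import ConfigurationError
from dyskit.features import FeatureTable
from dyskit.training import (
    ExperimentConfig,
    KernelNaiveBayes,
    ModelSpec,
    cross_validated_predictions,
    make_estimator,
    make_folds,
    misclassification_rate,
    oversample_to_balance,
    run_generalized_experiment,
    run_individual_experiment,
    train_model,
    tune_hyperparameters,
)


def table_with_counts(counts, seed=0):
    rng = np.random.default_rng(seed)
    y = np.concatenate([[c] * n for c, n in counts.items()]).astype(int)
    data = pd.DataFrame({"f__a": rng.standard_normal(y.size), "label": y})
    data["subject_id"] = "subject_01"
    return FeatureTable(data=data, feature_columns=["f__a"])


class TestOversampling:
    def test_counts_equalized(self):
        ft = oversample_to_balance(table_with_counts({0: 10, 1: 3, 2: 5}), seed=1)
        counts = np.bincount(ft.y)
        assert list(counts[:3]) == [10, 10, 10] and ft.n == 30

    def test_balanced_input_unchanged(self):
        ft = table_with_counts({0: 5, 1: 5})
        out = oversample_to_balance(ft, seed=1)
        assert sorted(out.row_ids.tolist()) == sorted(ft.row_ids.tolist())

    def test_added_rows_are_duplicates(self):
        ft = table_with_counts({0: 8, 3: 2})
        out = oversample_to_balance(ft, seed=2)
        originals = set(map(tuple, ft.data[["f__a", "label"]].to_numpy()))
        for row in out.data[["f__a", "label"]].to_numpy():
            assert tuple(row) in originals
        # provenance tokens of added rows point at existing physical rows
        assert set(out.row_ids.tolist()) <= set(ft.row_ids.tolist())


class TestFoldPlans:
    def test_kfold_partitions_disjointly(self):
        ft = make_toy_feature_table(n=100, n_classes=5, seed=1)
        plan = make_folds(ft, "kfold5", seed=0)
        seen = np.concatenate([te for _, te in plan.folds])
        assert sorted(seen.tolist()) == list(range(100))
        for tr, te in plan.folds:
            assert len(te) == 20 and not set(tr) & set(te)

    def test_ltso_folds_and_training_subjects(self):
        ft = make_toy_feature_table(n=120, subjects=12, seed=2)
        plan = make_folds(ft, "leave_two_subjects_out", seed=0)
        assert plan.n_folds == 6
        subj = ft.data["subject_id"].to_numpy()
        for tr, te in plan.folds:
            assert len(set(subj[tr])) == 10 and len(set(subj[te])) == 2
            assert not set(subj[tr]) & set(subj[te])

    def test_odd_subject_count_rejected(self):
        ft = make_toy_feature_table(n=60, subjects=3, seed=3)
        with pytest.raises(ConfigurationError):
            make_folds(ft, "leave_two_subjects_out", seed=0)

    def test_same_seed_same_plan(self):
        ft = make_toy_feature_table(n=100, seed=4)
        a = make_folds(ft, "kfold5", seed=9)
        b = make_folds(ft, "kfold5", seed=9)
        for (tra, tea), (trb, teb) in zip(a.folds, b.folds):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)


class TestEstimators:
    @pytest.mark.parametrize("algorithm", training.ALGORITHMS)
    def test_families_fit_and_predict(self, algorithm):
        ft = make_toy_feature_table(n=60, n_classes=3, seed=5)
        spec = ModelSpec(algorithm=algorithm)
        model = train_model(spec, ft, seed=0)
        preds = model.predict(ft)
        assert preds.shape == (60,)
        assert set(preds) <= set(range(5))

    def test_1nn_memorizes_training_data(self):
        ft = make_toy_feature_table(n=30, n_classes=3, seed=6)
        spec = ModelSpec("knn", hyperparameters={"n_neighbors": 1})
        model = train_model(spec, ft, seed=0, balance=False)
        assert np.array_equal(model.predict(ft), ft.y)

    def test_tree_separates_separable_toy(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)])
        data = pd.DataFrame({"f__a": x, "label": np.repeat([0, 1], 30)})
        ft = FeatureTable(data=data, feature_columns=["f__a"])
        model = train_model(ModelSpec("decision_tree"), ft, seed=0)
        test = FeatureTable(
            data=pd.DataFrame({"f__a": [0.5, 2.5], "label": [0, 1]}),
            feature_columns=["f__a"],
        )
        assert np.array_equal(model.predict(test), [0, 1])

    def test_single_class_training_predicts_that_class(self):
        ft = table_with_counts({3: 12})
        for algorithm in ("svm", "discriminant", "knn"):
            model = train_model(ModelSpec(algorithm), ft, seed=0)
            assert np.all(model.predict(ft) == 3)

    def test_kernel_naive_bayes_separates(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.2, (40, 2)), rng.normal(2, 0.2, (40, 2))])
        y = np.repeat([0, 1], 40)
        nb = KernelNaiveBayes().fit(X, y)
        assert np.mean(nb.predict(X) == y) > 0.95

    def test_sfs_setting_requires_selected_features(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("knn", setting="SFS")


class TestTuning:
    def test_budget_spent_exactly(self):
        ft = make_toy_feature_table(n=50, n_classes=2, seed=9)
        _, trace = tune_hyperparameters("knn", ft, budget=15, inner_folds=3, seed=0)
        assert trace.n_evaluations == 15

    def test_best_observed_contract(self):
        ft = make_toy_feature_table(n=50, n_classes=2, seed=10)
        best_hp, trace = tune_hyperparameters(
            "knn", ft, budget=8, inner_folds=3, seed=0
        )
        assert trace.best_value == min(trace.values)
        assert best_hp == trace.params[int(np.argmin(trace.values))]

    def test_random_search_never_beats_best_observed(self):
        """By construction the returned value is the minimum over the
        evaluated set; a random subsample of that set cannot be lower."""
        ft = make_toy_feature_table(n=50, n_classes=2, seed=11)
        _, trace = tune_hyperparameters("knn", ft, budget=6, inner_folds=3, seed=1)
        rng = np.random.default_rng(0)
        subset = rng.choice(trace.values, size=4, replace=False)
        assert subset.min() >= trace.best_value

    def test_bad_budget_rejected(self):
        ft = make_toy_feature_table(seed=12)
        with pytest.raises(ConfigurationError):
            tune_hyperparameters("knn", ft, budget=0)

    def test_optimizer_determinism(self):
        space = [bayesopt.Dimension("x", "float", 0.0, 1.0)]
        a = bayesopt.minimize(lambda p: (p["x"] - 0.3) ** 2, space, 10, seed=3)
        b = bayesopt.minimize(lambda p: (p["x"] - 0.3) ** 2, space, 10, seed=3)
        assert a.values == b.values and a.best_params == b.best_params


class TestExperiments:
    def test_kfold_pooled_predictions_cover_each_sample_once(self):
        ft = make_toy_feature_table(n=60, n_classes=3, seed=13)
        y_true, y_pred = cross_validated_predictions(ft, "knn", None, 5, seed=0)
        assert y_true.size == 60 and y_pred.size == 60
        assert np.array_equal(np.sort(y_true), np.sort(ft.y))

    def test_individual_experiment_structure(self):
        ft = make_toy_feature_table(n=80, n_classes=4, seed=14)
        cfg = ExperimentConfig(algorithms=("knn",), settings=("ALL", "SFS"),
                               seed=0, sfs_budget=6)
        res = run_individual_experiment(ft, cfg)
        assert len(res.variants) == 2
        assert res.best is not None
        for v in res.variants:
            assert v.test_report.n_samples == 80

    def test_single_class_subject_skipped(self):
        ft = table_with_counts({2: 20})
        res = run_individual_experiment(ft, ExperimentConfig(algorithms=("knn",),
                                                             settings=("ALL",)))
        assert res.skipped == "single-class data"

    def test_generalized_no_subject_leaks_between_train_and_test(self):
        ft = make_toy_feature_table(n=120, subjects=4, n_classes=3, seed=15)
        cfg = ExperimentConfig(algorithms=("knn",), settings=("ALL",),
                               seed=0, audit=True)
        res = run_generalized_experiment(ft, cfg)
        subj = ft.data["subject_id"].to_numpy()
        for tr, te in res.fold_plan.folds:
            assert not set(subj[tr]) & set(subj[te])

    def test_audit_shows_training_rows_only(self):
        ft = make_toy_feature_table(n=60, n_classes=3, seed=16)
        cfg = ExperimentConfig(algorithms=("knn",), settings=("ALL+HYP",),
                               tuning_budget=3, seed=0, audit=True)
        res = run_individual_experiment(ft, cfg)
        assert res.audit_log
        for entry in res.audit_log:
            assert entry["row_ids"] <= entry["train_row_ids"]

    def test_misclassification_rate(self):
        assert misclassification_rate([0, 1, 2], [0, 1, 1]) == pytest.approx(1 / 3)
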