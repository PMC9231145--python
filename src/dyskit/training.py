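"""Classifier families, oversampling, fold plans and experiment engines.

Six supervised families are trained on window features: decision tree,
discriminant analysis, naive Bayes, support vector machine, k-nearest
neighbours and ensemble learning. Each family runs under four settings —
all features (ALL), all features with Bayesian hyperparameter tuning
(ALL+HYP), sequential-forward-selected features (SFS) and both (SFS+HYP) —
giving a 24-variant grid per dataset.

Protocol (per dataset): the fold plan is either 5-fold cross-validation
(individual models, one subject's data) or leave-two-subjects-out over 12
subjects (generalized models, 6 folds). Within every fold the training
partition is oversampled to equal class counts, min-max normalization is
fitted on it, and the classifier is fitted on the normalized training rows;
test rows are normalized with the training parameters (clipped) and the test
predictions are pooled across folds. Feature selection and hyperparameter
tuning are computed once on the first fold's training partition and reused
in the remaining folds. Validation F1 is the mean over outer folds of the
inner 5-fold cross-validated macro F1 on the training partition. All of
oversampling, normalization fitting, selection and tuning touch training
rows only; with ``audit=True`` the engine records the provenance tokens each
stage consumed so this can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import bayesopt
from .evaluation import EvaluationReport, evaluate_predictions, select_best_model
from .exceptions import ConfigurationError, DataError, SchemaError
from .features import (
    FeatureTable,
    NormalizationParams,
    apply_normalization,
    extract_feature_matrix,
    fit_normalization,
)

ALGORITHMS = (
    "decision_tree", "discriminant", "naive_bayes", "svm", "knn", "ensemble",
)
SETTINGS = ("ALL", "ALL+HYP", "SFS", "SFS+HYP")


@dataclass
class ModelSpec:
    """An algorithm family plus a training setting."""

    algorithm: str
    setting: str = "ALL"
    hyperparameters: dict | None = None
    selected_features: list | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.setting not in SETTINGS:
            raise ConfigurationError(f"unknown setting {self.setting!r}")
        if "SFS" in self.setting and self.selected_features is None:
            raise ConfigurationError(f"{self.setting} requires selected_features")


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel-density class conditionals.

    Each feature's class-conditional density is a Gaussian KDE over the
    training values with a Silverman-rule bandwidth scaled by
    ``bandwidth_scale``.
    """

    def __init__(self, bandwidth_scale: float = 1.0):
        self.bandwidth_scale = bandwidth_scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._X_by_class = []
        self._bandwidths = []
        self._log_priors = []
        for c in self.classes_:
            Xc = X[y == c]
            n_c = Xc.shape[0]
            sigma = np.maximum(Xc.std(axis=0), 1e-3)
            h = self.bandwidth_scale * sigma * (4.0 / (3.0 * n_c)) ** 0.2
            self._X_by_class.append(Xc)
            self._bandwidths.append(np.maximum(h, 1e-6))
            self._log_priors.append(np.log(n_c / X.shape[0]))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for k, (Xc, h, lp) in enumerate(
            zip(self._X_by_class, self._bandwidths, self._log_priors)
        ):
            d = X[:, None, :] - Xc[None, :, :]
            log_kern = -0.5 * np.square(d / h[None, None, :])
            ll = logsumexp(log_kern, axis=1)  # (m, F)
            ll = ll - np.log(Xc.shape[0]) - np.log(h * np.sqrt(2.0 * np.pi))
            out[:, k] = ll.sum(axis=1) + lp
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def make_estimator(algorithm: str, hyperparameters: dict | None = None, seed: int = 0):
    """Instantiate a classifier of the named family.

    With ``hyperparameters=None`` the family defaults are used (knn k=5).
    """
    hp = dict(hyperparameters or {})
    seed = int(seed) & 0x7FFFFFFF
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            criterion=hp.get("criterion", "gini"),
            random_state=seed,
        )
    if algorithm == "discriminant":
        if hp.get("type", "linear") == "quadratic":
            return QuadraticDiscriminantAnalysis(reg_param=float(hp.get("gamma", 0.0)))
        if "gamma" in hp:
            return LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=float(np.clip(hp["gamma"], 0.0, 1.0))
            )
        return LinearDiscriminantAnalysis()
    if algorithm == "naive_bayes":
        if hp.get("density", "gaussian") == "kernel":
            return KernelNaiveBayes(
                bandwidth_scale=float(hp.get("bandwidth_scale", 1.0))
            )
        return GaussianNB()
    if algorithm == "svm":
        scale = hp.get("kernel_scale")
        gamma = "scale" if scale is None else 1.0 / float(scale) ** 2
        return SVC(kernel="rbf", C=float(hp.get("C", 1.0)), gamma=gamma,
                   random_state=seed)
    if algorithm == "knn":
        metric = {"euclidean": "euclidean", "cityblock": "manhattan"}[
            hp.get("metric", "euclidean")
        ]
        return KNeighborsClassifier(
            n_neighbors=int(hp.get("n_neighbors", 5)),
            metric=metric,
            weights=hp.get("weights", "uniform"),
        )
    if algorithm == "ensemble":
        method = hp.get("method", "bagging")
        n_est = int(hp.get("n_estimators", 100))
        if method == "adaboost":
            return AdaBoostClassifier(
                n_estimators=n_est,
                learning_rate=float(hp.get("learning_rate", 1.0)),
                random_state=seed,
            )
        return RandomForestClassifier(n_estimators=n_est, random_state=seed)
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def search_space(algorithm: str, n_samples: int):
    """Per-family hyperparameter search space, clamped to the data size."""
    n = max(int(n_samples), 4)
    D = bayesopt.Dimension
    if algorithm == "knn":
        return [
            D("n_neighbors", "log-int", 1, max(2, min(30, n // 2))),
            D("metric", "categorical", choices=("euclidean", "cityblock")),
            D("weights", "categorical", choices=("uniform", "distance")),
        ]
    if algorithm == "decision_tree":
        return [
            D("min_samples_leaf", "log-int", 1, max(2, n // 4)),
            D("criterion", "categorical", choices=("gini", "log_loss")),
        ]
    if algorithm == "svm":
        return [
            D("C", "log-float", 1e-3, 1e3),
            D("kernel_scale", "log-float", 1e-3, 1e3),
        ]
    if algorithm == "naive_bayes":
        return [
            D("density", "categorical", choices=("gaussian", "kernel")),
            D("bandwidth_scale", "log-float", 1e-2, 1e1),
        ]
    if algorithm == "discriminant":
        return [
            D("type", "categorical", choices=("linear", "quadratic")),
            D("gamma", "float", 0.0, 1.0),
        ]
    if algorithm == "ensemble":
        return [
            D("method", "categorical", choices=("bagging", "adaboost")),
            D("n_estimators", "log-int", 10, 200),
            D("learning_rate", "log-float", 1e-2, 1.0),
        ]
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Oversampling and fold plans
# ---------------------------------------------------------------------------

def oversample_to_balance(features: FeatureTable, seed: int = 0) -> FeatureTable:
    """Duplicate minority-class rows (with replacement) to equal class counts.

    Only ever applied to training partitions. Provenance tokens (_row_id) are
    carried along, so every added row is traceably a duplicate.
    """
    y = features.y
    if y.size == 0:
        raise DataError("cannot oversample an empty table")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 271828])
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    keep = [np.arange(features.n)]
    for c, cnt in zip(classes, counts):
        if cnt < target:
            pool = np.flatnonzero(y == c)
            keep.append(rng.choice(pool, size=target - cnt, replace=True))
    idx = np.concatenate(keep)
    return features.subset(idx)


@dataclass
class FoldPlan:
    """Train/test index pairs for one cross-validation scheme."""

    scheme: str
    folds: list  # list of (train_idx, test_idx) ndarrays
    seed: int
    subject_pairs: list = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_folds(
    features: FeatureTable, scheme: str = "kfold5", seed: int = 0, n_folds: int = 5
) -> FoldPlan:
    """Build the fold plan for either CV scheme.

    kfold5 is stratified by label when every class has at least ``n_folds``
    members, otherwise plain shuffled k-fold. leave_two_subjects_out pairs
    the subjects from a seeded shuffle (even count required); each fold tests
    on one pair and trains on all remaining subjects.
    """
    seed = int(seed) & 0x7FFFFFFF
    if scheme == "kfold5":
        y = features.y
        if features.n < n_folds:
            raise ConfigurationError(
                f"kfold{n_folds} needs at least {n_folds} samples"
            )
        counts = np.unique(y, return_counts=True)[1]
        if counts.min() >= n_folds:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                       random_state=seed)
        else:
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [
            (np.asarray(tr), np.asarray(te))
            for tr, te in splitter.split(np.zeros(features.n), y)
        ]
        return FoldPlan(scheme=scheme, folds=folds, seed=seed)
    if scheme == "leave_two_subjects_out":
        subjects = sorted(features.data["subject_id"].unique())
        if len(subjects) % 2 != 0:
            raise ConfigurationError(
                "leave-two-subjects-out needs an even subject count, got "
                f"{len(subjects)}"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(subjects))
        pairs = [
            (subjects[order[i]], subjects[order[i + 1]])
            for i in range(0, len(subjects), 2)
        ]
        subj = features.data["subject_id"].to_numpy()
        folds = []
        for pair in pairs:
            test = np.flatnonzero(np.isin(subj, pair))
            train = np.flatnonzero(~np.isin(subj, pair))
            folds.append((train, test))
        return FoldPlan(scheme=scheme, folds=folds, seed=seed, subject_pairs=pairs)
    raise ConfigurationError(f"unknown CV scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Fit / predict plumbing
# ---------------------------------------------------------------------------

def _fit_estimator(algorithm, hyperparameters, X, y, seed):
    if np.unique(y).size < 2:
        est = DummyClassifier(strategy="most_frequent")
    else:
        est = make_estimator(algorithm, hyperparameters, seed=seed)
    est.fit(X, y)
    return est


def cross_validated_predictions(
    features: FeatureTable,
    algorithm: str,
    hyperparameters: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
    audit: list | None = None,
    audit_stage: str = "inner_cv",
):
    """Pooled out-of-fold predictions with the per-fold training protocol.

    Within each fold: oversample the training rows, fit normalization on
    them, fit the classifier, normalize (clipped) and predict the test rows.
    Returns (y_true, y_pred) pooled over folds in fold order.
    """
    plan = make_folds(features, "kfold5", seed=seed, n_folds=n_folds)
    ys, ps = [], []
    for f, (tr, te) in enumerate(plan.folds):
        train = features.subset(tr)
        test = features.subset(te)
        train_os = oversample_to_balance(train, seed=seed + 7919 * f)
        params = fit_normalization(train_os)
        if audit is not None:
            audit.append(
                {
                    "stage": f"{audit_stage}:oversample+normalize",
                    "fold": f,
                    "row_ids": set(train_os.row_ids.tolist()),
                    "train_row_ids": set(train.row_ids.tolist()),
                }
            )
        est = _fit_estimator(
            algorithm, hyperparameters,
            apply_normalization(train_os, params).X, train_os.y, seed
        )
        ys.append(test.y)
        ps.append(est.predict(apply_normalization(test, params).X))
    return np.concatenate(ys), np.concatenate(ps).astype(int)


def misclassification_rate(y_true, y_pred) -> float:
    y_true = np.asarray(y_true)
    return float(np.mean(y_true != np.asarray(y_pred)))


def tune_hyperparameters(
    algorithm: str,
    fold1_training: FeatureTable,
    budget: int = 15,
    inner_folds: int = 5,
    seed: int = 0,
    audit: list | None = None,
) -> tuple:
    """Bayesian (GP + expected improvement) tuning on the first fold's data.

    Exactly ``budget`` objective evaluations are spent; the objective is the
    inner cross-validated misclassification rate. Returns
    ``(best_hyperparameters, trace)``.
    """
    if budget < 1:
        raise ConfigurationError("tuning budget must be >= 1")
    space = search_space(algorithm, fold1_training.n)
    if audit is not None:
        audit.append(
            {
                "stage": "tune",
                "fold": 0,
                "row_ids": set(fold1_training.row_ids.tolist()),
                "train_row_ids": set(fold1_training.row_ids.tolist()),
            }
        )

    def objective(params):
        y_true, y_pred = cross_validated_predictions(
            fold1_training, algorithm, params, n_folds=inner_folds, seed=seed
        )
        return misclassification_rate(y_true, y_pred)

    trace = bayesopt.minimize(objective, space, budget=budget, seed=seed)
    return trace.best_params, trace


@dataclass
class TrainedModel:
    """A fitted classifier plus the preprocessing state needed to predict."""

    spec: ModelSpec
    estimator: object
    normalization: NormalizationParams
    feature_columns: list
    training_fold: int = 0

    def predict(self, features: FeatureTable) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in features.feature_columns]
        if missing:
            raise SchemaError(f"prediction input lacks columns: {missing}")
        ft = features.restrict(self.feature_columns)
        return np.asarray(
            self.estimator.predict(apply_normalization(ft, self.normalization).X)
        ).astype(int)


def train_model(
    spec: ModelSpec,
    training: FeatureTable,
    seed: int = 0,
    balance: bool = True,
    normalization: NormalizationParams | None = None,
    training_fold: int = 0,
) -> TrainedModel:
    """Oversample, normalize and fit one classifier on a training partition."""
    ft = training
    if spec.selected_features is not None:
        ft = ft.restrict(spec.selected_features)
    if balance:
        ft = oversample_to_balance(ft, seed=seed)
    params = normalization or fit_normalization(ft)
    est = _fit_estimator(
        spec.algorithm, spec.hyperparameters,
        apply_normalization(ft, params).X, ft.y, seed
    )
    return TrainedModel(
        spec=spec,
        estimator=est,
        normalization=params,
        feature_columns=list(ft.feature_columns),
        training_fold=training_fold,
    )


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Settings of one cross-validated experiment grid."""

    algorithms: tuple = ALGORITHMS
    settings: tuple = SETTINGS
    outer_folds: int = 5
    inner_folds: int = 5
    sfs_budget: int = 20
    tuning_budget: int = 15
    seed: int = 0
    average: str = "macro"
    audit: bool = False


@dataclass
class VariantResult:
    """One (algorithm, setting) variant's cross-validated outcome."""

    spec: ModelSpec
    validation_f1: float
    test_report: EvaluationReport
    fold_validation_f1: list = field(default_factory=list)


@dataclass
class ExperimentResult:
    dataset_id: str
    scheme: str
    n_samples: int
    variants: list = field(default_factory=list)
    best: object = None
    skipped: str | None = None
    audit_log: list = field(default_factory=list)
    fold_plan: FoldPlan | None = None


def _as_feature_table(data) -> FeatureTable:
    if isinstance(data, FeatureTable):
        return data
    return extract_feature_matrix(data)


def _run_grid(ft: FeatureTable, plan: FoldPlan, config: ExperimentConfig,
              dataset_id: str) -> ExperimentResult:
    from .selection import sequential_forward_selection  # avoid import cycle

    audit: list | None = [] if config.audit else None
    result = ExperimentResult(
        dataset_id=dataset_id, scheme=plan.scheme, n_samples=ft.n,
        fold_plan=plan,
    )
    fold1_train = ft.subset(plan.folds[0][0])

    for algorithm in config.algorithms:
        selected = None
        if any("SFS" in s for s in config.settings):
            if audit is not None:
                audit.append(
                    {
                        "stage": "sfs",
                        "fold": 0,
                        "row_ids": set(fold1_train.row_ids.tolist()),
                        "train_row_ids": set(fold1_train.row_ids.tolist()),
                    }
                )
            sfs = sequential_forward_selection(
                fold1_train, algorithm,
                max_evaluations=config.sfs_budget,
                inner_folds=config.inner_folds,
                seed=config.seed,
            )
            selected = sfs.selected or list(ft.feature_columns)
        for setting in config.settings:
            use_selected = selected if "SFS" in setting else None
            sub1 = (
                fold1_train.restrict(use_selected)
                if use_selected is not None else fold1_train
            )
            hp = None
            if "HYP" in setting:
                hp, _ = tune_hyperparameters(
                    algorithm, sub1,
                    budget=config.tuning_budget,
                    inner_folds=config.inner_folds,
                    seed=config.seed,
                    audit=audit,
                )
            spec = ModelSpec(
                algorithm=algorithm, setting=setting,
                hyperparameters=hp, selected_features=use_selected,
            )
            y_true_all, y_pred_all, val_f1s = [], [], []
            for f, (tr, te) in enumerate(plan.folds):
                train = ft.subset(tr)
                test = ft.subset(te)
                if use_selected is not None:
                    train = train.restrict(use_selected)
                    test = test.restrict(use_selected)
                train_os = oversample_to_balance(train, seed=config.seed + 104729 * f)
                params = fit_normalization(train_os)
                if audit is not None:
                    audit.append(
                        {
                            "stage": "train:oversample+normalize",
                            "fold": f,
                            "row_ids": set(train_os.row_ids.tolist()),
                            "train_row_ids": set(train.row_ids.tolist()),
                        }
                    )
                est = _fit_estimator(
                    algorithm, hp,
                    apply_normalization(train_os, params).X, train_os.y,
                    config.seed,
                )
                y_true_all.append(test.y)
                y_pred_all.append(
                    np.asarray(est.predict(apply_normalization(test, params).X))
                )
                # validation: inner CV on this fold's training partition
                vt, vp = cross_validated_predictions(
                    train, algorithm, hp,
                    n_folds=config.inner_folds, seed=config.seed,
                    audit=audit, audit_stage=f"validate_fold{f}",
                )
                val_f1s.append(
                    evaluate_predictions(vt, vp, average=config.average).f1
                )
            report = evaluate_predictions(
                np.concatenate(y_true_all),
                np.concatenate(y_pred_all).astype(int),
                average=config.average,
            )
            result.variants.append(
                VariantResult(
                    spec=spec,
                    validation_f1=float(np.mean(val_f1s)),
                    test_report=report,
                    fold_validation_f1=[float(v) for v in val_f1s],
                )
            )
    result.best = select_best_model(
        result.variants, dataset_id=dataset_id, algorithm_order=config.algorithms
    )
    if audit is not None:
        result.audit_log = audit
    return result


def run_individual_experiment(
    data, config: ExperimentConfig | None = None, dataset_id: str = "individual"
) -> ExperimentResult:
    """5-fold cross-validated grid on one subject's data.

    ``data`` is an ExtremityTable (featurized with the default classes) or a
    ready FeatureTable. Subjects whose windows carry a single score only are
    skipped with a reason rather than trained.
    """
    config = config or ExperimentConfig()
    ft = _as_feature_table(data)
    if np.unique(ft.y).size < 2:
        return ExperimentResult(
            dataset_id=dataset_id, scheme="kfold5", n_samples=ft.n,
            skipped="single-class data",
        )
    plan = make_folds(ft, "kfold5", seed=config.seed, n_folds=config.outer_folds)
    return _run_grid(ft, plan, config, dataset_id)


def run_generalized_experiment(
    data, config: ExperimentConfig | None = None, dataset_id: str = "generalized"
) -> ExperimentResult:
    """Leave-two-subjects-out grid over the pooled cohort."""
    config = config or ExperimentConfig()
    ft = _as_feature_table(data)
    if np.unique(ft.y).size < 2:
        return ExperimentResult(
            dataset_id=dataset_id, scheme="leave_two_subjects_out", n_samples=ft.n,
            skipped="single-class data",
        )
    plan = make_folds(ft, "leave_two_subjects_out", seed=config.seed)
    return _run_grid(ft, plan, config, dataset_id)
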