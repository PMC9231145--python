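"""Feature-class screening and sequential forward feature selection.

Screening measures each candidate feature class alone: its value on each of
the 11 signals forms an 11-dimensional feature vector per window, which is
cross-validated through every classifier family at default hyperparameters;
the class passes if its best macro F1 reaches the threshold (default 0.7).

Sequential forward selection (SFS) is a greedy wrapper: starting from the
empty set it repeatedly scores remaining candidate columns by the inner
cross-validated misclassification rate of the downstream learner and adds
the best one, but only while that strictly decreases the objective. Each
candidate scoring decrements a total evaluation budget (default 20); ties
break toward the lower column index for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .evaluation import evaluate_predictions
from .exceptions import ConfigurationError, ScreeningError
from .features import FeatureTable, extract_feature_matrix
from .preprocess import ExtremityTable


@dataclass
class ScreeningResult:
    """Best single-class F1 per candidate and the pass/fail flags."""

    threshold: float
    best_f1: dict = field(default_factory=dict)
    best_algorithm: dict = field(default_factory=dict)

    @property
    def passed(self) -> dict:
        return {c: f1 >= self.threshold for c, f1 in self.best_f1.items()}

    def passing_classes(self) -> list:
        return [c for c, ok in self.passed.items() if ok]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "best_f1": {c: float(v) for c, v in self.best_f1.items()},
            "best_algorithm": dict(self.best_algorithm),
            "passed": self.passed,
        }


def screen_feature_classes(
    table: ExtremityTable,
    candidate_classes=None,
    algorithms=None,
    threshold: float = 0.7,
    cv_folds: int = 5,
    seed: int = 0,
    sample_rate: float = 60.0,
) -> ScreeningResult:
    """Screen candidate feature classes by single-class predictive power."""
    import numpy as np

    from .features import default_feature_classes
    from .training import ALGORITHMS, cross_validated_predictions

    if candidate_classes is None:
        candidate_classes = default_feature_classes()
    if algorithms is None:
        algorithms = ALGORITHMS
    if np.unique(table.meta["label"]).size < 2:
        raise ScreeningError("screening needs at least two label classes")
    result = ScreeningResult(threshold=float(threshold))
    for cname in candidate_classes:
        ft = extract_feature_matrix(table, [cname], sample_rate=sample_rate)
        best, best_alg = -1.0, None
        for alg in algorithms:
            y_true, y_pred = cross_validated_predictions(
                ft, alg, None, n_folds=cv_folds, seed=seed
            )
            f1 = evaluate_predictions(y_true, y_pred).f1
            if f1 > best:
                best, best_alg = f1, alg
        result.best_f1[cname] = float(best)
        result.best_algorithm[cname] = best_alg
    return result


@dataclass
class SfsResult:
    """Selected columns, the objective after each accepted addition, and
    the number of candidate evaluations spent."""

    selected: list
    objective_trace: list
    evaluations_used: int


def sequential_forward_selection(
    features: FeatureTable,
    learner: str,
    objective=None,
    max_evaluations: int = 20,
    inner_folds: int = 5,
    seed: int = 0,
) -> SfsResult:
    """Greedy forward selection under a total candidate-evaluation budget.

    ``learner`` names the classifier family evaluated inside the wrapper (at
    default hyperparameters); ``objective`` maps pooled (y_true, y_pred) to
    a loss, default misclassification rate. Deterministic given the seed.
    """
    from .training import cross_validated_predictions, misclassification_rate

    if max_evaluations < 1:
        raise ConfigurationError("max_evaluations must be >= 1")
    if objective is None:
        objective = misclassification_rate

    columns = list(features.feature_columns)
    selected: list = []
    trace: list = []
    budget = int(max_evaluations)
    used = 0
    current = float("inf")

    while budget > 0:
        remaining = [c for c in columns if c not in selected]
        if not remaining:
            break
        best_obj, best_col = None, None
        for col in remaining:
            if budget == 0:
                break
            sub = features.restrict(selected + [col])
            y_true, y_pred = cross_validated_predictions(
                sub, learner, None, n_folds=inner_folds, seed=seed
            )
            obj = float(objective(y_true, y_pred))
            budget -= 1
            used += 1
            # strict inequality: ties keep the earlier (lower-index) column
            if best_obj is None or obj < best_obj:
                best_obj, best_col = obj, col
        if best_col is not None and best_obj < current:
            selected.append(best_col)
            trace.append(best_obj)
            current = best_obj
        else:
            break
    return SfsResult(selected=selected, objective_trace=trace,
                     evaluations_used=used)
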