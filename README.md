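# dyskit

Severity estimation of dystonia from home-based wearable inertial sensors.

Children and young adults with dyskinetic cerebral palsy show involuntary
movements (dystonia) whose severity fluctuates over the day and is normally
rated by clinicians watching short videos — a slow, subjective snapshot.
`dyskit` implements the alternative: four inertial measurement units (IMUs)
worn on the forearms and lower legs stream free acceleration, angular
velocity and Euler orientation at 60 Hz; clinicians score each limb on a
0–4 scale per 5-s window (median of three raters); and cross-validated
machine-learning models learn to predict the window score from the sensor
signals. The package is aimed at movement-disorder researchers who want to
build, stress-test or extend such pipelines without access to patient data:
a synthetic cohort generator reproduces the statistical structure of the
recordings (score-dependent movement amplitude, between-subject
heterogeneity, noisy raters, sensor dropouts) so every stage is testable
end to end.

## Method

For each sensor the resultant channels are added to the raw axes,

    a_r = sqrt(a_x² + a_y² + a_z²),    ω_r = sqrt(ω_x² + ω_y² + ω_z²),

giving 11 signals per sensor (44 per timestamp across the four sensors).
Streams are synchronized by linear interpolation onto a uniform 60 Hz grid
over their common overlap and cut into non-overlapping 5-s windows
(300 samples), indexed to match the clinical scoring windows. Each
(window, limb) sample is featurized from its own limb's sensor with ten
feature classes per signal — absolute harmonic mean, absolute maximum,
bandpower (FFT), geometric mean, maximum, median, minimum, root-mean-square,
root-sum-of-squares and Shannon entropy — i.e. 110 features per sample,
min–max normalized to [0, 1] on the training partition.

Six classifier families (decision tree, discriminant analysis, naive Bayes,
SVM, k-NN, ensemble) are trained under four settings: all features (ALL),
all features plus Bayesian hyperparameter tuning with 15 objective
evaluations on the first fold (ALL+HYP), sequential forward feature
selection with a 20-evaluation budget and misclassification-rate objective
(SFS), and both (SFS+HYP). Training partitions are oversampled to equal
class counts. *Individual* models (one subject's data) are evaluated with
5-fold cross-validation; *generalized* models with leave-two-subjects-out
cross-validation (6 folds over 12 subjects). Models are compared by macro
F1 (precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean),
the winner per dataset chosen by validation F1, and test performance
reported with RMSE and 5×5 confusion matrices.

## Worked example

```python
import dyskit
from dyskit import simulate
from dyskit.training import ExperimentConfig

cohort = simulate.generate_cohort(simulate.CohortConfig(
    n_subjects=2, recordings_per_subject=2, recording_seconds=60.0, seed=3))
upper, lower = dyskit.tables_from_cohort(cohort)
model = dyskit.SeverityModel.from_extremity_table(
    upper.for_subject("subject_01"),
    config=ExperimentConfig(algorithms=("knn", "decision_tree"),
                            settings=("ALL", "SFS"), seed=0))
results = model.fit()
print(results.summary())
```

prints

```
Dystonia severity classification experiment
============================================================
dataset:        upper
scheme:         kfold5
n samples:      48
variants:       4
------------------------------------------------------------
    algorithm model  f1_validation  f1_test  precision_test  recall_test  rmse_test
decision_tree   SFS          0.965    0.948           0.946        0.951      0.250
          knn   ALL          0.939    0.982           0.988        0.978      0.144
          knn   SFS          0.938    0.964           0.964        0.964      0.204
decision_tree   ALL          0.914    0.931           0.930        0.938      0.289
------------------------------------------------------------
best model:     decision_tree (SFS)
validation F1:  0.965
test F1:        0.948   precision: 0.946   recall: 0.951
test RMSE:      0.250
adjacent-error fraction: 1.000
```

Each leaderboard row is one (algorithm, setting) variant: `f1_validation`
is the mean inner-cross-validated macro F1 on the training partitions and
`f1_test` the macro F1 of the pooled out-of-fold test predictions. The
winner is chosen by validation F1 (never by test F1). The adjacent-error
fraction says what share of the remaining misclassifications landed in a
neighbouring severity score — here all of them, the expected signature of
an ordinal severity scale. `results.plot_confusion()` renders the test
confusion matrix; `SeverityModel(..., scheme="leave_two_subjects_out")`
runs the generalized (cross-subject) evaluation instead.

A full configuration-driven run (simulate → ingest → window → featurize →
train → evaluate, with a leaderboard CSV, JSON reports and a reproducibility
manifest) is available from the shell:

```bash
dyskit simulate --out cohort --seed 1
dyskit run --config run.yaml --out results_dir --seed 1
```

where `run.yaml` selects cohort sizes and the model grid, e.g.

```yaml
simulate: {n_subjects: 4, recordings_per_subject: 2, recording_seconds: 60.0}
algorithms: [knn, decision_tree]
settings: [ALL, SFS]
```

(with no config, `dyskit run` executes the full 24-variant protocol on a
12-subject cohort — correct, but slow on a laptop).

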