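"""Configuration-driven orchestration: simulate -> ingest -> preprocess ->
featurize -> train -> evaluate -> report.

``run_experiment`` executes the enabled stages in order into a run
directory, writing a leaderboard CSV, per-dataset JSON reports, an exclusion
log mirroring the data-loss accounting of home recordings, and a manifest
with the full effective configuration and SHA-256 hashes of every artifact.
Reruns with an identical configuration produce identical artifacts and an
identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .evaluation import summarize_experiments
from .exceptions import ConfigurationError, UnsynchronizableRecordingError
from .features import default_feature_classes, extract_feature_matrix
from .ingest import read_annotation_csv, read_sensor_csv, synchronize_streams
from .model import SeverityModel
from .preprocess import windowed_tables_from_recordings
from .simulate import CohortConfig, generate_cohort, write_cohort
from .training import ALGORITHMS, SETTINGS, ExperimentConfig


@dataclass
class RunConfig:
    """Every effective parameter of one pipeline run.

    Defaults reproduce the reference protocol: 60 Hz sampling, 5-s windows
    (300 samples), the 10-class feature catalogue (110 features), screening
    threshold 0.7, SFS budget 20, tuning budget 15, 5-fold CV for individual
    models and leave-two-subjects-out for generalized models.
    """

    seed: int = 0
    simulate: dict | None = field(default_factory=dict)  # CohortConfig kwargs
    data_dir: str | None = None  # existing cohort (manifest.json inside)
    window_seconds: float = 5.0
    sample_rate: float = 60.0
    min_recording_seconds: float = 5.0
    feature_classes: tuple = ()
    screening_threshold: float = 0.7
    sfs_budget: int = 20
    tuning_budget: int = 15
    outer_folds: int = 5
    inner_folds: int = 5
    algorithms: tuple = ALGORITHMS
    settings: tuple = SETTINGS
    extremities: tuple = ("upper", "lower")
    run_individual: bool = True
    run_generalized: bool = True
    average: str = "macro"

    def __post_init__(self) -> None:
        if not self.feature_classes:
            self.feature_classes = default_feature_classes()
        if self.simulate is None and self.data_dir is None:
            raise ConfigurationError("either simulate or data_dir must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("feature_classes", "algorithms", "settings", "extremities"):
            d[k] = list(d[k])
        return d

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            algorithms=tuple(self.algorithms),
            settings=tuple(self.settings),
            outer_folds=self.outer_folds,
            inner_folds=self.inner_folds,
            sfs_budget=self.sfs_budget,
            tuning_budget=self.tuning_budget,
            seed=self.seed,
            average=self.average,
        )


def load_cohort_dir(data_dir):
    """Read a cohort directory (manifest + CSVs) into synchronized recordings.

    Returns ``(recordings, annotations, log)``; recordings that cannot be
    synchronized are excluded and counted, mirroring real data loss.
    """
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    annotations = read_annotation_csv(data_dir / manifest["annotations"])
    recordings = []
    log = {"recordings_total": len(manifest["recordings"]),
           "recordings_unsynchronizable": 0, "recordings_degraded": 0}
    for entry in manifest["recordings"]:
        streams = {
            loc: read_sensor_csv(data_dir / rel, location=loc)
            for loc, rel in entry["sensors"].items()
        }
        try:
            rec = synchronize_streams(
                streams,
                nominal_rate=entry.get("nominal_rate", 60.0),
                recording_id=entry["recording_id"],
                subject_id=entry["subject_id"],
            )
        except UnsynchronizableRecordingError:
            log["recordings_unsynchronizable"] += 1
            continue
        if rec.degraded:
            log["recordings_degraded"] += 1
        recordings.append(rec)
    return recordings, annotations, log


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: RunConfig, out_dir) -> dict:
    """Run the enabled stages; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: dict = {}

    # -- simulate ---------------------------------------------------------
    if config.data_dir is not None:
        data_dir = Path(config.data_dir)
    else:
        cohort_cfg = CohortConfig(
            seed=config.seed,
            sample_rate=config.sample_rate,
            **{k: v for k, v in (config.simulate or {}).items() if k not in
               ("seed", "sample_rate")},
        )
        cohort = generate_cohort(cohort_cfg)
        data_dir = out / "cohort"
        write_cohort(cohort, data_dir)
        stage_log["simulate"] = {
            "n_subjects": cohort_cfg.n_subjects,
            "n_recordings": len(cohort.recordings),
            "windows_per_recording": cohort_cfg.windows_per_recording,
        }

    # -- ingest -----------------------------------------------------------
    recordings, annotations, ingest_log = load_cohort_dir(data_dir)
    stage_log["ingest"] = ingest_log

    # -- preprocess + featurize ------------------------------------------
    upper, lower, exclusions = windowed_tables_from_recordings(
        recordings, annotations, window_seconds=config.window_seconds,
        strict=False,
    )
    stage_log["preprocess"] = {
        "samples_per_window": int(round(config.sample_rate * config.window_seconds)),
        "rows_upper": upper.n_rows,
        "rows_lower": lower.n_rows,
        "exclusions": exclusions,
    }
    pd.DataFrame([exclusions]).to_csv(out / "exclusion_log.csv", index=False)

    tables = {"upper": upper, "lower": lower}
    exp_cfg = config.experiment_config()
    leaderboard_rows = []
    reports: dict = {}
    summaries: dict = {}

    for extremity in config.extremities:
        table = tables[extremity]
        if table.n_rows == 0:
            continue
        ft = extract_feature_matrix(
            table, config.feature_classes, sample_rate=config.sample_rate
        )
        ft.to_csv(out / f"features_{extremity}.csv")
        if config.run_individual:
            best_records = []
            for subject in sorted(table.meta["subject_id"].unique()):
                sub_ft = ft.subset(
                    (ft.data["subject_id"] == subject).to_numpy().nonzero()[0]
                )
                res = SeverityModel(
                    sub_ft, scheme="kfold5", config=exp_cfg,
                    dataset_id=f"{extremity}:{subject}",
                ).fit()
                if res.skipped:
                    reports[f"individual_{extremity}_{subject}"] = {
                        "skipped": res.skipped
                    }
                    continue
                best_records.append(res.best)
                lb = res.leaderboard.copy()
                lb.insert(0, "subject", subject)
                lb.insert(1, "scope", "individual")
                leaderboard_rows.append(lb)
                reports[f"individual_{extremity}_{subject}"] = {
                    "best": {
                        "algorithm": res.best.algorithm,
                        "setting": res.best.setting,
                        "validation_f1": res.best.validation_f1,
                        "test_f1": res.best.test_f1,
                    },
                    "test_report": res.report.to_dict(),
                }
            if best_records:
                summaries[f"individual_{extremity}"] = (
                    summarize_experiments(best_records)
                    .round(6)
                    .to_dict()
                )
        if config.run_generalized:
            n_subjects = table.meta["subject_id"].nunique()
            if n_subjects >= 4 and n_subjects % 2 == 0:
                res = SeverityModel(
                    ft, scheme="leave_two_subjects_out", config=exp_cfg,
                    dataset_id=f"{extremity}:generalized",
                ).fit()
                if not res.skipped:
                    lb = res.leaderboard.copy()
                    lb.insert(0, "subject", "all")
                    lb.insert(1, "scope", "generalized")
                    leaderboard_rows.append(lb)
                    reports[f"generalized_{extremity}"] = {
                        "best": {
                            "algorithm": res.best.algorithm,
                            "setting": res.best.setting,
                            "validation_f1": res.best.validation_f1,
                            "test_f1": res.best.test_f1,
                        },
                        "test_report": res.report.to_dict(),
                    }

    if leaderboard_rows:
        leaderboard = pd.concat(leaderboard_rows, ignore_index=True)
        leaderboard.to_csv(out / "leaderboard.csv", index=False)
    (out / "reports.json").write_text(
        json.dumps(reports, indent=2, sort_keys=True)
    )
    if summaries:
        (out / "summary.json").write_text(
            json.dumps(summaries, indent=2, sort_keys=True)
        )

    artifacts = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    hashes = {a: _sha256(out / a) for a in artifacts}
    overall = hashlib.sha256(
        json.dumps(hashes, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": config.to_dict(),
        "stages": stage_log,
        "artifacts": hashes,
        "run_hash": overall,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
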