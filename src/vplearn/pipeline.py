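"""End-to-end orchestration: simulate the study, estimate thresholds,
decompose equivalent noise, fit learning curves and screen the data, writing
every product plus a reproducibility manifest."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import equivalent_noise as en
from .learning import LearningCurveModel
from .observers import SimulatedStudy, StudyConfig, simulate_study
from .screening import double_mad_outliers, summarize_condition
from .staircase import ThresholdEstimate
from .tables import write_threshold_table, write_trial_table

__all__ = ["RunConfig", "run_pipeline", "en_table_from_thresholds",
           "screening_report_from_thresholds"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: seed, study layout, calibration and outputs."""

    master_seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    calibration_k: float = en.K_GAUSSIAN
    mad_multiplier: float = 3.0
    output_dir: str = "vplearn_out"
    verbosity: int = 1

    def __post_init__(self):
        if not (isinstance(self.master_seed, (int, np.integer)) and self.master_seed >= 0):
            raise ValueError(f"master_seed must be a non-negative integer, got {self.master_seed}")
        # carry the pipeline seed into the study layout
        if self.study.master_seed != self.master_seed:
            object.__setattr__(
                self, "study",
                dataclasses.replace(self.study, master_seed=self.master_seed),
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study"]["trajectory"] = dataclasses.asdict(self.study.trajectory)
        d["study"]["eta"] = {f"{s}:{p}": v for (s, p), v in self.study.eta.items()}
        d["study"]["sigma_int"] = {f"{s}:{p}": v for (s, p), v in self.study.sigma_int.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        study = d.pop("study", None)
        if study is not None:
            study = dict(study)
            if "trajectory" in study:
                from .observers import LearningTrajectory

                study["trajectory"] = LearningTrajectory(**study["trajectory"])
            for key in ("eta", "sigma_int"):
                if key in study:
                    study[key] = {
                        tuple(k.split(":")): v for k, v in study[key].items()
                    }
            d["study"] = StudyConfig(**study)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # analysis-irrelevant presentation fields
        d.pop("verbosity", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def en_table_from_thresholds(
    thresholds: pd.DataFrame, calibration_k: float = en.K_GAUSSIAN
) -> pd.DataFrame:
    """Equivalent-noise decomposition per participant x stimulus x session
    from the per-block threshold summary (measures 'tilt' and 'sigma_ext')."""
    rows = []
    sub = thresholds[thresholds["task"] == "equivalent_noise"]
    keys = ["participant", "stimulus", "session"]
    for (participant, stimulus, session), grp in sub.groupby(keys):
        by_measure = grp.set_index("measure")
        if not {"tilt", "sigma_ext"}.issubset(by_measure.index):
            continue
        zero = by_measure.loc["tilt"]
        high = by_measure.loc["sigma_ext"]
        if np.isnan(zero["threshold"]) or np.isnan(high["threshold"]):
            continue
        results = en.EquivalentNoiseModel.from_thresholds(
            ThresholdEstimate(zero["threshold"], zero["spread"], 0),
            ThresholdEstimate(high["threshold"], high["spread"], 0),
            calibration_k=calibration_k,
        ).fit()
        row = {"participant": participant, "stimulus": stimulus, "session": session}
        row.update(results.to_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def screening_report_from_thresholds(
    thresholds: pd.DataFrame, mad_multiplier: float = 3.0
) -> dict:
    """Double-MAD flags and descriptives for the pre/post coherence
    thresholds, per stimulus x session condition."""
    tests = thresholds[
        (thresholds["task"] == "coherence")
        & thresholds["session"].isin([thresholds["session"].min(),
                                      thresholds["session"].max()])
    ]
    report = {}
    for (stimulus, session), grp in tests.groupby(["stimulus", "session"]):
        values = grp["threshold"].dropna().to_numpy()
        if len(values) < 3:
            continue
        screen = double_mad_outliers(values, mad_multiplier)
        mean, sem, skew = summarize_condition(values)
        report[f"{stimulus}:session{session}"] = {
            "n": int(len(values)),
            "mean": mean,
            "sem": sem,
            "skewness": skew,
            "left_mad": screen.left_mad,
            "right_mad": screen.right_mad,
            "n_outliers": int(screen.flags.sum()),
            "outlier_values": [float(v) for v in values[screen.flags]],
        }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the products under config.output_dir.

    Returns the analysis report (also written as report.json). Any stage
    failure aborts with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    study: SimulatedStudy = stage("simulate", lambda: simulate_study(config.study))
    stage("write-trials", lambda: write_trial_table(study.trials, out / "trials.csv"))
    stage("write-thresholds",
          lambda: write_threshold_table(study.thresholds, out / "thresholds.csv"))

    en_table = stage(
        "equivalent-noise",
        lambda: en_table_from_thresholds(study.thresholds, config.calibration_k),
    )
    stage("write-en", lambda: en_table.to_csv(out / "en_estimates.csv", index=False))

    learning = stage(
        "learning-curve",
        lambda: LearningCurveModel.from_study(study.thresholds, "gp").fit(),
    )
    stage("write-learning", lambda: (out / "learning_curve.json").write_text(
        json.dumps(learning.to_dict(), indent=2)
    ))

    screening = stage(
        "screening",
        lambda: screening_report_from_thresholds(study.thresholds, config.mad_multiplier),
    )
    stage("write-screening", lambda: (out / "screening.json").write_text(
        json.dumps(screening, indent=2)
    ))

    manifest = {
        "seed": config.master_seed,
        "vplearn_version": __version__,
        "config_hash": config.config_hash(),
        "outputs": ["trials.csv", "thresholds.csv", "en_estimates.csv",
                    "learning_curve.json", "screening.json", "report.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    report = {
        "manifest": manifest,
        "n_trials": int(len(study.trials)),
        "learning_curve": learning.to_dict(),
        "screening": screening,
        "en_group_means": {
            f"{stim}:session{int(sess)}": {
                "eta": float(grp["eta"].mean()),
                "sigma_int": float(grp["sigma_int"].mean()),
            }
            for (stim, sess), grp in en_table.groupby(["stimulus", "session"])
        } if not en_table.empty else {},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
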