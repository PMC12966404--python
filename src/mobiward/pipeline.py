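"""End-to-end run: cohort → bed-day scenarios → prediction → report files.

``run_pipeline`` writes everything into one output directory and records a
manifest (inputs, parameters, output files with SHA-256 hashes) so a run
can be audited and reproduced.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .bedsim import scenario_suite
from .cohort import Cohort, first_sae_day, is_early_sae
from .fixture import build_fixture_cohort, verify_marginals
from .generator import GeneratorParams, make_ml_dataset, sample_cohort
from .io import write_cohort
from .prediction import run_classification, run_onset_regression

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    out_dir: Path
    cohort_source: str = Field(default="synthetic", pattern="^(synthetic|fixture)$")
    n_patients: int = Field(default=109, ge=10)
    seed: int = 0
    n_boot: int = Field(default=2000, ge=2)
    endpoint: str = Field(default="any_sae", pattern="^(any_sae|mri|fever|transfusion)$")
    feature_set: str = Field(default="clinical", pattern="^(clinical|mi_extended|longitudinal)$")
    classifier_folds: int = Field(default=5, ge=2)
    regression_folds: int = Field(default=3, ge=2)
    run_prediction: bool = True
    make_figures: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_cohort(config: PipelineConfig) -> Cohort:
    if config.cohort_source == "fixture":
        return build_fixture_cohort(seed=config.seed)
    params = GeneratorParams(n_patients=config.n_patients, seed=config.seed)
    return sample_cohort(params)


def _cohort_summary(cohort: Cohort) -> dict:
    n = len(cohort.patients)
    n_sae = sum(1 for p in cohort.patients if first_sae_day(p) is not None)
    n_early = sum(1 for p in cohort.patients if is_early_sae(p))
    return {
        "n_patients": n,
        "n_with_sae": n_sae,
        "pct_with_sae": round(100.0 * n_sae / n, 2),
        "n_early_sae": n_early,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    cohort = _build_cohort(config)
    cohort_path = out / "cohort.json"
    write_cohort(cohort, cohort_path, format="json")
    outputs.append(cohort_path)

    extras: dict = {}
    if config.cohort_source == "fixture":
        report = verify_marginals(cohort)
        marg_path = out / "fixture_marginals.csv"
        report.to_frame().to_csv(marg_path, index=False)
        outputs.append(marg_path)
        extras["fixture_marginals_passed"] = bool(report.passed)

    suite = scenario_suite(cohort, n_boot=config.n_boot, seed=config.seed)
    suite_path = out / "scenario_suite.csv"
    suite.to_csv(suite_path, index=False)
    outputs.append(suite_path)

    if config.run_prediction:
        X, y, onsets = make_ml_dataset(
            cohort, endpoint=config.endpoint, feature_set=config.feature_set
        )
        clf_reports = run_classification(
            X, y, endpoint=config.endpoint,
            n_folds=config.classifier_folds, seed=config.seed,
        )
        clf_frame = pd.concat([r.to_frame() for r in clf_reports], ignore_index=True)
        clf_path = out / "classification_cv.csv"
        clf_frame.to_csv(clf_path, index=False)
        outputs.append(clf_path)
        extras["classification"] = {
            r.model_name: {"accuracy": r.mean_accuracy, "roc_auc": r.mean_roc_auc,
                           "mcc": r.mean_mcc}
            for r in clf_reports
        }
        reg_reports = run_onset_regression(
            X, onsets, endpoint=config.endpoint,
            n_folds=config.regression_folds, seed=config.seed,
        )
        reg_frame = pd.DataFrame([
            {"endpoint": r.endpoint, "model": r.model_name,
             "mad_days": r.mad_days, "rmsd_days": r.rmsd_days}
            for r in reg_reports
        ])
        reg_path = out / "onset_regression.csv"
        reg_frame.to_csv(reg_path, index=False)
        outputs.append(reg_path)
        extras["onset_regression"] = {
            r.model_name: {"mad_days": r.mad_days, "rmsd_days": r.rmsd_days}
            for r in reg_reports
        }

    if config.make_figures:
        import matplotlib.pyplot as plt

        from .plots import plot_event_profile, plot_scenario_fractions

        for name, plotter, arg in (
            ("event_profile.png", plot_event_profile, cohort),
            ("scenario_fractions.png", plot_scenario_fractions, suite),
        ):
            ax = plotter(arg)
            fig_path = out / name
            ax.figure.savefig(fig_path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
            outputs.append(fig_path)

    manifest = {
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": json.loads(config.model_dump_json()),
        "cohort": _cohort_summary(cohort),
        **extras,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                       encoding="utf-8")
    return manifest
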