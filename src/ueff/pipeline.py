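"""End-to-end orchestration: cohorts → calibration → validation → reports.

One call reproduces the full analysis workflow: obtain a training cohort
(CSV or synthetic), fit the three exponential calibrations, cross-validate
them, predict UEFF with the chosen model, transfer-test frozen models on an
external cohort, compare UEFF across steatosis grades, and run the ROC
analyses for the ≥5 % and ≥10 % fat-fraction classifications. The report
bundle mirrors the four standard table shapes (cohort distributions, linear
screens, model performance, diagnostic performance) and is byte-reproducible
from the seeds it records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, ModelKind, model_diagnostics, predict_ueff
from .cohort import Cohort, load_cohort
from .diagnostics import RocResult, evaluate_classifier
from .grading import DEFAULT_THRESHOLDS, GradeThresholds, steatosis_grade
from .stats import fit_linear_models, kruskal_wallis_dunn, pearson_with_ci, simple_linreg
from .synthetic import SyntheticConfig, generate_cohort, summarize_cohort
from .validation import external_test, fit_model, repeated_kfold_cv

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

_MODEL_KINDS = (ModelKind.AC, ModelKind.BSCD, ModelKind.COMBINED)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one input source per cohort."""

    train_path: str | Path | None = None
    train_synthetic: SyntheticConfig | None = None
    test_path: str | Path | None = None
    test_synthetic: SyntheticConfig | None = None
    ueff_model: ModelKind = ModelKind.COMBINED
    cv_k: int = 3
    cv_repeats: int = 5
    cv_seed: int = 0
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS
    alpha: float = 0.05
    j_definition: str = "youden"
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.train_path is None) == (self.train_synthetic is None):
            raise ValueError("exactly one training input source required")
        if self.test_path is not None and self.test_synthetic is not None:
            raise ValueError("at most one test input source")


def _resolve(path, synth, fallback_label: str) -> Cohort | None:
    if path is not None:
        return load_cohort(path, label=fallback_label)
    if synth is not None:
        return generate_cohort(synth)
    return None


def _summary_block(cohort: Cohort) -> dict:
    s = summarize_cohort(cohort)
    return {
        "label": cohort.label,
        "n": s.n,
        "variables": s.variables.to_dict(orient="records"),
        "grades": s.grades.to_dict(orient="records"),
    }


def _roc_tasks(cohort: Cohort, thresholds: GradeThresholds, alpha: float,
               j_definition: str) -> dict[str, RocResult]:
    ueff = cohort.column("ueff")
    pdff = cohort.column("pdff")
    out = {}
    for cut_name, cut in (("ge5", thresholds.steatosis_cuts[0]),
                          ("ge10", thresholds.steatosis_cuts[1])):
        labels = (pdff >= cut).astype(int)
        if labels.min() == labels.max():
            continue
        out[cut_name] = evaluate_classifier(
            ueff, labels, alpha=alpha, j_definition=j_definition
        )
    return out


def _grade_comparison(cohort: Cohort, thresholds: GradeThresholds) -> dict:
    ueff = cohort.column("ueff")
    grades = np.array([steatosis_grade(r.pdff, thresholds) for r in cohort])
    res = kruskal_wallis_dunn(ueff, grades)
    return {
        "h": res.h,
        "p_value": res.p_value,
        "pairwise": res.pairwise.to_dict(orient="records"),
        "per_grade": [
            {
                "grade": int(g),
                "n": int((grades == g).sum()),
                "ueff_mean": float(ueff[grades == g].mean()) if (grades == g).any() else None,
                "ueff_sd": float(ueff[grades == g].std(ddof=1))
                if (grades == g).sum() > 1 else None,
            }
            for g in range(4)
        ],
    }


def _cohort_analysis(cohort: Cohort, config: PipelineConfig) -> dict:
    """Per-cohort post-prediction analyses (correlation, grades, ROC, screen)."""
    ueff = cohort.column("ueff")
    pdff = cohort.column("pdff")
    corr = pearson_with_ci(ueff, pdff, config.alpha)
    slope, intercept, p_slope = simple_linreg(ueff, pdff)
    block = {
        "summary": _summary_block(cohort),
        "ueff_pdff_correlation": dataclasses.asdict(corr),
        "ueff_pdff_line": {"slope": slope, "intercept": intercept, "p": p_slope},
        "grade_comparison": _grade_comparison(cohort, config.thresholds),
        "roc": {k: v.to_dict() for k, v in
                _roc_tasks(cohort, config.thresholds, config.alpha,
                           config.j_definition).items()},
    }
    try:
        block["linear_screen"] = fit_linear_models(cohort).table.to_dict(orient="records")
    except ValueError:
        block["linear_screen"] = None  # e.g. missing BMI column
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the (JSON-serializable) report bundle."""
    train = _resolve(config.train_path, config.train_synthetic, "train")
    test = _resolve(config.test_path, config.test_synthetic, "test")

    models: dict[str, CalibrationModel] = {
        kind.value: fit_model(train, kind) for kind in _MODEL_KINDS
    }
    cv = {
        kind.value: repeated_kfold_cv(
            train, kind, k=config.cv_k, repeats=config.cv_repeats, seed=config.cv_seed
        ).to_dict()
        for kind in _MODEL_KINDS
    }

    performance = {"cross_validation": cv, "in_sample": {}, "external": {}}
    for name, model in models.items():
        d = model_diagnostics(model, train)
        performance["in_sample"][name] = dataclasses.asdict(d)
    if test is not None:
        for name, model in models.items():
            diag, corr = external_test(model, test)
            performance["external"][name] = {
                "diagnostics": dataclasses.asdict(diag),
                "correlation": dataclasses.asdict(corr),
            }

    chosen = models[config.ueff_model.value]
    train_pred = predict_ueff(chosen, train)
    report = {
        "config": {
            "ueff_model": config.ueff_model.value,
            "cv": {"k": config.cv_k, "repeats": config.cv_repeats, "seed": config.cv_seed},
            "alpha": config.alpha,
            "j_definition": config.j_definition,
            "steatosis_cuts": list(config.thresholds.steatosis_cuts),
            "fibrosis_cuts": list(config.thresholds.fibrosis_cuts),
            "train_source": str(config.train_path or config.train_synthetic.to_json()),
            "test_source": str(config.test_path or
                               (config.test_synthetic.to_json() if config.test_synthetic else None)),
        },
        "models": {name: json.loads(m.to_json()) for name, m in models.items()},
        "performance": performance,
        "train": _cohort_analysis(train_pred, config),
    }
    if test is not None:
        test_pred = predict_ueff(chosen, test)
        report["test"] = _cohort_analysis(test_pred, config)

    if config.outdir is not None:
        write_report(report, config.outdir)
    return report


def _frame(records) -> pd.DataFrame:
    return pd.DataFrame(records)


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write the bundle: full-precision JSON plus 6-significant-digit CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, index=False, float_format="%.6g")

    summaries = []
    rocs = []
    comparisons = []
    screens = []
    for side in ("train", "test"):
        if side not in report:
            continue
        block = report[side]
        sm = _frame(block["summary"]["variables"])
        sm.insert(0, "cohort", block["summary"]["label"])
        summaries.append(sm)
        for task, r in block["roc"].items():
            rocs.append({"cohort": block["summary"]["label"], "task": task, **r})
        cmp_df = _frame(block["grade_comparison"]["pairwise"])
        cmp_df.insert(0, "cohort", block["summary"]["label"])
        comparisons.append(cmp_df)
        if block.get("linear_screen"):
            sc = _frame(block["linear_screen"])
            sc.insert(0, "cohort", block["summary"]["label"])
            screens.append(sc)
    _write(pd.concat(summaries, ignore_index=True), "cohort_summary.csv")
    if rocs:
        _write(_frame(rocs), "diagnostic_performance.csv")
    _write(pd.concat(comparisons, ignore_index=True), "grade_comparisons.csv")
    if screens:
        _write(pd.concat(screens, ignore_index=True), "linear_models.csv")

    perf_rows = []
    for kind, cvd in report["performance"]["cross_validation"].items():
        row = {
            "model": kind,
            "cv_adj_r2_mean": cvd["mean_adj_r2"],
            "cv_adj_r2_sd": cvd["sd_adj_r2"],
            "cv_rmse_mean": cvd["mean_rmse"],
            "cv_rmse_sd": cvd["sd_rmse"],
        }
        ext = report["performance"]["external"].get(kind)
        if ext:
            row.update(
                ext_adj_r2=ext["diagnostics"]["adj_r2"],
                ext_rmse=ext["diagnostics"]["rmse"],
                ext_rho=ext["correlation"]["rho"],
                ext_rho_ci_low=ext["correlation"]["ci_low"],
                ext_rho_ci_high=ext["correlation"]["ci_high"],
            )
        perf_rows.append(row)
    _write(_frame(perf_rows), "model_performance.csv")
    return outdir
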