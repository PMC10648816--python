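"""Repeated k-fold cross-validation and frozen-model external testing.

The calibration is validated two ways: 3-fold cross-validation repeated five
times on the training cohort (15 held-out-fold evaluations, summarized as
mean ± SD of adjusted R² and RMSE), and a frozen-model transfer test in which
the model fitted on one etiology (NAFLD) is applied without refitting to the
other (MAFLD). Partitioning is a plain seeded shuffle — no stratification —
with fold sizes differing by at most one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    CalibrationModel,
    FitDiagnostics,
    FitError,
    ModelKind,
    diagnostics_from_predictions,
    fit_combined_model,
    fit_single_model,
    model_diagnostics,
)
from .cohort import Cohort
from .stats import CorrelationResult, pearson_with_ci

__all__ = ["CvResult", "fit_model", "repeated_kfold_cv", "external_test", "kfold_indices"]


def fit_model(cohort: Cohort, kind: ModelKind | str) -> CalibrationModel:
    """Fit the requested calibration (AC, BSCD or COMBINED) on a cohort."""
    kind = ModelKind(kind)
    y = cohort.column("pdff")
    if kind is ModelKind.COMBINED:
        return fit_combined_model(cohort.column("ac"), cohort.column("bscd"), y)
    x = cohort.column("ac") if kind is ModelKind.AC else cohort.column("bscd")
    return fit_single_model(x, y, kind)


@dataclass
class CvResult:
    """Aggregated held-out-fold diagnostics of a repeated k-fold scheme."""

    fold_diagnostics: list[FitDiagnostics]
    mean_adj_r2: float
    sd_adj_r2: float
    mean_rmse: float
    sd_rmse: float
    k: int
    repeats: int
    seed: int
    n_failed_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "mean_adj_r2": self.mean_adj_r2,
            "sd_adj_r2": self.sd_adj_r2,
            "mean_rmse": self.mean_rmse,
            "sd_rmse": self.sd_rmse,
            "n_failed_folds": self.n_failed_folds,
            "folds": [
                {"adj_r2": d.adj_r2, "rmse": d.rmse, "n": d.n} for d in self.fold_diagnostics
            ],
        }


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """One shuffled partition of range(n) into k folds, sizes within 1."""
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def repeated_kfold_cv(
    cohort: Cohort,
    model_kind: ModelKind | str,
    k: int = 3,
    repeats: int = 5,
    seed: int = 0,
) -> CvResult:
    """k-fold cross-validation repeated ``repeats`` times with fresh shuffles.

    Per repeat the cohort is partitioned into k disjoint near-equal folds;
    the model is fitted on k−1 folds and scored on the held-out fold.
    Aggregates are the mean and sample SD (n−1) over all k·repeats fold
    diagnostics. Folds whose fit fails to converge are excluded from the
    aggregate but counted and reported with a warning, never silently.
    """
    n = len(cohort)
    if n < 3 * k:
        raise ValueError(f"need n ≥ 3k for meaningful folds (n={n}, k={k})")
    rng = np.random.default_rng(seed)
    diags: list[FitDiagnostics] = []
    failed = 0
    for rep in range(repeats):
        folds = kfold_indices(n, k, rng)
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            train = cohort.subset(np.flatnonzero(mask))
            test = cohort.subset(fold)
            try:
                model = fit_model(train, model_kind)
            except FitError as exc:
                failed += 1
                warnings.warn(f"repeat {rep}: fold fit failed ({exc}); excluded", stacklevel=2)
                continue
            diags.append(model_diagnostics(model, test))
    if not diags:
        raise FitError("every cross-validation fold failed to converge")
    adj = np.array([d.adj_r2 for d in diags])
    rmse = np.array([d.rmse for d in diags])
    ddof = 1 if len(diags) > 1 else 0
    return CvResult(
        fold_diagnostics=diags,
        mean_adj_r2=float(adj.mean()),
        sd_adj_r2=float(adj.std(ddof=ddof)),
        mean_rmse=float(rmse.mean()),
        sd_rmse=float(rmse.std(ddof=ddof)),
        k=k,
        repeats=repeats,
        seed=seed,
        n_failed_folds=failed,
    )


def external_test(
    model: CalibrationModel, cohort: Cohort
) -> tuple[FitDiagnostics, CorrelationResult]:
    """Apply a frozen fitted model to an external cohort — no refitting.

    Returns the fit diagnostics and the Pearson correlation (with Fisher-z
    CI) between the model's predictions and observed MRI-PDFF. Disjointness
    from the training data is the caller's responsibility (cohort labels
    carry provenance for asserting it).
    """
    if not model.fit_meta.converged:
        raise FitError("refusing to test a non-converged model")
    y = cohort.column("pdff")
    yhat = model.predict(ac=cohort.column("ac"), bscd=cohort.column("bscd"))
    diag = diagnostics_from_predictions(y, yhat, model.n_predictors)
    corr = pearson_with_ci(yhat, y)
    return diag, corr
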