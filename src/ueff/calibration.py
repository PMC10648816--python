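"""Exponential non-linear least-squares calibration of MRI-PDFF on QUS.

The core model is a saturating exponential in the QUS predictor,

    PDFF = β1 · exp(β2 · x) + β3,

fitted by iterative least squares for the attenuation coefficient (AC), the
backscatter-distribution coefficient (BSC-D), or both combined; the combined
model is the additive two-exponential with a shared offset,

    PDFF = β1 · exp(β2 · AC) + β3 · exp(β4 · BSC-D) + β5,

so each predictor keeps the marginal shape of its single-predictor law.
The fitted combined model defines the ultrasound-estimated fat fraction
(UEFF): its prediction for each subject, deliberately left unclipped —
a slightly negative UEFF for a fat-free liver is meaningful output.

Start values come from log-linearization: with β3 anchored just below
min(y), ordinary least squares of ln(y − β3) on x gives β2 (slope) and β1
(exp of intercept). Convergence is declared when the relative SSE change
falls below 1e-10 (up to 500 iterations); both are recorded in the fit
metadata.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .cohort import Cohort

__all__ = [
    "ModelKind",
    "FitMeta",
    "CalibrationModel",
    "FitDiagnostics",
    "FitError",
    "DegenerateInputError",
    "fit_single_model",
    "fit_combined_model",
    "predict_ueff",
    "model_diagnostics",
]

SSE_RTOL = 1e-10
MAX_ITER = 500


def _json_text(source) -> str:
    """JSON text from either a literal string or a file path."""
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    return s if s.lstrip().startswith("{") else Path(s).read_text()


class ModelKind(str, enum.Enum):
    AC = "AC"
    BSCD = "BSCD"
    COMBINED = "COMBINED"


class FitError(RuntimeError):
    """Non-convergence of the iterative least-squares fit."""


class DegenerateInputError(ValueError):
    """Constant or collinear predictors make the model unidentifiable."""


@dataclass(frozen=True)
class FitMeta:
    converged: bool
    iterations: int
    sse: float
    start_values: tuple[float, ...]
    message: str = ""
    ill_conditioned: bool = False


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted exponential calibration; the object that defines UEFF."""

    kind: ModelKind
    coefficients: tuple[float, ...]
    fit_meta: FitMeta

    def __post_init__(self) -> None:
        expected = 5 if self.kind is ModelKind.COMBINED else 3
        if len(self.coefficients) != expected:
            raise ValueError(
                f"{self.kind.value} model needs {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )

    @property
    def n_predictors(self) -> int:
        return 2 if self.kind is ModelKind.COMBINED else 1

    def predict(self, ac: np.ndarray | None = None, bscd: np.ndarray | None = None) -> np.ndarray:
        if self.kind is ModelKind.COMBINED:
            if ac is None or bscd is None:
                raise ValueError("combined model needs both ac and bscd")
            b1, b2, b3, b4, b5 = self.coefficients
            return b1 * np.exp(b2 * np.asarray(ac, float)) + b3 * np.exp(
                b4 * np.asarray(bscd, float)
            ) + b5
        x = ac if self.kind is ModelKind.AC else bscd
        if x is None:
            raise ValueError(f"{self.kind.value} model needs the {self.kind.value} predictor")
        b1, b2, b3 = self.coefficients
        return b1 * np.exp(b2 * np.asarray(x, float)) + b3

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "kind": self.kind.value,
            "coefficients": [float(f"{c:.17g}") for c in self.coefficients],
            "fit_meta": asdict(self.fit_meta),
        }
        d["fit_meta"]["start_values"] = list(self.fit_meta.start_values)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        text = _json_text(source)
        d = json.loads(text)
        meta = d["fit_meta"]
        meta["start_values"] = tuple(meta["start_values"])
        return cls(
            kind=ModelKind(d["kind"]),
            coefficients=tuple(d["coefficients"]),
            fit_meta=FitMeta(**meta),
        )


@dataclass(frozen=True)
class FitDiagnostics:
    """R², adjusted R² and RMSE of a model/data pairing.

    ``p`` counts QUS predictors (1 or 2), not raw coefficients, so the
    adjustment penalizes the number of independent variables. Both R²
    variants may be negative on external data.
    """

    r2: float
    adj_r2: float
    rmse: float
    n: int
    p: int


def _validate_xy(x: np.ndarray, y: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


# cap on the exponent's dynamic range across the observed predictor span:
# |rate| * ptp(x) <= RATE_SPAN, i.e. the exponential term may vary by at most
# e^RATE_SPAN over the data. A saturating tissue-calibration law uses one or
# two e-folds; the cap excludes single-point spike solutions (huge rate,
# vanishing amplitude) that would otherwise dominate noisy fits and overflow
# on new data, while leaving a wide margin around physiological curvature.
RATE_SPAN = 8.0


def _rate_bound(x: np.ndarray) -> float:
    return RATE_SPAN / float(np.ptp(x))


def _log_linear_start(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    b3 = float(y.min()) - 1e-3
    z = np.log(y - b3 + 1e-6)
    slope, intercept = np.polyfit(x, z, 1)
    rb = _rate_bound(x)
    slope = float(np.clip(slope, -0.99 * rb, 0.99 * rb))
    return float(np.exp(intercept)), float(slope), b3


def _run_nls(residual, p0: np.ndarray, bounds=(-np.inf, np.inf)) -> tuple[np.ndarray, FitMeta]:
    """Trust-region least squares terminated by relative SSE change < SSE_RTOL
    (scipy's ftol criterion is exactly that test) or by the iteration cap."""
    p0 = np.asarray(p0, dtype=float)
    sse0 = float(np.sum(np.asarray(residual(p0), float) ** 2))
    sol = least_squares(
        residual,
        p0,
        bounds=bounds,
        method="trf",
        x_scale="jac",  # predictors live on very different scales
        ftol=SSE_RTOL,
        xtol=1e-14,
        gtol=None,
        # finite-difference trf spends ~(n_params + 1) evaluations per
        # iteration; cap corresponds to MAX_ITER iterations
        max_nfev=MAX_ITER * (p0.size + 2),
    )
    sse = float(2.0 * sol.cost)
    # a purely relative SSE stop can never fire on an exact fit (SSE ≈ 0 up
    # to rounding), so near-zero SSE counts as converged
    exact = sse <= 1e-14 * max(1.0, sse0)
    meta = FitMeta(
        converged=sol.status > 0 or exact,
        iterations=int(sol.nfev),
        sse=float(2.0 * sol.cost),
        start_values=tuple(float(v) for v in np.atleast_1d(p0)),
        message=str(sol.message),
    )
    return sol.x, meta


def fit_single_model(x, y, kind: ModelKind | str) -> CalibrationModel:
    """Fit PDFF = β1·exp(β2·x) + β3 on one QUS predictor by least squares."""
    kind = ModelKind(kind)
    if kind is ModelKind.COMBINED:
        raise ValueError("use fit_combined_model for the two-predictor form")
    x, y = _validate_xy(x, y, min_n=4)
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor: β2 is unidentifiable")
    p0 = np.array(_log_linear_start(x, y))

    def residual(p):
        return p[0] * np.exp(p[1] * x) + p[2] - y

    rb = _rate_bound(x)
    bounds = ([-np.inf, -rb, -np.inf], [np.inf, rb, np.inf])
    coef, meta = _run_nls(residual, p0, bounds)
    if not meta.converged:
        raise FitError(
            f"no convergence after {meta.iterations} iterations (best SSE {meta.sse:.6g})"
        )
    return CalibrationModel(kind=kind, coefficients=tuple(coef), fit_meta=meta)


def fit_combined_model(ac, bscd, y) -> CalibrationModel:
    """Fit the additive two-exponential PDFF model on AC and BSC-D jointly.

    Deterministic multi-start: (1) a backfitting start — the AC-only fit
    plus an exponential fit of its residuals on BSC-D; (2) the AC-only fit
    with a null BSC-D term; (3) independent log-linearizations with halved
    amplitudes. The best SSE wins; by construction the result never does
    worse than the nested AC-only model.
    """
    ac, y = _validate_xy(ac, y, min_n=7)
    bscd, _ = _validate_xy(bscd, y, min_n=7)
    if np.ptp(ac) == 0 or np.ptp(bscd) == 0:
        raise DegenerateInputError("constant predictor: exponent unidentifiable")

    ill = False
    ra = np.corrcoef(ac, bscd)[0, 1]
    if abs(ra) > 1 - 1e-10:
        ill = True
        warnings.warn("ac and bscd are (nearly) collinear; fit is ill-conditioned", stacklevel=2)

    def residual(p):
        return p[0] * np.exp(p[1] * ac) + p[2] * np.exp(p[3] * bscd) + p[4] - y

    rb_ac, rb_b = _rate_bound(ac), _rate_bound(bscd)
    bounds = (
        [-np.inf, -rb_ac, -np.inf, -rb_b, -np.inf],
        [np.inf, rb_ac, np.inf, rb_b, np.inf],
    )

    # start 1 — backfitting: AC-only fit, then the residual trend on BSC-D
    single = fit_single_model(ac, y, ModelKind.AC)
    a1s, a2s, a3s = single.coefficients
    starts = [np.array([a1s, a2s, 0.0, 0.0, a3s])]
    resid_y = y - (a1s * np.exp(a2s * ac))
    try:
        rfit = fit_single_model(bscd, resid_y, ModelKind.BSCD)
        c1s, c2s, c3s = rfit.coefficients
        starts.insert(0, np.array([a1s, a2s, c1s, c2s, a3s + c3s]))
    except (FitError, DegenerateInputError):
        pass
    # start 2 — independent log-linearizations with halved amplitudes
    a1, a2, _ = _log_linear_start(ac, y)
    c1, c2, _ = _log_linear_start(bscd, y)
    starts.append(np.array([a1 / 2, a2, c1 / 2, c2, float(y.min()) - 1e-3]))

    coef, meta = None, None
    for p0 in starts:
        c_try, m_try = _run_nls(residual, p0, bounds)
        if meta is None or m_try.sse < meta.sse:
            coef, meta = c_try, m_try
    # nesting: the AC-only law is a special case of the additive form
    if meta.sse > single.fit_meta.sse * (1 + 1e-9):
        coef = np.array([a1s, a2s, 0.0, 0.0, a3s])
        meta = FitMeta(
            converged=single.fit_meta.converged,
            iterations=meta.iterations + single.fit_meta.iterations,
            sse=single.fit_meta.sse,
            start_values=tuple(float(v) for v in starts[0]),
            message="reduced to AC-only special case",
        )
    if not meta.converged:
        raise FitError(
            f"no convergence after {meta.iterations} iterations (best SSE {meta.sse:.6g})"
        )
    if ill:
        meta = FitMeta(**{**asdict(meta), "ill_conditioned": True})
    return CalibrationModel(kind=ModelKind.COMBINED, coefficients=tuple(coef), fit_meta=meta)


def predict_ueff(model: CalibrationModel, cohort: Cohort) -> Cohort:
    """Fill each record's ``ueff`` with the model prediction, order preserved.

    Predictions are not clipped: negative values are legal output.
    """
    if not model.fit_meta.converged:
        raise FitError("refusing to predict from a non-converged model")
    preds = model.predict(ac=cohort.column("ac"), bscd=cohort.column("bscd"))
    return cohort.with_ueff(preds)


def model_diagnostics(model: CalibrationModel, cohort: Cohort) -> FitDiagnostics:
    """R², adjusted R² and RMSE of the model against observed MRI-PDFF."""
    y = cohort.column("pdff")
    yhat = model.predict(ac=cohort.column("ac"), bscd=cohort.column("bscd"))
    return diagnostics_from_predictions(y, yhat, model.n_predictors)


def diagnostics_from_predictions(y, yhat, n_predictors: int) -> FitDiagnostics:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = y.size
    p = n_predictors
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return FitDiagnostics(r2=r2, adj_r2=adj, rmse=math.sqrt(ss_res / n), n=n, p=p)
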