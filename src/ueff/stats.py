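"""Correlation, linear-model screening, and grade-wise group comparisons.

Pearson correlations carry 95 % confidence intervals from the Fisher z
transform: with z = atanh(ρ) approximately normal with SD 1/√(n−3), the CI
is tanh(z ± z_{1−α/2}/√(n−3)). The sub-range scan searches contiguous fat-
fraction intervals for the strongest UEFF–PDFF correlation, reflecting the
saturation of quantitative ultrasound above roughly 20 % fat. Group
comparisons use the tie-corrected Kruskal–Wallis test with Dunn's pairwise
z-tests and Holm's step-down multiplicity adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .cohort import Cohort

__all__ = [
    "CorrelationResult",
    "LinRegResult",
    "GroupTestResult",
    "pearson_with_ci",
    "subrange_correlation_scan",
    "simple_linreg",
    "fit_linear_models",
    "holm_adjust",
    "kruskal_wallis_dunn",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float
    range_used: tuple[float, float] | None = None


def fisher_ci(rho: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher CI needs n ≥ 4")
    if abs(rho) >= 1.0:
        return rho, rho
    z = math.atanh(rho)
    half = sps.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Sample Pearson ρ with Fisher-z CI and two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n ≥ 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    n = x.size
    rho = float(np.corrcoef(x, y)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0 - 1e-15:
        return CorrelationResult(rho=rho, ci_low=rho, ci_high=rho, n=n, p_value=0.0)
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    lo, hi = fisher_ci(rho, n, alpha)
    return CorrelationResult(rho=rho, ci_low=lo, ci_high=hi, n=n, p_value=float(p))


def subrange_correlation_scan(
    x, y, min_fraction: float = 0.5, alpha: float = 0.05
) -> CorrelationResult:
    """Strongest-correlation contiguous sub-range of x (exploratory).

    Scans every interval [x_(i), x_(j)] with endpoints at observed values
    containing at least ``min_fraction`` of the records and returns the
    Pearson result on the interval maximizing ρ; ties go to the widest
    interval. With ``min_fraction = 1`` this reduces to the full-sample
    correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    m_min = max(4, int(math.ceil(min_fraction * n)))
    if n < m_min:
        raise ValueError("no admissible interval: sample too small")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    best: tuple[float, float, int, int] | None = None  # (rho, width, i, j)
    for i in range(n):
        for j in range(i + m_min - 1, n):
            seg_x = xs[i : j + 1]
            seg_y = ys[i : j + 1]
            if np.ptp(seg_x) == 0 or np.ptp(seg_y) == 0:
                continue
            rho = float(np.corrcoef(seg_x, seg_y)[0, 1])
            width = xs[j] - xs[i]
            key = (round(rho, 12), width)
            if best is None or key > (round(best[0], 12), best[1]):
                best = (rho, width, i, j)
    if best is None:
        raise ValueError("no admissible interval with non-constant values")
    _, _, i, j = best
    res = pearson_with_ci(xs[i : j + 1], ys[i : j + 1], alpha)
    return CorrelationResult(
        rho=res.rho,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        n=res.n,
        p_value=res.p_value,
        range_used=(float(xs[i]), float(xs[j])),
    )


def simple_linreg(x, y) -> tuple[float, float, float]:
    """Ordinary least-squares line y = βx + c; returns (β, c, p_slope)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n ≥ 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 1.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


@dataclass
class LinRegResult:
    """Univariable and multivariable linear screens of PDFF on predictors.

    ``table`` has one row per (analysis, predictor) with adjusted R², the
    model F statistic, the coefficient and its p-value; the multivariable
    rows share the joint model's adj R² and F.
    """

    table: pd.DataFrame
    outcome: str = "pdff"


def fit_linear_models(
    cohort: Cohort, predictors: tuple[str, ...] = ("ac", "bscd", "ls", "bmi")
) -> LinRegResult:
    """Univariable OLS per predictor plus one joint multivariable OLS."""
    y = cohort.column("pdff")
    X = {p: cohort.column(p) for p in predictors}
    complete = ~np.isnan(y)
    for v in X.values():
        complete &= ~np.isnan(v)
    if complete.sum() < len(predictors) + 2:
        raise ValueError("too few complete cases")
    y = y[complete]
    Xm = np.column_stack([X[p][complete] for p in predictors])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xm])) < len(predictors) + 1:
        raise ValueError("exact collinearity among predictors")
    rows = []
    for i, p in enumerate(predictors):
        fit = sm.OLS(y, sm.add_constant(Xm[:, i])).fit()
        rows.append(
            {
                "analysis": "univariable",
                "predictor": p,
                "adj_r2": float(fit.rsquared_adj),
                "F": float(fit.fvalue),
                "beta": float(fit.params[1]),
                "p_value": float(fit.pvalues[1]),
            }
        )
    joint = sm.OLS(y, sm.add_constant(Xm)).fit()
    for i, p in enumerate(predictors):
        rows.append(
            {
                "analysis": "multivariable",
                "predictor": p,
                "adj_r2": float(joint.rsquared_adj),
                "F": float(joint.fvalue),
                "beta": float(joint.params[i + 1]),
                "p_value": float(joint.pvalues[i + 1]),
            }
        )
    return LinRegResult(table=pd.DataFrame(rows))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, ≥ raw, capped at 1)."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class GroupTestResult:
    """Kruskal–Wallis omnibus plus Dunn pairwise comparisons."""

    h: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_holm
    group_order: tuple


def kruskal_wallis_dunn(values, groups, alpha: float = 0.05) -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis H with Dunn/Holm post-hoc pairwise tests.

    All-equal samples are reported as H = 0, p = 1 by convention. Dunn's z
    uses the tie-corrected pooled variance of mean ranks; p-values are
    two-sided and Holm-adjusted over all pairs.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist(), key=str)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples) or values.size < 3:
        raise ValueError("each group needs ≥1 observation and ≥3 total")
    if np.ptp(values) == 0:
        pairs = [
            {"group_a": a, "group_b": b, "z": 0.0, "p_raw": 1.0, "p_holm": 1.0}
            for a, b in itertools.combinations(labels, 2)
        ]
        return GroupTestResult(0.0, 1.0, pd.DataFrame(pairs), tuple(labels))
    h, p = sps.kruskal(*samples)

    n = values.size
    ranks = sps.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    pairs = []
    for a, b in itertools.combinations(labels, 2):
        var = (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (
            1.0 / sizes[a] + 1.0 / sizes[b]
        )
        z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var) if var > 0 else 0.0
        p_raw = 2 * sps.norm.sf(abs(z))
        pairs.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p_raw)})
    df = pd.DataFrame(pairs)
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return GroupTestResult(float(h), float(p), df, tuple(labels))
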