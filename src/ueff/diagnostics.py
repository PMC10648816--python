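"""ROC analysis, Youden-optimal cutoffs, diagnostic metrics, and power.

The AUC is computed by the Mann–Whitney identity — the fraction of
(positive, negative) score pairs ranked concordantly, ties counting one
half — with a DeLong-variance normal confidence interval clipped to [0, 1].
Cutoffs maximize Youden's J = sensitivity + specificity − 1 over the
midpoints between adjacent distinct scores (plus ±∞), with ties broken
toward the higher cutoff (higher specificity). The classification rule is
score ≥ cutoff ⇒ positive. Power for the test of AUC = 0.5 uses the
Hanley–McNeil variance approximation at the observed AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as sps

__all__ = [
    "RocResult",
    "roc_auc",
    "best_cutoff_youden",
    "classification_metrics",
    "power_auc",
    "evaluate_classifier",
]


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    n1, n0 = pos.size, neg.size
    return (r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    # placement values: V10_i = P(score_neg < pos_i) + ½P(=), and symmetrically
    n1, n0 = pos.size, neg.size
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n0 for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / n1 for q in neg])
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def roc_auc(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC by pair counting with a DeLong CI clipped to [0, 1]."""
    scores, labels = _check_binary(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    auc = _auc_mann_whitney(pos, neg)
    var = _delong_variance(pos, neg, auc)
    half = sps.norm.ppf(1 - alpha / 2) * math.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    return np.concatenate([[-np.inf], mids, [np.inf]])


def best_cutoff_youden(scores, labels, j_definition: str = "youden") -> float:
    """Cutoff maximizing J over all candidate thresholds.

    ``j_definition="youden"`` uses J = TPR − FPR (the standard index);
    ``"literal"`` uses J = TPR − FNR = 2·TPR − 1, kept for auditability of
    sensitivity-only threshold selection. Ties break toward the higher
    cutoff, i.e. higher specificity.
    """
    scores, labels = _check_binary(scores, labels)
    if j_definition not in ("youden", "literal"):
        raise ValueError("j_definition must be 'youden' or 'literal'")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_j = -np.inf
    best_cut = -np.inf
    for cut in _candidate_cutoffs(scores):
        tpr = np.mean(pos >= cut)
        fpr = np.mean(neg >= cut)
        j = tpr - fpr if j_definition == "youden" else 2 * tpr - 1
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and cut > best_cut):
            best_j, best_cut = j, cut
    return float(best_cut)


def classification_metrics(scores, labels, cutoff: float) -> dict[str, float]:
    """SN, SP, PPV, NPV and total accuracy of the rule score ≥ cutoff.

    Predictive values with an empty predicted class are reported as NaN.
    """
    if math.isnan(cutoff):
        raise ValueError("cutoff must not be NaN")
    scores, labels = _check_binary(scores, labels)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    ta = (tp + tn) / (tp + tn + fp + fn)
    return {"sn": sn, "sp": sp, "ppv": ppv, "npv": npv, "ta": ta}


def _hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def power_auc(
    auc: float,
    n_pos: int,
    n_neg: int,
    alpha: float = 0.05,
    beta_max: float = 0.10,
) -> tuple[float, bool]:
    """Power of the two-sided test of AUC = 0.5 at the observed AUC.

    Null SE from the Hanley–McNeil variance at AUC = 0.5, alternative SE at
    the observed AUC; returns (power, power ≥ 1 − beta_max).
    """
    if not (0.0 < auc < 1.0):
        raise ValueError("auc must lie strictly in (0, 1)")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be ≥ 1")
    se0 = math.sqrt(_hanley_mcneil_var(0.5, n_pos, n_neg))
    se1 = math.sqrt(_hanley_mcneil_var(auc, n_pos, n_neg))
    z_a = sps.norm.ppf(1 - alpha / 2)
    delta = abs(auc - 0.5)
    power = sps.norm.sf((z_a * se0 - delta) / se1) + sps.norm.cdf(
        (-z_a * se0 - delta) / se1
    )
    power = float(min(1.0, max(0.0, power)))
    return power, power >= 1.0 - beta_max


@dataclass(frozen=True)
class RocResult:
    """One binary classification task's full diagnostic read-out."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float  # % UEFF
    sn: float
    sp: float
    ppv: float
    npv: float
    ta: float
    power: float
    adequate_power: bool
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "cutoff": self.cutoff,
            "sn": self.sn,
            "sp": self.sp,
            "ppv": self.ppv,
            "npv": self.npv,
            "ta": self.ta,
            "power": self.power,
            "adequate_power": self.adequate_power,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def evaluate_classifier(
    scores, labels, alpha: float = 0.05, beta_max: float = 0.10,
    j_definition: str = "youden",
) -> RocResult:
    """AUC + CI, Youden cutoff, confusion metrics and power in one pass."""
    scores, labels = _check_binary(scores, labels)
    auc, lo, hi = roc_auc(scores, labels, alpha)
    cutoff = best_cutoff_youden(scores, labels, j_definition)
    metrics = classification_metrics(scores, labels, cutoff)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    auc_for_power = min(max(auc, 1e-9), 1 - 1e-9)
    power, adequate = power_auc(auc_for_power, n_pos, n_neg, alpha, beta_max)
    return RocResult(
        auc=auc, ci_low=lo, ci_high=hi, cutoff=cutoff,
        sn=metrics["sn"], sp=metrics["sp"], ppv=metrics["ppv"],
        npv=metrics["npv"], ta=metrics["ta"],
        power=power, adequate_power=adequate, n_pos=n_pos, n_neg=n_neg,
    )
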