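"""Ordinal severity grading of steatosis (MRI-PDFF) and fibrosis (stiffness).

Steatosis grades follow the 5/10/20 % MRI-PDFF convention (none / mild /
moderate / severe); fibrosis stages follow the elastography "rule of four"
(F2 ≥ 5 kPa, F3 ≥ 9 kPa, F4 ≥ 13 kPa). All thresholds are lower-inclusive,
matching the ≥-style dichotomies (<5 % vs ≥5 %) used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort

__all__ = [
    "GradeThresholds",
    "STEATOSIS_LABELS",
    "FIBROSIS_LABELS",
    "steatosis_grade",
    "fibrosis_grade",
    "grade_counts",
]

STEATOSIS_LABELS = ("S0", "S1", "S2", "S3")
FIBROSIS_LABELS = ("F0/F1", "F2", "F3", "F4")


@dataclass(frozen=True)
class GradeThresholds:
    """Lower-inclusive cut points for both ordinal scales."""

    steatosis_cuts: tuple[float, float, float] = (5.0, 10.0, 20.0)  # % MRI-PDFF
    fibrosis_cuts: tuple[float, float, float] = (5.0, 9.0, 13.0)  # kPa

    def __post_init__(self) -> None:
        for cuts in (self.steatosis_cuts, self.fibrosis_cuts):
            if len(cuts) != 3 or not all(c > 0 for c in cuts):
                raise ValueError("need three positive cut points")
            if not (cuts[0] < cuts[1] < cuts[2]):
                raise ValueError(f"cuts must be strictly increasing, got {cuts}")


DEFAULT_THRESHOLDS = GradeThresholds()


def _ordinal(value: float, cuts: tuple[float, float, float]) -> int:
    return sum(value >= c for c in cuts)


def steatosis_grade(pdff: float, cuts: GradeThresholds = DEFAULT_THRESHOLDS) -> int:
    """Grade index 0–3 (S0 <5 %, S1 5–10 %, S2 10–20 %, S3 ≥20 %); bounds inclusive."""
    if pdff < 0:
        raise ValueError(f"pdff must be non-negative, got {pdff}")
    return _ordinal(pdff, cuts.steatosis_cuts)


def fibrosis_grade(ls: float, cuts: GradeThresholds = DEFAULT_THRESHOLDS) -> int:
    """Stage index 0–3 (F0/F1, F2 ≥5, F3 ≥9, F4 ≥13 kPa); bounds inclusive."""
    if ls <= 0:
        raise ValueError(f"liver stiffness must be positive, got {ls}")
    return _ordinal(ls, cuts.fibrosis_cuts)


def grade_counts(
    cohort: Cohort, cuts: GradeThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Counts and percentages per grade on both scales, zero grades retained.

    Returns a tidy frame with columns ``scale`` (steatosis / fibrosis),
    ``grade`` (label), ``count`` and ``percent``; counts sum to n per scale.
    """
    n = len(cohort)
    s_counts = [0, 0, 0, 0]
    f_counts = [0, 0, 0, 0]
    for r in cohort:
        s_counts[steatosis_grade(r.pdff, cuts)] += 1
        f_counts[fibrosis_grade(r.ls, cuts)] += 1
    rows = []
    for scale, labels, counts in (
        ("steatosis", STEATOSIS_LABELS, s_counts),
        ("fibrosis", FIBROSIS_LABELS, f_counts),
    ):
        for label, c in zip(labels, counts):
            rows.append(
                {"scale": scale, "grade": label, "count": c, "percent": 100.0 * c / n}
            )
    return pd.DataFrame(rows)
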