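"""Seeded synthetic cohorts with the joint structure the calibration assumes.

The generator emulates a fatty-liver imaging cohort: the steatosis-grade mix
fixes how many subjects fall in each MRI-PDFF band (<5, 5–10, 10–20, ≥20 %);
fat fraction is uniform within its band; the attenuation coefficient is tied
to fat by a saturating exponential law PDFF = a1·exp(a2·AC) + a3 (inverted to
produce AC from the noiseless fat fraction); the backscatter-distribution
coefficient saturates in fat, BSC-D = c1 + c2·(1 − exp(−c3·PDFF)); liver
stiffness is log-normal and statistically independent of fat; BMI rises
weakly with log fat fraction. Observed MRI-PDFF is the true value plus
Gaussian measurement noise, clipped at zero.

Default coefficients are package fixtures calibrated once by least squares
against published cohort summary statistics (AC 0.55–1.22 dB/cm/MHz spanning
PDFF ≈ 1–44 %, BSC-D ≈ 85–111 a.u.); they are not fitted patient data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, Group, PatientRecord
from .grading import DEFAULT_THRESHOLDS, grade_counts

__all__ = [
    "LogNormalSpec",
    "SyntheticConfig",
    "nafld_config",
    "mafld_config",
    "largest_remainder_counts",
    "generate_cohort",
    "CohortSummary",
    "summarize_cohort",
]

# grade-mix proportions matching the reference cohorts' published counts
NAFLD_GRADE_MIX = (0.211, 0.244, 0.378, 0.167)
MAFLD_GRADE_MIX = (0.549, 0.157, 0.196, 0.098)

# fixture link coefficients (see module docstring)
DEFAULT_AC_LINK = (4.0535, 2.1562, -12.270)
DEFAULT_BSCD_LINK = (84.589, 27.343, 0.0758)


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution parameterized by its arithmetic mean and SD."""

    mean: float
    sd: float

    def mu_sigma(self) -> tuple[float, float]:
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        return math.log(self.mean) - sigma2 / 2, math.sqrt(sigma2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization (including seed) of the cohort generator."""

    n: int = 90
    seed: int = 0
    group: Group = Group.NAFLD
    grade_mix: tuple[float, float, float, float] = NAFLD_GRADE_MIX
    ac_link: tuple[float, float, float] = DEFAULT_AC_LINK
    bscd_link: tuple[float, float, float] = DEFAULT_BSCD_LINK
    noise_sd_pdff: float = 6.0  # % PDFF measurement noise
    noise_sd_bscd: float = 6.0  # arbitrary units
    ls_distribution: LogNormalSpec = LogNormalSpec(7.24, 3.2)  # kPa
    bmi_mean: float = 23.4  # kg/m² baseline (before fat effect)
    bmi_sd: float = 3.8
    bmi_pdff_effect: float = 2.5  # kg/m² per log1p(% PDFF)
    pdff_max: float = 45.0  # truncation of the severe band
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("need n ≥ 8 (at least two subjects per grade band)")
        if abs(sum(self.grade_mix) - 1.0) > 1e-6:
            raise ValueError(f"grade_mix must sum to 1, got {sum(self.grade_mix)}")
        if min(self.grade_mix) < 0:
            raise ValueError("grade_mix proportions must be non-negative")
        if self.noise_sd_pdff < 0 or self.noise_sd_bscd < 0:
            raise ValueError("noise SDs must be non-negative")
        a1, a2, _ = self.ac_link
        if a1 <= 0 or a2 <= 0:
            raise ValueError("ac_link requires a1 > 0, a2 > 0 (increasing AC→PDFF)")
        _, c2, c3 = self.bscd_link
        if c2 <= 0 or c3 <= 0:
            raise ValueError("bscd_link requires c2 > 0, c3 > 0 (saturating BSC-D)")
        if self.pdff_max <= 20.0:
            raise ValueError("pdff_max must exceed the severe-grade lower bound, 20 %")

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["group"] = self.group.value
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticConfig":
        from .calibration import _json_text

        d = json.loads(_json_text(source))
        d["grade_mix"] = tuple(d["grade_mix"])
        d["ac_link"] = tuple(d["ac_link"])
        d["bscd_link"] = tuple(d["bscd_link"])
        d["ls_distribution"] = LogNormalSpec(**d["ls_distribution"])
        d["group"] = Group(d["group"])
        return cls(**d)


def nafld_config(seed: int = 0, n: int = 90, **overrides) -> SyntheticConfig:
    """Default configuration emulating the NAFLD-like training cohort."""
    return SyntheticConfig(n=n, seed=seed, label="synthetic-NAFLD", **overrides)


def mafld_config(seed: int = 1, n: int = 51, **overrides) -> SyntheticConfig:
    """External-test cohort: same links, leaner grade mix, stiffer livers."""
    overrides.setdefault("grade_mix", MAFLD_GRADE_MIX)
    overrides.setdefault("ls_distribution", LogNormalSpec(11.26, 8.9))
    overrides.setdefault("group", Group.MAFLD)
    return SyntheticConfig(n=n, seed=seed, label="synthetic-MAFLD", **overrides)


def largest_remainder_counts(proportions, n: int) -> np.ndarray:
    """Integer allocation of n among proportions; counts sum to n exactly."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    quotas = p * n
    counts = np.floor(quotas).astype(int)
    shortfall = n - counts.sum()
    for i in np.argsort(-(quotas - counts), kind="stable")[:shortfall]:
        counts[i] += 1
    return counts


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw one cohort; deterministic given ``config.seed``.

    All randomness flows from a single seed sequence, with one child stream
    per variable, so adding a variable never perturbs the others.
    """
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_pdff, rng_noise, rng_bscd, rng_ls, rng_bmi, rng_age, rng_misc = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n
    cuts = DEFAULT_THRESHOLDS.steatosis_cuts
    bands = [(0.0, cuts[0]), (cuts[0], cuts[1]), (cuts[1], cuts[2]), (cuts[2], config.pdff_max)]
    counts = largest_remainder_counts(config.grade_mix, n)
    true_pdff = np.concatenate(
        [rng_pdff.uniform(lo, hi, c) for (lo, hi), c in zip(bands, counts)]
    )

    a1, a2, a3 = config.ac_link
    ac = np.log((true_pdff - a3) / a1) / a2
    c1, c2, c3 = config.bscd_link
    bscd = c1 + c2 * (1.0 - np.exp(-c3 * true_pdff))
    if config.noise_sd_bscd > 0:
        bscd = bscd + rng_bscd.normal(0.0, config.noise_sd_bscd, n)
    bscd = np.clip(bscd, 1e-6, None)

    pdff = true_pdff
    if config.noise_sd_pdff > 0:
        pdff = np.clip(pdff + rng_noise.normal(0.0, config.noise_sd_pdff, n), 0.0, None)

    mu, sigma = config.ls_distribution.mu_sigma()
    ls = rng_ls.lognormal(mu, sigma, n)
    bmi = (
        rng_bmi.normal(config.bmi_mean, config.bmi_sd, n)
        + config.bmi_pdff_effect * np.log1p(true_pdff)
    )
    age = np.clip(rng_age.normal(55.0, 13.0, n), 18.0, 90.0)
    sex = rng_misc.choice(["F", "M"], size=n)
    t2dm = rng_misc.random(n) < 0.25

    records = [
        PatientRecord(
            id=f"{config.label}-{i:04d}",
            group=config.group,
            ac=float(ac[i]),
            bscd=float(bscd[i]),
            ls=float(ls[i]),
            pdff=float(pdff[i]),
            bmi=float(bmi[i]),
            age=float(age[i]),
            sex=str(sex[i]),
            t2dm=bool(t2dm[i]),
            etiology="none" if config.group is Group.NAFLD else "mixed",
        )
        for i in range(n)
    ]
    return Cohort(records, label=config.label, provenance=f"generate_cohort(seed={config.seed})")


_SUMMARY_VARIABLES = ("ac", "bscd", "ls", "pdff", "ueff", "bmi")


@dataclass
class CohortSummary:
    """Distribution table (mean/SD/range per variable) plus grade counts."""

    variables: pd.DataFrame
    grades: pd.DataFrame
    n: int


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Mean, sample SD (n−1; NaN for a single record) and range per variable.

    Variables with no values set (e.g. ``ueff`` before prediction) are
    omitted. Grade counts cover both the steatosis and fibrosis scales.
    """
    rows = []
    for name in _SUMMARY_VARIABLES:
        col = cohort.column(name)
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        sd = float(np.std(col, ddof=1)) if col.size > 1 else float("nan")
        rows.append(
            {
                "variable": name,
                "n": int(col.size),
                "mean": float(col.mean()),
                "sd": sd,
                "min": float(col.min()),
                "max": float(col.max()),
            }
        )
    return CohortSummary(
        variables=pd.DataFrame(rows), grades=grade_counts(cohort), n=len(cohort)
    )
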