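"""Patient-level domain types, measurement QC/aggregation, and CSV round-trip.

A quantitative-ultrasound liver exam yields repeated per-site measurements:
tissue attenuation imaging (TAI, attenuation coefficient AC in dB/cm/MHz,
each reading carrying a fit-R² quality score), tissue scatter-distribution
imaging (TSI, backscatter-distribution coefficient BSC-D in arbitrary units,
no per-reading quality metric), and 2D shear-wave elastography (SWE, liver
stiffness LS in kPa, each reading carrying a reliable-measure index, RMI).
Per-patient values are the mean of the valid readings after the standard
validity rules: TAI readings with fit-R² < 0.6 and SWE readings with
RMI < 0.4 are discarded, at least five valid readings are required, and SWE
additionally requires an interquartile-range/median ratio below 30 %.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Group",
    "RawMeasurement",
    "PatientRecord",
    "Cohort",
    "CohortError",
    "InsufficientMeasurementsError",
    "DispersionTooHighError",
    "ModalityMismatchError",
    "MissingColumnError",
    "DuplicateIdError",
    "TAI_MIN_QUALITY",
    "SWE_MIN_QUALITY",
    "SWE_MAX_IQR_OVER_MEDIAN",
    "MIN_VALID_MEASUREMENTS",
    "aggregate_measurements",
    "load_cohort",
    "write_cohort",
]

TAI_MIN_QUALITY = 0.6
SWE_MIN_QUALITY = 0.4
SWE_MAX_IQR_OVER_MEDIAN = 0.30
MIN_VALID_MEASUREMENTS = 5


class Modality(str, enum.Enum):
    """Per-measurement ultrasound application."""

    TAI = "TAI"  # attenuation coefficient, dB/cm/MHz
    TSI = "TSI"  # backscatter-distribution coefficient, arbitrary units
    SWE = "SWE"  # liver stiffness, kPa


class Group(str, enum.Enum):
    """Clinical etiology label: training vs external-test cohort."""

    NAFLD = "NAFLD"
    MAFLD = "MAFLD"


class CohortError(ValueError):
    """Base class for cohort-level validation failures."""


class InsufficientMeasurementsError(CohortError):
    """Fewer than the required number of valid measurements survive QC."""


class DispersionTooHighError(CohortError):
    """SWE IQR/median ratio at or above the 30 % reliability limit."""


class ModalityMismatchError(CohortError):
    """A measurement of a different modality was passed to the aggregator."""


class MissingColumnError(CohortError):
    """A required CSV column is absent."""


class DuplicateIdError(CohortError):
    """Two rows share a patient id."""


@dataclass(frozen=True)
class RawMeasurement:
    """One ultrasound reading with its optional per-reading quality metric.

    ``quality`` is the TAI fit-R² or the SWE reliable-measure index, both in
    [0, 1]; TSI readings carry no quality metric (``None``).
    """

    modality: Modality
    value: float
    quality: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"measurement value must be finite, got {self.value}")
        if self.quality is not None and not (0.0 <= self.quality <= 1.0):
            raise ValueError(f"quality must lie in [0, 1], got {self.quality}")


def _iqr_over_median(values: np.ndarray) -> float:
    # linear-interpolation quartiles ("type 7"), the numpy default
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    if med == 0:
        return math.inf
    return (q3 - q1) / med


def aggregate_measurements(
    measurements: Iterable[RawMeasurement], modality: Modality | str
) -> float:
    """Apply the modality's validity rules and return the mean of valid readings.

    TAI: drop readings with fit-R² < 0.6, require ≥5 survivors.
    SWE: drop readings with RMI < 0.4, require ≥5 survivors with
    IQR/median < 0.30. TSI: require ≥5 readings (no quality metric).

    Raises
    ------
    ModalityMismatchError
        If any measurement is of a different modality.
    InsufficientMeasurementsError
        If fewer than five valid readings remain.
    DispersionTooHighError
        If the SWE survivors' IQR/median ratio is ≥ 0.30.
    """
    modality = Modality(modality)
    ms = list(measurements)
    for m in ms:
        if m.modality != modality:
            raise ModalityMismatchError(
                f"expected {modality.value} measurements, got {m.modality.value}"
            )
    if modality is Modality.TAI:
        valid = [m.value for m in ms if m.quality is not None and m.quality >= TAI_MIN_QUALITY]
    elif modality is Modality.SWE:
        valid = [m.value for m in ms if m.quality is not None and m.quality >= SWE_MIN_QUALITY]
    else:
        valid = [m.value for m in ms]
    if len(valid) < MIN_VALID_MEASUREMENTS:
        raise InsufficientMeasurementsError(
            f"{modality.value}: {len(valid)} valid measurements, "
            f"need at least {MIN_VALID_MEASUREMENTS}"
        )
    arr = np.asarray(valid, dtype=float)
    if modality is Modality.SWE:
        ratio = _iqr_over_median(arr)
        if ratio >= SWE_MAX_IQR_OVER_MEDIAN:
            raise DispersionTooHighError(
                f"SWE IQR/median = {ratio:.3f} ≥ {SWE_MAX_IQR_OVER_MEDIAN}"
            )
    return float(arr.mean())


@dataclass
class PatientRecord:
    """One subject's aggregated imaging values and clinical covariates.

    ``ueff`` (the model-predicted fat fraction, %) starts unset and is filled
    by prediction; it may legitimately be negative, so it is not range-checked.
    """

    id: str
    group: Group
    ac: float  # attenuation coefficient, dB/cm/MHz
    bscd: float  # backscatter-distribution coefficient, arbitrary units
    ls: float  # liver stiffness, kPa
    pdff: float  # MRI proton-density fat fraction, %
    bmi: float | None = None  # kg/m²
    age: float | None = None  # years
    sex: str | None = None
    t2dm: bool | None = None
    etiology: str | None = None
    ueff: float | None = None  # predicted fat fraction, %; may be negative

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if not self.id:
            raise ValueError("patient id must be non-empty")
        for name in ("ac", "bscd", "ls"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not (math.isfinite(self.pdff) and 0.0 <= self.pdff <= 100.0):
            raise ValueError(f"pdff must lie in [0, 100], got {self.pdff}")


_REQUIRED_COLUMNS = ("id", "group", "ac", "bscd", "ls", "pdff")
_OPTIONAL_COLUMNS = ("bmi", "age", "sex", "t2dm", "etiology", "ueff")


@dataclass
class Cohort:
    """Ordered, uniquely-identified collection of patient records."""

    records: list[PatientRecord]
    label: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must be non-empty")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, name: str) -> np.ndarray:
        """Numeric column as an array (NaN for unset optional values)."""
        vals = [getattr(r, name) for r in self.records]
        return np.array([np.nan if v is None else float(v) for v in vals])

    def subset(self, indices: Sequence[int], label: str | None = None) -> "Cohort":
        recs = [replace(self.records[i]) for i in indices]
        return Cohort(recs, label=label or self.label, provenance=self.provenance)

    def with_ueff(self, ueff: Sequence[float]) -> "Cohort":
        if len(ueff) != len(self.records):
            raise ValueError("ueff length must match cohort size")
        recs = [replace(r, ueff=float(u)) for r, u in zip(self.records, ueff)]
        return Cohort(recs, label=self.label, provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {f.name: getattr(r, f.name) for f in fields(r)}
            row["group"] = r.group.value
            rows.append(row)
        return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))

    def provenance_hash(self) -> str:
        payload = json.dumps(
            {"label": self.label, "provenance": self.provenance, "n": len(self)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_cohort(
    path: str | Path,
    label: str | None = None,
    schema: dict[str, str] | None = None,
) -> Cohort:
    """Read a cohort from CSV, validating each row against the record invariants.

    ``schema`` optionally maps canonical column names (``id``, ``group``,
    ``ac``, ``bscd``, ``ls``, ``pdff``, ...) to the file's column names.
    Rows violating a record invariant are dropped with a warning naming the
    row and reason; structural problems (missing column, duplicate id) raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"required column {col!r} missing from {path.name}")
    records: list[PatientRecord] = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col in _OPTIONAL_COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = bool(row[col]) if col == "t2dm" else row[col]
        try:
            records.append(
                PatientRecord(
                    id=str(row["id"]),
                    group=Group(str(row["group"])),
                    ac=float(row["ac"]),
                    bscd=float(row["bscd"]),
                    ls=float(row["ls"]),
                    pdff=float(row["pdff"]),
                    **kwargs,
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path.name} row {idx}: rejected ({exc})", stacklevel=2)
    if not records:
        raise CohortError(f"no valid rows in {path}")
    return Cohort(records, label=label or path.stem, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV (full float precision, round-trips via load_cohort)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    return path
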