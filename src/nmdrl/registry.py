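"""Patient administration registry: loading, validation, derived quantities, stratification.

A registry is a delimited-text file with one row per radiopharmaceutical
administration. Each row carries the demographics needed to stratify
diagnostic-reference-level surveys (sex, age, weight, height) and the two
activities (prescribed and syringe residual, MBq) whose difference is the
net administered activity actually delivered to the patient.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

MAX_AGE = 120
#: terminal pooled age bin starts here: [100, inf)
TERMINAL_BIN_EDGE = 100

#: WHO adult BMI class cutoffs (kg/m^2), lower edge inclusive
DEFAULT_BMI_CUTOFFS = (18.5, 25.0, 30.0)
BMI_CLASSES = ("underweight", "normal", "overweight", "obese")

SEXES = ("male", "female")

#: default header-name mapping from CSV columns to PatientRecord fields
DEFAULT_COLUMNS: dict[str, str] = {
    "patient_id": "patient_id",
    "protocol": "protocol",
    "radiopharmaceutical": "radiopharmaceutical",
    "prescribed_activity": "prescribed_mbq",
    "residual_activity": "residual_mbq",
    "sex": "sex",
    "age": "age_years",
    "weight": "weight_kg",
    "height": "height_m",
    "exam_date": "exam_date",
}


@dataclass(frozen=True)
class RegistryDialect:
    """CSV dialect + column mapping for registry files.

    ``decimal`` exists because Brazilian sources frequently use comma
    decimals; the loader normalizes them before parsing numbers.
    """

    separator: str = ","
    decimal: str = "."
    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))


@dataclass(frozen=True)
class PatientRecord:
    """One administration: demographics plus prescribed/residual activity."""

    patient_id: str
    protocol: str
    radiopharmaceutical: str
    prescribed_activity: float  # MBq
    residual_activity: float  # MBq
    sex: str  # "male" | "female"
    age: int  # years
    weight: float  # kg
    height: float  # m
    exam_date: _dt.date

    @property
    def administered_activity(self) -> float:
        """Net activity delivered to the patient (MBq): prescribed − residual."""
        return self.prescribed_activity - self.residual_activity

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)

    def validate(self) -> None:
        """Raise ValueError on any violated record invariant."""
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (0 <= self.age <= MAX_AGE):
            raise ValueError(f"age {self.age} outside [0, {MAX_AGE}]")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.prescribed_activity < 0:
            raise ValueError("prescribed activity must be >= 0")
        if self.residual_activity < 0:
            raise ValueError("residual activity must be >= 0")
        if self.residual_activity > self.prescribed_activity:
            raise ValueError("residual exceeds prescribed")


@dataclass(frozen=True)
class Reject:
    """A rejected registry row with its 1-based data row number and reason."""

    row: int
    reason: str


@dataclass
class LoadResult:
    records: list[PatientRecord]
    rejects: list[Reject]

    def write_rejects(self, path: str | Path) -> None:
        """Write the rejects report as CSV (row number, reason)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "reason"])
            for r in self.rejects:
                w.writerow([r.row, r.reason])


class MissingColumnError(KeyError):
    """A mandatory registry column is absent from the file header."""


def _parse_float(text: str, decimal: str) -> float:
    text = text.strip()
    if not text:
        raise ValueError("blank")
    if decimal != ".":
        text = text.replace(decimal, ".")
    return float(text)


def load_registry(path: str | Path, dialect: RegistryDialect | None = None) -> LoadResult:
    """Read a registry CSV, returning valid records and a rejects listing.

    A missing mandatory column is a hard error naming the column. A row with
    an unparseable or invariant-violating cell becomes a Reject, never a
    crash. Lines starting with ``#`` are treated as comments.
    """
    dialect = dialect or RegistryDialect()
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=dialect.separator)
                if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty registry file")
    header = [h.strip() for h in rows[0]]
    colidx: dict[str, int] = {}
    for field_name, col_name in dialect.columns.items():
        if col_name not in header:
            raise MissingColumnError(f"mandatory column {col_name!r} (field {field_name}) missing from {path}")
        colidx[field_name] = header.index(col_name)

    records: list[PatientRecord] = []
    rejects: list[Reject] = []
    for i, row in enumerate(rows[1:], start=1):
        try:
            rec = PatientRecord(
                patient_id=row[colidx["patient_id"]].strip(),
                protocol=row[colidx["protocol"]].strip(),
                radiopharmaceutical=row[colidx["radiopharmaceutical"]].strip(),
                prescribed_activity=_parse_float(row[colidx["prescribed_activity"]], dialect.decimal),
                residual_activity=_parse_float(row[colidx["residual_activity"]], dialect.decimal),
                sex=row[colidx["sex"]].strip().lower(),
                age=int(_parse_float(row[colidx["age"]], dialect.decimal)),
                weight=_parse_float(row[colidx["weight"]], dialect.decimal),
                height=_parse_float(row[colidx["height"]], dialect.decimal),
                exam_date=_dt.date.fromisoformat(row[colidx["exam_date"]].strip()),
            )
            rec.validate()
        except IndexError:
            rejects.append(Reject(i, "short row"))
            continue
        except ValueError as exc:
            msg = str(exc)
            if "blank" in msg or "could not convert" in msg:
                msg = "unparseable or blank numeric cell"
            rejects.append(Reject(i, msg))
            continue
        records.append(rec)
    log.info("loaded %d records, %d rejects from %s", len(records), len(rejects), path)
    return LoadResult(records, rejects)


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index weight/height² (kg/m²). Raises on non-positive input."""
    if weight <= 0 or height <= 0:
        raise ValueError(f"invalid anthropometry: weight={weight}, height={height}")
    return weight / height**2


def classify_bmi(bmi: float, cutoffs: Sequence[float] = DEFAULT_BMI_CUTOFFS) -> str:
    """Classify a BMI into {underweight, normal, overweight, obese}.

    Intervals are half-open with the lower edge inclusive: e.g. with the
    default WHO cutoffs a BMI of exactly 18.5 is "normal".
    """
    if bmi <= 0:
        raise ValueError("bmi must be > 0")
    if len(cutoffs) != 3 or list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be three increasing values")
    for cls, hi in zip(BMI_CLASSES[:-1], cutoffs):
        if bmi < hi:
            return cls
    return BMI_CLASSES[-1]


def age_bin(age: int) -> tuple[int, int | None]:
    """5-year half-open age bin [5k, 5k+5); ages >= 100 pool into [100, None)."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if age >= TERMINAL_BIN_EDGE:
        return (TERMINAL_BIN_EDGE, None)
    lo = 5 * (age // 5)
    return (lo, lo + 5)


def format_age_bin(bin_: tuple[int, int | None]) -> str:
    lo, hi = bin_
    return f"[{lo},inf)" if hi is None else f"[{lo},{hi})"


@dataclass(frozen=True, order=True)
class StratumKey:
    """One cell of the stratification: protocol × sex × 5-year age bin × BMI class.

    Inactive axes carry pooled labels ("both" for sex, "all" for the others).
    """

    protocol: str
    sex: str
    age_bin: str
    bmi_class: str


ALL_AXES = ("protocol", "sex", "age_bin", "bmi_class")


def stratify(
    records: Iterable[PatientRecord],
    axes: Sequence[str] = ALL_AXES,
    bmi_cutoffs: Sequence[float] = DEFAULT_BMI_CUTOFFS,
    per_kg: bool = False,
) -> dict[StratumKey, list[float]]:
    """Partition records into strata and collect their administered activities.

    ``axes`` selects which StratumKey axes are active; inactive axes are
    pooled. With ``per_kg`` the collected values are MBq per kg body weight
    instead of absolute MBq. Keys come back in sorted (deterministic) order
    and the strata partition the input: every record lands in exactly one.
    """
    unknown = set(axes) - set(ALL_AXES)
    if unknown:
        raise ValueError(f"unknown stratification axes: {sorted(unknown)}")
    out: dict[StratumKey, list[float]] = defaultdict(list)
    for rec in records:
        key = StratumKey(
            protocol=rec.protocol if "protocol" in axes else "all",
            sex=rec.sex if "sex" in axes else "both",
            age_bin=format_age_bin(age_bin(rec.age)) if "age_bin" in axes else "all",
            bmi_class=classify_bmi(rec.bmi, bmi_cutoffs) if "bmi_class" in axes else "all",
        )
        value = rec.administered_activity
        if per_kg:
            value /= rec.weight
        out[key].append(value)
    return dict(sorted(out.items()))
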