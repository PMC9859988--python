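"""Organ dosimetry from dose-per-activity coefficients.

Reference dose-coefficient tables give the absorbed dose to each organ per
unit administered activity (mGy/MBq), plus an effective-dose column
(mSv/MBq), at five anchor ages: 1, 5, 10, 15 years and adult. Patients come
at arbitrary ages, so the anchors are interpolated: coefficients fall with
age roughly like c(age) = α + β·ln(age) because organ mass grows with age
and absorbed dose varies inversely with it. When an organ's anchors do not
follow that curve well (low R²), a piecewise interpolation that is exact at
the anchors is used instead.

Dose itself is linear: absorbed dose (mGy) = activity (MBq) × coefficient
(mGy/MBq), and likewise effective dose in mSv.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MBQ_PER_MCI = 37.0  # exact: 1 mCi = 3.7e7 Bq

#: age (years) assigned to the "adult" anchor for interpolation purposes
DEFAULT_ADULT_AGE = 18.0

#: fitted-curve quality threshold below which the piecewise fallback is used
DEFAULT_R2_THRESHOLD = 0.90

EFFECTIVE_ROW = "effective"


def mci_to_mbq(mci: float) -> float:
    """Convert activity from millicuries to megabecquerels (1 mCi = 37 MBq)."""
    return mci * MBQ_PER_MCI


class UnknownOrganError(KeyError):
    pass


class UnknownRadiopharmaceuticalError(KeyError):
    pass


@dataclass
class DoseCoefficientTable:
    """Organ × anchor-age grid of dose coefficients for one radiopharmaceutical.

    ``organ_coefficients`` maps organ name → mGy/MBq values aligned with
    ``anchor_ages``; ``effective_coefficients`` is the matching mSv/MBq row.
    """

    radiopharmaceutical: str
    anchor_ages: np.ndarray  # years, strictly increasing
    organ_coefficients: dict[str, np.ndarray]
    effective_coefficients: np.ndarray
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.anchor_ages = np.asarray(self.anchor_ages, dtype=float)
        if self.anchor_ages.size < 2 or np.any(np.diff(self.anchor_ages) <= 0):
            raise ValueError("anchor ages must be strictly increasing")
        self.organ_coefficients = {
            o: np.asarray(c, dtype=float) for o, c in self.organ_coefficients.items()
        }
        self.effective_coefficients = np.asarray(self.effective_coefficients, dtype=float)
        for organ, coefs in self.organ_coefficients.items():
            if coefs.size != self.anchor_ages.size:
                raise ValueError(f"{organ}: expected one coefficient per anchor age")
            if np.any(coefs <= 0):
                raise ValueError(f"{organ}: coefficients must be positive")
        if self.effective_coefficients.size != self.anchor_ages.size:
            raise ValueError("effective row: expected one coefficient per anchor age")
        if np.any(self.effective_coefficients <= 0):
            raise ValueError("effective coefficients must be positive")

    @property
    def organs(self) -> list[str]:
        return list(self.organ_coefficients)


@dataclass(frozen=True)
class AgeInterpolation:
    """Fitted age dependence of one organ's coefficient: c(age) = α + β·ln(age)."""

    organ: str
    alpha: float
    beta: float
    r_squared: float
    mode: str  # "log_fit" | "piecewise_log"


def fit_log_curve(
    anchor_ages: Sequence[float],
    coefficients: Sequence[float],
    organ: str = "",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> AgeInterpolation:
    """Least-squares fit of coefficient = α + β·ln(age) over the anchors.

    R² = 1 − SSres/SStot with the zero-variance convention that a perfect
    fit of constant data has R² = 1. If R² falls below ``r2_threshold`` the
    returned mode is "piecewise_log": evaluation then interpolates
    ln(coefficient) linearly in ln(age) between adjacent anchors, which is
    exact at every anchor and keeps coefficients positive.
    """
    ages = np.asarray(anchor_ages, dtype=float)
    coefs = np.asarray(coefficients, dtype=float)
    if ages.size < 3:
        raise ValueError("need at least 3 anchor ages to fit")
    if np.any(ages <= 0):
        raise ValueError("anchor ages must be positive")
    x = np.log(ages)
    beta, alpha = np.polyfit(x, coefs, 1)
    resid = coefs - (alpha + beta * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((coefs - coefs.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if np.isclose(ss_res, 0.0) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2 = float(min(max(r2, 0.0), 1.0)) if np.isfinite(r2) else 0.0
    mode = "log_fit" if r2 >= r2_threshold else "piecewise_log"
    return AgeInterpolation(organ=organ, alpha=float(alpha), beta=float(beta),
                            r_squared=r2, mode=mode)


def _piecewise_log(ages: np.ndarray, coefs: np.ndarray, age: float) -> float:
    # linear interpolation of ln(coef) against ln(age); exact at anchors
    return float(np.exp(np.interp(np.log(age), np.log(ages), np.log(coefs))))


def coefficient_at_age(
    table: DoseCoefficientTable,
    organ: str,
    age: float,
    mode: str = "auto",
    adult_age: float | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> float:
    """Dose coefficient (mGy/MBq; mSv/MBq for the "effective" row) at any age.

    Ages at or above the adult anchor clamp to the adult coefficient and ages
    at or below the youngest anchor clamp to its coefficient. In between,
    ``mode`` selects the fitted logarithmic curve ("log_fit"), the
    anchor-exact piecewise interpolant ("piecewise_log"), or "auto", which
    fits the curve and falls back to piecewise when the fit is poor.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if organ == EFFECTIVE_ROW:
        coefs = table.effective_coefficients
    else:
        try:
            coefs = table.organ_coefficients[organ]
        except KeyError:
            raise UnknownOrganError(
                f"organ {organ!r} not tabulated for {table.radiopharmaceutical}"
            ) from None
    ages = table.anchor_ages.copy()
    if adult_age is not None:
        ages[-1] = adult_age
    if age >= ages[-1]:
        return float(coefs[-1])
    if age <= ages[0]:
        return float(coefs[0])
    if mode == "auto":
        fit = fit_log_curve(ages, coefs, organ=organ, r2_threshold=r2_threshold)
        mode = fit.mode
    else:
        fit = None
    if mode == "log_fit":
        if fit is None:
            fit = fit_log_curve(ages, coefs, organ=organ, r2_threshold=r2_threshold)
        value = fit.alpha + fit.beta * np.log(age)
        # a fitted line can undershoot for extreme anchors; never return <= 0
        return float(max(value, np.min(coefs) * 1e-6))
    if mode == "piecewise_log":
        return _piecewise_log(ages, coefs, age)
    raise ValueError(f"unknown interpolation mode {mode!r}")


def absorbed_dose(administered_activity: float, coefficient: float) -> float:
    """Absorbed dose (mGy) = administered activity (MBq) × coefficient (mGy/MBq)."""
    if administered_activity < 0:
        raise ValueError("activity must be >= 0")
    if coefficient <= 0:
        raise ValueError("coefficient must be > 0")
    return administered_activity * coefficient


def effective_dose(administered_activity: float, e_coefficient: float) -> float:
    """Effective dose (mSv) = administered activity (MBq) × coefficient (mSv/MBq)."""
    return absorbed_dose(administered_activity, e_coefficient)


@dataclass
class DoseReport:
    """Per-organ absorbed doses for one administration."""

    radiopharmaceutical: str
    activity: float  # MBq
    age: float
    sex: str
    organ_doses: dict[str, float]  # mGy
    effective_dose: float  # mSv
    risk_eligible: set[str]  # organs with a risk-parameter row available

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "organ": organ,
                "absorbed_dose_mgy": dose,
                "risk_eligible": organ in self.risk_eligible,
            }
            for organ, dose in sorted(self.organ_doses.items())
        ]
        return pd.DataFrame(rows, columns=["organ", "absorbed_dose_mgy", "risk_eligible"])


def dose_map_query(
    table: DoseCoefficientTable,
    activity: float,
    age: float,
    sex: str,
    eligible_sites: Mapping[str, str] | None = None,
    mode: str = "auto",
    adult_age: float | None = None,
) -> DoseReport:
    """Absorbed dose to every tabulated organ plus effective dose for one exam.

    ``eligible_sites`` maps organ names to risk-model cancer sites; organs
    with an entry are flagged eligible for the downstream risk analysis.
    """
    organ_doses = {
        organ: absorbed_dose(
            activity, coefficient_at_age(table, organ, age, mode=mode, adult_age=adult_age)
        )
        for organ in table.organs
    }
    e_dose = effective_dose(
        activity, coefficient_at_age(table, EFFECTIVE_ROW, age, mode=mode, adult_age=adult_age)
    )
    eligible = set()
    if eligible_sites:
        eligible = {o for o in table.organs if o in eligible_sites}
    return DoseReport(
        radiopharmaceutical=table.radiopharmaceutical,
        activity=activity,
        age=age,
        sex=sex,
        organ_doses=organ_doses,
        effective_dose=e_dose,
        risk_eligible=eligible,
    )


# ---------------------------------------------------------------------------
# table I/O

def load_coefficient_table(path: str | Path) -> DoseCoefficientTable:
    """Read one radiopharmaceutical's coefficient CSV.

    Schema: column ``organ`` (one row per organ plus one "effective" row),
    anchor-age columns ``age_1 .. age_adult`` (mGy/MBq; mSv/MBq for the
    effective row) and a free-text ``source`` column. The radiopharmaceutical
    key is taken from a ``# radiopharmaceutical:`` comment line or the stem.
    """
    path = Path(path)
    key = path.stem
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "radiopharmaceutical:" in line:
                key = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    frame = pd.read_csv(path, comment="#")
    age_cols = [c for c in frame.columns if c.startswith("age_")]
    if not age_cols:
        raise ValueError(f"{path}: no anchor-age columns (age_*)")
    ages = []
    for c in age_cols:
        tag = c.removeprefix("age_")
        ages.append(DEFAULT_ADULT_AGE if tag == "adult" else float(tag))
    order = np.argsort(ages)
    age_cols = [age_cols[i] for i in order]
    ages = sorted(ages)
    organ_coefs: dict[str, np.ndarray] = {}
    sources: dict[str, str] = {}
    effective = None
    for _, row in frame.iterrows():
        organ = str(row["organ"]).strip()
        coefs = row[age_cols].to_numpy(dtype=float)
        sources[organ] = str(row.get("source", ""))
        if organ == EFFECTIVE_ROW:
            effective = coefs
        else:
            organ_coefs[organ] = coefs
    if effective is None:
        raise ValueError(f"{path}: missing 'effective' row")
    return DoseCoefficientTable(
        radiopharmaceutical=key,
        anchor_ages=np.asarray(ages, dtype=float),
        organ_coefficients=organ_coefs,
        effective_coefficients=effective,
        sources=sources,
    )


def _shipped_dir():
    return resources.files("nmdrl") / "data" / "coefficients"


def available_radiopharmaceuticals() -> list[str]:
    """Keys of the coefficient tables shipped with the package."""
    return sorted(p.name.removesuffix(".csv") for p in _shipped_dir().iterdir()
                  if p.name.endswith(".csv"))


def load_shipped_table(radiopharmaceutical: str) -> DoseCoefficientTable:
    """Load a shipped coefficient table by radiopharmaceutical key (e.g. "MIBI-99mTc-rest")."""
    fname = radiopharmaceutical.replace("/", "_") + ".csv"
    entry = _shipped_dir() / fname
    if not entry.is_file():
        raise UnknownRadiopharmaceuticalError(
            f"no shipped coefficient table for {radiopharmaceutical!r}; "
            f"available: {available_radiopharmaceuticals()}"
        )
    with resources.as_file(entry) as p:
        return load_coefficient_table(p)
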