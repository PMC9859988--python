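"""BEIR VII-style radiation-induced cancer risk engine.

The excess risk of cancer at site *s* after an equivalent dose *D* (Sv)
received at age *e*, evaluated at attained age *a*, follows the solid-tumor
preferred model

    ERR or EAR = β_s · D · exp(γ·e*) · (a/60)^η,

where e* = (e − 30)/10 below age 30 and 0 above, and β_s, γ, η are
site/sex/model-specific parameters. ERR is a dimensionless multiplier of
the baseline rate; EAR is an absolute excess (the shipped parameters are
per 10⁴ person-years per Sv). For low-dose diagnostic exposures the linear
coefficient for solid cancers is divided by the dose and dose-rate
effectiveness factor (DDREF, default 1.5); leukemia is not DDREF-reduced.

The excess site-specific rate M(D,e,a) transports the model to a target
population: under ERR transport it is ERR × the population's baseline rate
λ^c(a); under EAR transport it is the EAR itself converted to per
person-year. The lifetime attributable risk then sums the survival-weighted
excess rates from the end of the latency period to age 100:

    LAR(D,e) = Σ_{a=e+L}^{100} M(D,e,a) · S(a)/S(e),

with L = 5 years for solid tumors and 2 years for leukemia.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lifetables import (
    PER_100K,
    TERMINAL_AGE,
    CancerRateTable,
    LifeTable,
    conditional_survival,
    rate_at,
)

log = logging.getLogger(__name__)

LEUKEMIA_SITES = {"leukemia"}

#: EAR β in the shipped parameter file is per 10^4 person-years per Sv
EAR_PER_PERSON_YEARS = 1e4


class MissingParamsError(KeyError):
    pass


@dataclass(frozen=True)
class RiskParams:
    """One (site, sex, model) row of the risk-parameter table."""

    site: str
    sex: str
    model: str  # "ERR" | "EAR"
    beta: float  # per Sv (ERR) or per 10^4 PY per Sv (EAR)
    gamma: float  # per decade of e*
    eta: float  # exponent of (a/60)
    source: str = ""

    def __post_init__(self) -> None:
        if self.model not in ("ERR", "EAR"):
            raise ValueError(f"model must be ERR or EAR, got {self.model!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def is_leukemia(self) -> bool:
        return self.site in LEUKEMIA_SITES


@dataclass
class RiskParamsTable:
    rows: dict[tuple[str, str, str], RiskParams]

    def get(self, site: str, sex: str, model: str) -> RiskParams:
        try:
            return self.rows[(site, sex, model)]
        except KeyError:
            raise MissingParamsError(
                f"no risk parameters for site={site!r}, sex={sex!r}, model={model!r}"
            ) from None

    def has(self, site: str, sex: str, model: str) -> bool:
        return (site, sex, model) in self.rows

    @property
    def sites(self) -> list[str]:
        return sorted({k[0] for k in self.rows})


def load_risk_params(path: str | Path) -> RiskParamsTable:
    """Read the parameter CSV (site, sex, model, beta, gamma, eta, units, source)."""
    frame = pd.read_csv(path, comment="#")
    rows = {}
    for _, r in frame.iterrows():
        p = RiskParams(
            site=str(r["site"]),
            sex=str(r["sex"]),
            model=str(r["model"]),
            beta=float(r["beta"]),
            gamma=float(r["gamma"]),
            eta=float(r["eta"]),
            source=str(r.get("source", "")),
        )
        key = (p.site, p.sex, p.model)
        if key in rows:
            raise ValueError(f"duplicate parameter row for {key}")
        rows[key] = p
    return RiskParamsTable(rows=rows)


def load_shipped_params() -> RiskParamsTable:
    """Load the risk-parameter table shipped with the package."""
    with resources.as_file(resources.files("nmdrl") / "data" / "risk_params.csv") as p:
        return load_risk_params(p)


#: coefficient-table organ name -> risk-model cancer site
ORGAN_TO_SITE = {
    "liver": "liver",
    "kidneys": "kidney",
    "kidney": "kidney",
    "urinary_bladder": "bladder",
    "bladder": "bladder",
    "thyroid": "thyroid",
    "stomach": "stomach",
    "stomach_wall": "stomach",
    "colon": "colon",
    "lungs": "lung",
    "lung": "lung",
    "ovaries": "ovary",
    "uterus": "uterus",
    "prostate": "prostate",
    "salivary_glands": "salivary_gland",
    "red_marrow": "leukemia",
}


def eligible_organ_sites(table_organs: Sequence[str], params: RiskParamsTable,
                         sex: str, model: str = "ERR") -> dict[str, str]:
    """Organs of a coefficient table with a usable risk-parameter row.

    Eligibility simply means a (site, sex, model) parameter row exists for
    the organ's mapped cancer site.
    """
    out = {}
    for organ in table_organs:
        site = ORGAN_TO_SITE.get(organ)
        if site and params.has(site, sex, model):
            out[organ] = site
    return out


@dataclass(frozen=True)
class RiskConfig:
    """Engine configuration with the BEIR VII defaults."""

    ddref: float = 1.5
    latency_solid: float = 5.0  # years
    latency_leukemia: float = 2.0  # years
    upper_age: int = TERMINAL_AGE
    transport: str = "ERR"  # which model carries the transport

    def __post_init__(self) -> None:
        if self.ddref < 1:
            raise ValueError("ddref must be >= 1")
        if self.latency_solid < 0 or self.latency_leukemia < 0:
            raise ValueError("latencies must be >= 0")
        if self.upper_age > TERMINAL_AGE:
            raise ValueError(f"upper_age must be <= {TERMINAL_AGE}")
        if self.transport not in ("ERR", "EAR"):
            raise ValueError("transport must be ERR or EAR")

    def latency(self, site: str) -> float:
        return self.latency_leukemia if site in LEUKEMIA_SITES else self.latency_solid

    def snapshot(self) -> dict:
        """Config dict embedded in every risk report for auditability."""
        return {
            "ddref": self.ddref,
            "latency_solid_years": self.latency_solid,
            "latency_leukemia_years": self.latency_leukemia,
            "upper_age_years": self.upper_age,
            "transport": self.transport,
        }


def e_star(e: float) -> float:
    """Transformed age-at-exposure: (e − 30)/10 below 30, 0 at or above 30."""
    if e < 0:
        raise ValueError("exposure age must be >= 0")
    return (e - 30.0) / 10.0 if e < 30 else 0.0


def err_ear(D: float, e: float, a: float, params: RiskParams,
            config: RiskConfig = RiskConfig()) -> float:
    """Evaluate β_s·D_eff·exp(γ·e*)·(a/60)^η.

    D_eff is D/DDREF for solid-cancer sites (low-dose evaluation) and D
    itself for leukemia. ERR rows return a dimensionless excess relative
    risk; EAR rows return an excess absolute rate per 10⁴ person-years.
    """
    if D < 0:
        raise ValueError("dose must be >= 0")
    if a < e:
        raise ValueError("attained age must be >= exposure age")
    if a < 1:
        raise ValueError("attained age must be >= 1")
    d_eff = D if params.is_leukemia else D / config.ddref
    return params.beta * d_eff * np.exp(params.gamma * e_star(e)) * (a / 60.0) ** params.eta


def m_dea(D: float, e: float, a: float, params: RiskParams, rates: CancerRateTable,
          config: RiskConfig = RiskConfig(), endpoint: str = "incidence") -> float:
    """Excess site-specific rate M(D,e,a), per person-year.

    ERR transport multiplies the excess relative risk by the target
    population's baseline rate λ^c(a) for the chosen endpoint; EAR transport
    converts the absolute excess to per person-year directly (the baseline
    cancels, the endpoint argument is ignored).
    """
    excess = err_ear(D, e, a, params, config)
    if params.model == "ERR":
        lam = rate_at(rates, params.site, params.sex, int(a), endpoint=endpoint)
        return max(excess * lam, 0.0)
    return max(excess / EAR_PER_PERSON_YEARS, 0.0)


def lar(D: float, e: int, params: RiskParams, rates: CancerRateTable,
        lifetable: LifeTable, config: RiskConfig = RiskConfig(),
        endpoint: str = "incidence") -> float:
    """Lifetime attributable risk: Σ_{a=e+L}^{upper_age} M(D,e,a)·S(a)/S(e).

    Integer attained ages, bounds inclusive. Interpretable as the excess
    lifetime probability of the endpoint; multiply by 100 000 for the
    per-100 000-exposed convention. Returns 0 (with a logged note) when the
    latency pushes past the terminal age.
    """
    start = int(np.ceil(e + config.latency(params.site)))
    if start > config.upper_age:
        log.warning("e + L = %d exceeds upper age %d: no risk-bearing ages remain",
                    start, config.upper_age)
        return 0.0
    total = 0.0
    for a in range(start, config.upper_age + 1):
        total += m_dea(D, e, a, params, rates, config, endpoint) * conditional_survival(lifetable, e, a)
    return total


@dataclass
class RiskCurve:
    """The three reporting curves for one exposure: ERR(a), M(a) and LAR.

    ``lar_cumulative`` is the scalar lifetime risk for the exposure age
    ``exposure_age``; ``lar_by_exposure_age`` re-evaluates the lifetime risk
    as a function of hypothetical exposure age over ``exposure_grid``.
    """

    site: str
    sex: str
    model: str
    exposure_age: int
    dose_sv: float
    endpoint: str
    attained_ages: np.ndarray
    err_values: np.ndarray  # ERR (dimensionless) or EAR (per 10^4 PY)
    m_values: np.ndarray  # per person-year
    lar_cumulative: float
    lar_per_100k: float
    exposure_grid: np.ndarray
    lar_by_exposure_age: np.ndarray
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "attained_age_years": self.attained_ages,
                "excess_risk": self.err_values,
                "m_per_person_year": self.m_values,
            }
        )


def risk_curves(D: float, e: int, site: str, sex: str, params_table: RiskParamsTable,
                rates: CancerRateTable, lifetable: LifeTable,
                config: RiskConfig = RiskConfig(), endpoint: str = "incidence",
                exposure_grid: Sequence[int] | None = None) -> RiskCurve:
    """Tabulate ERR(a) and M(a) over the risk-bearing ages and the LAR.

    The lifetime risk is reported both for the actual exposure age ``e`` and
    across ``exposure_grid`` (default every 5 years from 0 to 95), which is
    how lifetime-risk-versus-exposure-age figures are drawn.
    """
    p = params_table.get(site, sex, config.transport)
    start = int(np.ceil(e + config.latency(site)))
    ages = np.arange(start, config.upper_age + 1) if start <= config.upper_age else np.array([], dtype=int)
    errs = np.array([err_ear(D, e, a, p, config) for a in ages])
    ms = np.array([m_dea(D, e, a, p, rates, config, endpoint) for a in ages])
    total = lar(D, e, p, rates, lifetable, config, endpoint)
    grid = np.asarray(exposure_grid if exposure_grid is not None else np.arange(0, 96, 5), dtype=int)
    lar_grid = np.array([lar(D, int(ee), p, rates, lifetable, config, endpoint) for ee in grid])
    return RiskCurve(
        site=site, sex=sex, model=config.transport, exposure_age=e, dose_sv=D,
        endpoint=endpoint, attained_ages=ages, err_values=errs, m_values=ms,
        lar_cumulative=total, lar_per_100k=total * PER_100K,
        exposure_grid=grid, lar_by_exposure_age=lar_grid,
        config=config.snapshot(),
    )


def mgy_to_sv(dose_mgy: float) -> float:
    """Equivalent dose (Sv) from absorbed dose (mGy), radiation weighting factor 1.

    Appropriate for the photon/electron emitters used diagnostically.
    """
    return dose_mgy / 1000.0
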