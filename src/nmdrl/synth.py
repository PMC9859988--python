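"""Seeded generators for registries, life tables, rate tables and coefficient tables.

Every input the pipeline consumes can be synthesized here so the whole tool
is exercisable offline. Administered activities are lognormal per protocol
(activity distributions in practice are right-skewed and positive), ages are
drawn from a mixture over 5-year bins, anthropometry is normal by sex, and
the life table is a Gompertz survivorship — the standard two-parameter
adult-mortality law. The generators are deterministic given their seed, and
each written CSV records its parameters in ``#`` comment headers so fixtures
are self-describing.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lifetables import TERMINAL_AGE, CancerRateTable, LifeTable, load_rate_table
from .registry import DEFAULT_COLUMNS


@dataclass(frozen=True)
class ProtocolModel:
    """Lognormal activity model for one procedure protocol."""

    radiopharmaceutical: str
    mu_log: float  # ln(MBq) median on the log scale
    sigma_log: float = 0.25
    weight_scaled: bool = False  # scale activity by weight/70 kg

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")


#: plausible central activities for the common diagnostic protocols; test
#: scaffolding, not clinical guidance.
DEFAULT_PROTOCOLS: dict[str, ProtocolModel] = {
    "DMSA-99mTc renal static": ProtocolModel("DMSA-99mTc", np.log(185.0)),
    "DTPA-99mTc renal dynamic": ProtocolModel("DTPA-99mTc", np.log(370.0)),
    "FDG-18F whole body": ProtocolModel("FDG-18F", np.log(370.0), weight_scaled=True),
    "MDP-99mTc bone": ProtocolModel("MDP-99mTc", np.log(925.0)),
    "MIBI-99mTc myocardium rest": ProtocolModel("MIBI-99mTc-rest", np.log(740.0)),
    "MIBI-99mTc myocardium stress": ProtocolModel("MIBI-99mTc-stress", np.log(1110.0)),
    "MIBI-99mTc parathyroid": ProtocolModel("MIBI-99mTc-parathyroid", np.log(740.0)),
}


@dataclass
class RegistryModel:
    """Generative model for a synthetic administration registry."""

    protocols: Mapping[str, ProtocolModel] = field(
        default_factory=lambda: dict(DEFAULT_PROTOCOLS)
    )
    n: int = 1000
    seed: int = 0
    #: probability weight of each 5-year age bin [5k, 5k+5), k = 0..19
    age_bin_weights: Sequence[float] | None = None
    female_fraction: float = 0.5
    #: (mean, sd) of adult weight kg and height m by sex
    weight_kg: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (78.0, 12.0), "female": (68.0, 12.0)}
    )
    height_m: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (1.73, 0.07), "female": (1.61, 0.07)}
    )
    #: residual syringe activity as a uniform fraction of the prescription
    residual_fraction: tuple[float, float] = (0.01, 0.05)
    start_date: _dt.date = _dt.date(2017, 1, 1)


def _default_age_weights() -> np.ndarray:
    # adult-heavy mixture: most nuclear-medicine patients are 40-75
    k = np.arange(20)
    w = np.exp(-0.5 * ((5 * k + 2.5 - 57.5) / 17.5) ** 2) + 0.05
    return w / w.sum()


def generate_registry(model: RegistryModel, path: str | Path | None = None) -> pd.DataFrame:
    """Draw a synthetic registry; optionally write it as a loader-ready CSV.

    Deterministic for a given model+seed (same seed → byte-identical file).
    Net administered activity is the lognormal draw; the prescription adds a
    uniform residual fraction on top, so prescribed = administered + residual
    and every row passes registry validation.
    """
    rng = np.random.default_rng(model.seed)
    weights = (np.asarray(model.age_bin_weights, dtype=float)
               if model.age_bin_weights is not None else _default_age_weights())
    weights = weights / weights.sum()
    names = sorted(model.protocols)
    rows = []
    for i in range(model.n):
        proto_name = names[int(rng.integers(len(names)))]
        proto = model.protocols[proto_name]
        sex = "female" if rng.random() < model.female_fraction else "male"
        bin_k = int(rng.choice(len(weights), p=weights))
        age = int(5 * bin_k + rng.integers(5))
        w_mean, w_sd = model.weight_kg[sex]
        h_mean, h_sd = model.height_m[sex]
        if age < 18:
            # crude pediatric scaling keeps anthropometry physiologic
            scale = max(age, 1) / 18.0
            w_mean, w_sd = max(w_mean * scale, 4.0), max(w_sd * scale, 1.0)
            h_mean, h_sd = max(h_mean * (0.45 + 0.55 * scale), 0.5), 0.05
        weight = float(np.clip(rng.normal(w_mean, w_sd), 3.0, 200.0))
        height = float(np.clip(rng.normal(h_mean, h_sd), 0.45, 2.2))
        administered = float(rng.lognormal(proto.mu_log, proto.sigma_log))
        if proto.weight_scaled:
            administered *= weight / 70.0
        frac = float(rng.uniform(*model.residual_fraction))
        prescribed = administered / (1.0 - frac)
        residual = prescribed - administered
        date = model.start_date + _dt.timedelta(days=int(rng.integers(0, 1096)))
        rows.append(
            {
                DEFAULT_COLUMNS["patient_id"]: f"P{i:06d}",
                DEFAULT_COLUMNS["protocol"]: proto_name,
                DEFAULT_COLUMNS["radiopharmaceutical"]: proto.radiopharmaceutical,
                DEFAULT_COLUMNS["prescribed_activity"]: round(prescribed, 3),
                DEFAULT_COLUMNS["residual_activity"]: round(residual, 3),
                DEFAULT_COLUMNS["sex"]: sex,
                DEFAULT_COLUMNS["age"]: age,
                DEFAULT_COLUMNS["weight"]: round(weight, 1),
                DEFAULT_COLUMNS["height"]: round(height, 2),
                DEFAULT_COLUMNS["exam_date"]: date.isoformat(),
            }
        )
    frame = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))
    if path is not None:
        _write_with_header(
            frame, path,
            [f"synthetic registry: n={model.n} seed={model.seed}",
             f"protocols={names}"],
        )
    return frame


def _write_with_header(frame: pd.DataFrame, path: str | Path, comments: Sequence[str]) -> None:
    buf = io.StringIO()
    for line in comments:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def gompertz_survival(ages: np.ndarray, B: float, theta: float) -> np.ndarray:
    """Gompertz survivorship S(a) = exp(−(B/θ)(e^{θa} − 1))."""
    if B <= 0 or theta <= 0:
        raise ValueError("Gompertz parameters must be positive")
    return np.exp(-(B / theta) * (np.expm1(theta * np.asarray(ages, dtype=float))))


def generate_lifetable(B: float = 1e-4, theta: float = 0.09, sex: str = "both",
                       path: str | Path | None = None) -> LifeTable:
    """Deterministic Gompertz life table at integer ages 0..100."""
    ages = np.arange(TERMINAL_AGE + 1)
    s = gompertz_survival(ages, B, theta)
    table = LifeTable(survivors=s, sex=sex)
    if path is not None:
        frame = pd.DataFrame({"sex": sex, "age": ages, "survivors": table.survivors})
        _write_with_header(frame, path, [f"synthetic Gompertz life table: B={B} theta={theta}"])
    return table


def powerlaw_rate(scale_per_100k: float = 50.0, power: float = 3.0,
                  pivot_age: float = 60.0) -> Callable[[np.ndarray], np.ndarray]:
    """Rate model λ(a) = scale·(a/pivot)^power per 100k — adult-cancer-like rise."""
    def f(ages: np.ndarray) -> np.ndarray:
        return scale_per_100k * (np.asarray(ages, dtype=float) / pivot_age) ** power
    return f


def constant_rate(level_per_100k: float) -> Callable[[np.ndarray], np.ndarray]:
    def f(ages: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(ages).shape, float(level_per_100k))
    return f


def generate_rate_table(
    sites: Sequence[str],
    sexes: Sequence[str] = ("male", "female"),
    incidence_model: Callable[[np.ndarray], np.ndarray] | None = None,
    mortality_model: Callable[[np.ndarray], np.ndarray] | None = None,
    banded: bool = False,
    path: str | Path | None = None,
) -> CancerRateTable:
    """Deterministic synthetic incidence/mortality rate table.

    Default models: power-law incidence rising to 50/100k at age 60 and
    mortality at half the incidence. With ``banded`` the CSV uses 5-year
    half-open bands (as cancer atlases do); otherwise single ages.
    """
    inc = incidence_model or powerlaw_rate(50.0, 3.0)
    mort = mortality_model or (lambda a: 0.5 * inc(a))
    ages = np.arange(TERMINAL_AGE + 1)
    inc_vals = np.maximum(inc(ages), 0.0)
    mort_vals = np.maximum(mort(ages), 0.0)
    rows = []
    for site in sites:
        for sex in sexes:
            for a in ages:
                rows.append({"site": site, "sex": sex, "age": int(a),
                             "incidence_per_100k": float(inc_vals[a]),
                             "mortality_per_100k": float(mort_vals[a])})
    frame = pd.DataFrame(rows)
    table = CancerRateTable(frame=frame)
    if path is not None:
        if banded:
            brows = []
            for site in sites:
                for sex in sexes:
                    for lo in range(0, TERMINAL_AGE + 1, 5):
                        hi = lo + 5
                        brows.append({
                            "site": site, "sex": sex, "age_low": lo,
                            "age_high": "inf" if hi > TERMINAL_AGE else hi,
                            "incidence_per_100k": float(inc_vals[lo]),
                            "mortality_per_100k": float(mort_vals[lo]),
                        })
            _write_with_header(pd.DataFrame(brows), path, ["synthetic banded rate table"])
        else:
            _write_with_header(frame, path, ["synthetic single-age rate table"])
    return table


def generate_coefficient_table(
    radiopharmaceutical: str = "SYNTH-99mTc",
    organs: Sequence[str] = ("liver", "kidneys", "urinary_bladder", "thyroid"),
    alpha: float = 0.05,
    beta: float = -0.012,
    anchor_ages: Sequence[float] = (1.0, 5.0, 10.0, 15.0, 18.0),
    jitter: float = 0.0,
    seed: int = 0,
    path: str | Path | None = None,
):
    """Synthetic coefficient table with exactly log-linear anchors (plus optional jitter).

    Each organ's anchors follow c(age) = α·k + β·k·ln(age) for a per-organ
    scale k, so the log-curve fit recovers them exactly when ``jitter`` is 0.
    """
    from .dosimetry import DoseCoefficientTable  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    ages = np.asarray(anchor_ages, dtype=float)
    organ_coefs = {}
    for i, organ in enumerate(organs):
        k = 1.0 + 0.5 * i
        vals = (alpha + beta * np.log(ages)) * k
        if jitter:
            vals = vals * (1.0 + rng.uniform(-jitter, jitter, size=vals.size))
        if np.any(vals <= 0):
            raise ValueError("model produced non-positive coefficients; adjust alpha/beta")
        organ_coefs[organ] = vals
    effective = (alpha + beta * np.log(ages)) * 0.8
    table = DoseCoefficientTable(
        radiopharmaceutical=radiopharmaceutical,
        anchor_ages=ages,
        organ_coefficients=organ_coefs,
        effective_coefficients=effective,
        sources={o: "synthetic" for o in organs},
    )
    if path is not None:
        cols = {"organ": list(organs) + ["effective"]}
        for j, age in enumerate(ages):
            tag = "adult" if j == len(ages) - 1 else str(int(age))
            cols[f"age_{tag}"] = [organ_coefs[o][j] for o in organs] + [effective[j]]
        cols["source"] = ["synthetic"] * (len(organs) + 1)
        _write_with_header(
            pd.DataFrame(cols), path,
            [f"radiopharmaceutical: {radiopharmaceutical}", f"synthetic coefficients seed={seed}"],
        )
    return table
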