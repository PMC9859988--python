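"""Population life tables and baseline cancer rates for risk transport.

Transporting a radiation risk model to a target population needs two
population inputs: a survivorship function S(a) (the probability of being
alive at age a) from the national life table, and baseline cancer incidence
and mortality rates by site, sex and age. Both are indexed here by integer
age 0..100, the range the lifetime-risk sum runs over; abridged inputs
(5-year bands) are expanded by holding the band value constant within the
band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TERMINAL_AGE = 100
#: floor applied to survivorship so conditional ratios never divide by zero
SURVIVAL_FLOOR = 1e-12


@dataclass
class LifeTable:
    """Survivorship S(a) at integer ages 0..100 for one sex.

    S is normalized to S(0) = 1 and must be non-increasing; the terminal
    values are floored at a tiny positive number.
    """

    survivors: np.ndarray
    sex: str = "both"

    def __post_init__(self) -> None:
        s = np.asarray(self.survivors, dtype=float)
        if s.size != TERMINAL_AGE + 1:
            raise ValueError(f"need survivorship at ages 0..{TERMINAL_AGE} ({TERMINAL_AGE + 1} values)")
        if s[0] <= 0:
            raise ValueError("S(0) must be positive")
        s = s / s[0]
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survivorship must be non-increasing")
        self.survivors = np.maximum(s, SURVIVAL_FLOOR)

    def S(self, a: int) -> float:
        if not 0 <= a <= TERMINAL_AGE:
            raise ValueError(f"age {a} outside 0..{TERMINAL_AGE}")
        return float(self.survivors[a])

    def qx(self) -> np.ndarray:
        """Per-age death probabilities recovered as q(a) = 1 − S(a+1)/S(a)."""
        s = self.survivors
        return 1.0 - s[1:] / s[:-1]


def survival_from_mortality(qx: Sequence[float], sex: str = "both") -> LifeTable:
    """Build a LifeTable from per-age death probabilities q(a), a = 0..99.

    Standard actuarial construction: S(0) = 1, S(a+1) = S(a)·(1 − q(a)).
    """
    q = np.asarray(qx, dtype=float)
    if q.size != TERMINAL_AGE:
        raise ValueError(f"need {TERMINAL_AGE} death probabilities (ages 0..{TERMINAL_AGE - 1})")
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("death probabilities must lie in [0, 1)")
    s = np.empty(TERMINAL_AGE + 1)
    s[0] = 1.0
    np.cumprod(1.0 - q, out=s[1:])
    return LifeTable(survivors=s, sex=sex)


def conditional_survival(table: LifeTable, e: int, a: int) -> float:
    """S(a)/S(e): probability of reaching age a given alive at age e."""
    if a < e:
        raise ValueError(f"attained age {a} < exposure age {e}")
    se = table.S(e)
    if se <= SURVIVAL_FLOOR:
        raise ValueError(f"S({e}) is zero; conditional survival undefined")
    return table.S(a) / se


def load_life_table(path: str | Path, sex: str | None = None) -> LifeTable:
    """Read a life-table CSV with columns sex, age and survivors or qx.

    Banded ages (columns age_low/age_high) are expanded constant-within-band.
    """
    frame = pd.read_csv(path, comment="#")
    if sex is not None and "sex" in frame.columns:
        frame = frame[frame["sex"] == sex]
        if frame.empty:
            raise ValueError(f"{path}: no rows for sex {sex!r}")
    sex = sex or (str(frame["sex"].iloc[0]) if "sex" in frame.columns else "both")
    if "survivors" in frame.columns:
        ages = frame["age"].to_numpy(dtype=int)
        surv = frame["survivors"].to_numpy(dtype=float)
        full = np.interp(np.arange(TERMINAL_AGE + 1), ages, surv)
        return LifeTable(survivors=full, sex=sex)
    if "qx" in frame.columns:
        q = np.zeros(TERMINAL_AGE)
        ages = frame["age"].to_numpy(dtype=int)
        vals = frame["qx"].to_numpy(dtype=float)
        for a, v in zip(ages, vals):
            if 0 <= a < TERMINAL_AGE:
                q[a] = v
        return survival_from_mortality(q, sex=sex)
    raise ValueError(f"{path}: need a 'survivors' or 'qx' column")


PER_100K = 1e5


class UnknownSiteError(KeyError):
    pass


@dataclass
class CancerRateTable:
    """Baseline cancer incidence and mortality rates by site, sex and age.

    Internally a long-format DataFrame expanded to single ages 0..100; input
    rates are per 100 000 person-years, as national cancer atlases print
    them.
    """

    frame: pd.DataFrame  # columns: site, sex, age, incidence_per_100k, mortality_per_100k

    def __post_init__(self) -> None:
        required = {"site", "sex", "age", "incidence_per_100k", "mortality_per_100k"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        if (self.frame[["incidence_per_100k", "mortality_per_100k"]] < 0).any().any():
            raise ValueError("rates must be non-negative")
        self._index = {
            (site, sex): sub.set_index("age")
            for (site, sex), sub in self.frame.groupby(["site", "sex"], sort=True)
        }

    @property
    def sites(self) -> list[str]:
        return sorted(self.frame["site"].unique())

    def lookup(self, site: str, sex: str, a: int, endpoint: str = "incidence") -> float:
        """Rate per person-year (input per-100k value divided by 100 000)."""
        if not 0 <= a <= TERMINAL_AGE:
            raise ValueError(f"age {a} outside 0..{TERMINAL_AGE}")
        if endpoint not in ("incidence", "mortality"):
            raise ValueError(f"endpoint must be incidence or mortality, got {endpoint!r}")
        try:
            sub = self._index[(site, sex)]
        except KeyError:
            raise UnknownSiteError(f"no rates for site={site!r}, sex={sex!r}") from None
        try:
            value = float(sub.loc[a, f"{endpoint}_per_100k"])
        except KeyError:
            raise ValueError(f"no rate tabulated at age {a} for {site}/{sex}") from None
        return value / PER_100K


def rate_at(table: CancerRateTable, site: str, sex: str, a: int,
            endpoint: str = "incidence") -> float:
    """Baseline rate λ^c(a) per person-year for one site, sex and integer age."""
    return table.lookup(site, sex, a, endpoint=endpoint)


def load_rate_table(path: str | Path) -> CancerRateTable:
    """Read a rate CSV (site, sex, age_low, age_high, incidence/mortality per 100k).

    Bands are half-open [age_low, age_high) and expand constant-within-band
    to integer ages; an open-ended final band (blank or "inf" age_high)
    extends to age 100. Single-age files with an ``age`` column are accepted
    as-is.
    """
    frame = pd.read_csv(path, comment="#")
    if "age" in frame.columns:
        return CancerRateTable(frame=frame)
    rows = []
    for _, row in frame.iterrows():
        lo = int(row["age_low"])
        hi_raw = row["age_high"]
        hi = TERMINAL_AGE if (pd.isna(hi_raw) or str(hi_raw).lower() in ("inf", "")) else int(hi_raw) - 1
        hi = min(hi, TERMINAL_AGE)
        for a in range(lo, hi + 1):
            rows.append(
                {
                    "site": row["site"],
                    "sex": row["sex"],
                    "age": a,
                    "incidence_per_100k": float(row["incidence_per_100k"]),
                    "mortality_per_100k": float(row["mortality_per_100k"]),
                }
            )
    return CancerRateTable(frame=pd.DataFrame(rows))
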