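"""Diagnostic reference levels in administered activity (DRLA).

The DRLA of a procedure stratum is the third quartile (75th percentile) of
the administered activities observed in it — the conventional benchmark for
auditing whether a service's prescriptions sit within normal practice.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import BMI_CLASSES, StratumKey

QUANTILE_METHODS = ("linear", "nearest_rank")


def third_quartile(values: Sequence[float], method: str = "linear") -> float:
    """Third quartile of a non-empty list of activities (MBq).

    ``linear`` (default) uses order-statistic interpolation with plotting
    position h = (n−1)·0.75 + 1. ``nearest_rank`` returns the ⌈0.75·n⌉-th
    order statistic, offered for comparability with survey conventions that
    avoid interpolation.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("third quartile undefined for an empty list")
    if np.any(vals < 0):
        raise ValueError("activities must be non-negative")
    if method == "linear":
        return float(np.quantile(vals, 0.75, method="linear"))
    if method == "nearest_rank":
        k = int(np.ceil(0.75 * vals.size))
        return float(np.sort(vals)[k - 1])
    raise ValueError(f"unknown quantile method {method!r}; choose from {QUANTILE_METHODS}")


@dataclass(frozen=True)
class DRLAEntry:
    """DRLA summary for one stratum."""

    stratum: StratumKey
    n: int
    min: float
    median: float
    drla: float  # Q3, MBq
    max: float
    flag: str = ""  # "", "insufficient n", or "n < <advisory>"


def _age_bin_sort_key(label: str) -> int:
    m = re.match(r"\[(\d+),", label)
    return int(m.group(1)) if m else -1


def _bmi_sort_key(label: str) -> int:
    try:
        return BMI_CLASSES.index(label)
    except ValueError:
        return len(BMI_CLASSES)


def _stratum_sort_key(key: StratumKey):
    return (key.protocol, key.sex, _age_bin_sort_key(key.age_bin), _bmi_sort_key(key.bmi_class))


def drla_table(
    strata: Mapping[StratumKey, Sequence[float]],
    min_n: int = 1,
    advisory_n: int = 10,
    method: str = "linear",
) -> list[DRLAEntry]:
    """One DRLAEntry per stratum, sorted by protocol, sex, age bin, BMI class.

    Strata with fewer than ``min_n`` administrations are kept in the output
    but flagged "insufficient n" so they can be excluded from reference-level
    reporting; strata below the ``advisory_n`` recommendation (DRLs from tiny
    samples are unstable) carry an advisory flag.
    """
    entries: list[DRLAEntry] = []
    for key in sorted(strata, key=_stratum_sort_key):
        vals = np.asarray(strata[key], dtype=float)
        if vals.size == 0:
            continue
        if vals.size < min_n:
            flag = "insufficient n"
        elif vals.size < advisory_n:
            flag = f"n < {advisory_n}"
        else:
            flag = ""
        entries.append(
            DRLAEntry(
                stratum=key,
                n=int(vals.size),
                min=float(vals.min()),
                median=float(np.median(vals)),
                drla=third_quartile(vals, method=method),
                max=float(vals.max()),
                flag=flag,
            )
        )
    return entries


def compare_to_reference(activity: float, drla: float) -> tuple[float, bool]:
    """Ratio of an administered activity to the stratum DRLA and an above-DRL flag.

    The flag is strict: an activity exactly at the reference level is not
    "above".
    """
    if drla <= 0:
        raise ValueError("reference DRLA must be > 0")
    ratio = activity / drla
    return ratio, ratio > 1.0


def to_frame(entries: Sequence[DRLAEntry]) -> pd.DataFrame:
    """Tabulate DRLA entries with explicit units in the column headers."""
    rows = []
    for e in entries:
        rows.append(
            {
                "protocol": e.stratum.protocol,
                "sex": e.stratum.sex,
                "age_bin_years": e.stratum.age_bin,
                "bmi_class": e.stratum.bmi_class,
                "n": e.n,
                "min_mbq": e.min,
                "median_mbq": e.median,
                "drla_q3_mbq": e.drla,
                "max_mbq": e.max,
                "flag": e.flag,
            }
        )
    cols = ["protocol", "sex", "age_bin_years", "bmi_class", "n",
            "min_mbq", "median_mbq", "drla_q3_mbq", "max_mbq", "flag"]
    return pd.DataFrame(rows, columns=cols)


def write_report(entries: Sequence[DRLAEntry], path: str | Path, fmt: str = "csv") -> None:
    """Write the DRLA report as CSV or JSON."""
    frame = to_frame(entries)
    path = Path(path)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
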