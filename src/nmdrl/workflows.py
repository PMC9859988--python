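"""End-to-end report workflows tying the modules together.

These functions are what the CLI subcommands call: a DRL survey over a
registry file, and a combined dose + reference-comparison + risk report for
a single administration. Reports are deterministic functions of their
inputs and configuration; every numeric column carries its units in the
header, and the log records input-file hashes so a regulator can audit what
a report was computed from.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import drl as _drl
from . import dosimetry as _dosi
from . import lifetables as _lt
from . import registry as _reg
from . import risk as _risk

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths + options for a full run; loadable from YAML."""

    registry_path: str | None = None
    coefficient_dir: str | None = None  # None -> shipped tables
    lifetable_path: str | None = None  # None -> synthetic Gompertz default
    rate_table_path: str | None = None  # None -> synthetic default rates
    risk_params_path: str | None = None  # None -> shipped parameter file
    axes: Sequence[str] = field(default_factory=lambda: list(_reg.ALL_AXES))
    quantile_method: str = "linear"
    min_n: int = 1
    bmi_cutoffs: Sequence[float] = field(default_factory=lambda: list(_reg.DEFAULT_BMI_CUTOFFS))
    per_kg: bool = False
    risk: _risk.RiskConfig = field(default_factory=_risk.RiskConfig)
    endpoint: str = "incidence"
    output_format: str = "csv"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        risk_cfg = _risk.RiskConfig(**raw.pop("risk", {}))
        return cls(risk=risk_cfg, **raw)


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_coefficients(config: RunConfig, radiopharmaceutical: str) -> _dosi.DoseCoefficientTable:
    if config.coefficient_dir:
        return _dosi.load_coefficient_table(
            Path(config.coefficient_dir) / f"{radiopharmaceutical}.csv"
        )
    return _dosi.load_shipped_table(radiopharmaceutical)


def _load_risk_inputs(config: RunConfig, sex: str):
    from . import synth  # lazily: workflows do not always need it
    params = (_risk.load_risk_params(config.risk_params_path)
              if config.risk_params_path else _risk.load_shipped_params())
    if config.lifetable_path:
        lifetable = _lt.load_life_table(config.lifetable_path, sex=sex)
    else:
        lifetable = synth.generate_lifetable(sex=sex)
    if config.rate_table_path:
        rates = _lt.load_rate_table(config.rate_table_path)
    else:
        rates = synth.generate_rate_table(sites=params.sites, sexes=("male", "female"))
    return params, lifetable, rates


def run_drl(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """DRL survey: load the registry, stratify, write the DRLA + rejects reports.

    Returns the DRLA table; writes ``drla_report.csv`` (or .json) and
    ``rejects.csv`` under ``out_dir``.
    """
    if not config.registry_path:
        raise ValueError("run_drl requires registry_path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("registry %s sha256=%s", config.registry_path, _hash_file(config.registry_path))
    result = _reg.load_registry(config.registry_path)
    if not result.records:
        log.warning("registry %s produced no valid records", config.registry_path)
    strata = _reg.stratify(result.records, axes=config.axes,
                           bmi_cutoffs=config.bmi_cutoffs, per_kg=config.per_kg)
    entries = _drl.drla_table(strata, min_n=config.min_n, method=config.quantile_method)
    ext = "json" if config.output_format == "json" else "csv"
    _drl.write_report(entries, out_dir / f"drla_report.{ext}",
                      fmt="json" if ext == "json" else "csv")
    result.write_rejects(out_dir / "rejects.csv")
    return _drl.to_frame(entries)


@dataclass
class PatientSpec:
    """Inputs for a single dose + risk report."""

    radiopharmaceutical: str
    activity: float  # MBq, net administered
    age: int
    sex: str


def run_dose_risk(config: RunConfig, spec: PatientSpec,
                  out_dir: str | Path | None = None,
                  drla_reference: float | None = None) -> dict:
    """Combined report: organ doses, DRLA comparison and risk curves.

    Organ doses come from the coefficient table at the patient's age; each
    risk-eligible organ (one with a parameter row for its cancer site) gets
    the three risk curves. A missing parameter row downgrades that organ to
    a warning, never a crash. The returned dict is JSON-serializable and
    embeds the risk-config snapshot.
    """
    table = _load_coefficients(config, spec.radiopharmaceutical)
    params, lifetable, rates = _load_risk_inputs(config, spec.sex)
    eligible = _risk.eligible_organ_sites(table.organs, params, spec.sex,
                                          model=config.risk.transport)
    report_dose = _dosi.dose_map_query(table, spec.activity, spec.age, spec.sex,
                                       eligible_sites=eligible)
    organ_rows = []
    risk_blocks = {}
    for organ, dose_mgy in sorted(report_dose.organ_doses.items()):
        row = {"organ": organ, "absorbed_dose_mgy": dose_mgy,
               "risk_eligible": organ in report_dose.risk_eligible}
        if drla_reference is not None and drla_reference > 0:
            ratio, above = _drl.compare_to_reference(spec.activity, drla_reference)
            row["activity_over_drla"] = ratio
            row["above_drla"] = above
        organ_rows.append(row)
        if organ not in report_dose.risk_eligible:
            if organ in _risk.ORGAN_TO_SITE:
                log.warning("organ %s: no %s parameters for sex=%s; skipping risk",
                            organ, config.risk.transport, spec.sex)
            continue
        site = eligible[organ]
        try:
            curve = _risk.risk_curves(
                _risk.mgy_to_sv(dose_mgy), spec.age, site, spec.sex,
                params, rates, lifetable, config=config.risk, endpoint=config.endpoint,
            )
        except (_risk.MissingParamsError, _lt.UnknownSiteError) as exc:
            log.warning("organ %s: %s", organ, exc)
            continue
        risk_blocks[organ] = {
            "site": site,
            "dose_sv": curve.dose_sv,
            "lar": curve.lar_cumulative,
            "lar_per_100k_exposed": curve.lar_per_100k,
            "attained_ages_years": curve.attained_ages.tolist(),
            "excess_risk": curve.err_values.tolist(),
            "m_per_person_year": curve.m_values.tolist(),
            "lar_exposure_grid_years": curve.exposure_grid.tolist(),
            "lar_by_exposure_age": curve.lar_by_exposure_age.tolist(),
        }
    report = {
        "patient": {
            "radiopharmaceutical": spec.radiopharmaceutical,
            "administered_activity_mbq": spec.activity,
            "age_years": spec.age,
            "sex": spec.sex,
        },
        "effective_dose_msv": report_dose.effective_dose,
        "organ_doses": organ_rows,
        "risk": risk_blocks,
        "risk_config": config.risk.snapshot(),
        "endpoint": config.endpoint,
    }
    if drla_reference is not None:
        report["drla_reference_mbq"] = drla_reference
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "dose_risk_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        pd.DataFrame(organ_rows).to_csv(out_dir / "organ_doses.csv", index=False)
    return report
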