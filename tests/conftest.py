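import numpy as np
import pandas as pd
import pytest

from nmdrl import lifetables as lt
from nmdrl import risk as rk
from nmdrl import synth


REGISTRY_HEADER = ("patient_id,protocol,radiopharmaceutical,prescribed_mbq,"
                   "residual_mbq,sex,age_years,weight_kg,height_m,exam_date")


def make_registry_csv(tmp_path, rows, name="registry.csv"):
    path = tmp_path / name
    path.write_text(REGISTRY_HEADER + "\n" + "\n".join(rows) + ("\n" if rows else "\n"))
    return path


@pytest.fixture
def registry_csv_factory(tmp_path):
    return lambda rows, name="registry.csv": make_registry_csv(tmp_path, rows, name)


@pytest.fixture
def well_formed_rows():
    return [
        "P1,MIBI rest,MIBI-99mTc-rest,760,20,male,40,78,1.75,2018-03-01",
        "P2,MIBI rest,MIBI-99mTc-rest,755.5,15.5,female,43,68,1.61,2018-03-02",
        "P3,MDP bone,MDP-99mTc,940,15,male,62,82,1.7,2018-04-10",
    ]


@pytest.fixture(scope="session")
def gompertz_table():
    return synth.generate_lifetable(B=1e-4, theta=0.09, sex="male")


@pytest.fixture(scope="session")
def flat_rates():
    """Constant 50/100k incidence, 25/100k mortality at all ages, both sexes."""
    return synth.generate_rate_table(
        sites=["liver", "stomach", "leukemia"],
        incidence_model=synth.constant_rate(50.0),
        mortality_model=synth.constant_rate(25.0),
    )


@pytest.fixture(scope="session")
def toy_params():
    """Synthetic ERR/EAR parameter rows independent of the shipped file."""
    rows = {}
    for sex in ("male", "female"):
        for site, beta in (("liver", 0.5), ("stomach", 0.3), ("leukemia", 1.0)):
            rows[(site, sex, "ERR")] = rk.RiskParams(site, sex, "ERR", beta, -0.3, -1.4)
            rows[(site, sex, "EAR")] = rk.RiskParams(site, sex, "EAR", beta * 4, -0.41, 2.8)
    return rk.RiskParamsTable(rows=rows)


def naive_lar(D, e, params, rates, lifetable, config, endpoint="incidence"):
    """Independent brute-force lifetime-risk sum used as the oracle.

    Re-derives every term from first principles: the risk-model product, the
    baseline-rate lookup and the survival ratio, without calling the engine.
    """
    L = config.latency_leukemia if params.site == "leukemia" else config.latency_solid
    start = int(np.ceil(e + L))
    total = 0.0
    for a in range(start, config.upper_age + 1):
        estar = (e - 30.0) / 10.0 if e < 30 else 0.0
        d_eff = D if params.site == "leukemia" else D / config.ddref
        excess = params.beta * d_eff * np.exp(params.gamma * estar) * (a / 60.0) ** params.eta
        if params.model == "ERR":
            sub = rates.frame
            m = sub[(sub["site"] == params.site) & (sub["sex"] == params.sex)
                    & (sub["age"] == a)][f"{endpoint}_per_100k"].iloc[0] / 1e5 * excess
        else:
            m = excess / 1e4
        total += m * lifetable.survivors[a] / lifetable.survivors[e]
    return total
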