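import numpy as np
import pytest

from nmdrl import lifetables as lt
from nmdrl import risk as rk
from nmdrl import synth
from conftest import naive_lar

IMMORTAL = lt.LifeTable(survivors=np.ones(101))


def _params(site="liver", sex="male", model="ERR", beta=0.5, gamma=-0.3, eta=-1.4):
    return rk.RiskParams(site, sex, model, beta, gamma, eta)


class TestEStar:
    @pytest.mark.parametrize("e,expected", [(40, 0.0), (30, 0.0), (20, -1.0), (0, -3.0)])
    def test_piecewise_definition(self, e, expected):
        assert rk.e_star(e) == expected


class TestErrEar:
    def test_zero_dose_gives_zero(self):
        assert rk.err_ear(0.0, 40, 60, _params()) == 0.0

    def test_reference_age_identity(self):
        # at a = 60 and e >= 30 both modifier terms equal 1
        cfg = rk.RiskConfig(ddref=1.0)
        assert rk.err_ear(0.2, 40, 60, _params(beta=0.5), cfg) == pytest.approx(0.1)

    def test_direct_evaluation_at_a90(self):
        # beta·D·(90/60)^(-1.4) with no DDREF reduction and e >= 30
        cfg = rk.RiskConfig(ddref=1.0)
        got = rk.err_ear(0.1, 40, 90, _params(beta=0.5, gamma=-0.3, eta=-1.4), cfg)
        assert got == pytest.approx(0.5 * 0.1 * 1.5 ** -1.4, rel=1e-12)
        assert got == pytest.approx(0.02834277, rel=1e-6)

    def test_ddref_divides_solid_but_not_leukemia(self):
        cfg = rk.RiskConfig(ddref=1.5)
        solid = rk.err_ear(0.3, 40, 60, _params(site="liver"), cfg)
        leuk = rk.err_ear(0.3, 40, 60, _params(site="leukemia"), cfg)
        assert leuk == pytest.approx(1.5 * solid)

    def test_linear_in_dose(self):
        p = _params()
        assert rk.err_ear(0.4, 20, 70, p) == pytest.approx(2 * rk.err_ear(0.2, 20, 70, p))

    def test_attained_age_before_exposure_rejected(self):
        with pytest.raises(ValueError):
            rk.err_ear(0.1, 50, 40, _params())


class TestMdea:
    def test_zero_dose_zero_everywhere(self, flat_rates):
        for a in (50, 70, 100):
            assert rk.m_dea(0.0, 40, a, _params(), flat_rates) == 0.0

    def test_zero_baseline_rate_zeroes_err_transport(self):
        zero = synth.generate_rate_table(["liver"], incidence_model=synth.constant_rate(0),
                                         mortality_model=synth.constant_rate(0))
        assert rk.m_dea(0.5, 40, 70, _params(), zero) == 0.0

    def test_product_of_err_and_rate(self, flat_rates):
        cfg = rk.RiskConfig(ddref=1.0)
        p = _params(beta=1.0, gamma=0.0, eta=0.0)
        # ERR = 0.05 at every age; lambda = 5e-4 per person-year
        assert rk.m_dea(0.05, 40, 70, p, flat_rates, cfg) == pytest.approx(2.5e-5)

    def test_ear_transport_ignores_baseline(self, flat_rates):
        cfg = rk.RiskConfig(ddref=1.0, transport="EAR")
        p = _params(model="EAR", beta=2.0, gamma=0.0, eta=0.0)
        # EAR = 2.0·D per 1e4 PY -> /1e4 per person-year
        assert rk.m_dea(0.1, 40, 70, p, flat_rates, cfg) == pytest.approx(2e-5)


class TestLar:
    def test_zero_dose_gives_zero(self, flat_rates, gompertz_table):
        assert rk.lar(0.0, 40, _params(), flat_rates, gompertz_table) == 0.0

    def test_immortal_population_closed_form(self, flat_rates):
        # constant M = m summed over ages 45..100 inclusive = 56·m
        cfg = rk.RiskConfig(ddref=1.0)
        p = _params(beta=1.0, gamma=0.0, eta=0.0)
        m = 0.05 * 5e-4
        got = rk.lar(0.05, 40, p, flat_rates, IMMORTAL, cfg)
        assert got == pytest.approx(m * 56, rel=1e-12)

    def test_two_term_hand_sum_near_terminal_age(self):
        # e = 94, L = 5 -> only ages 99 and 100 contribute
        s = np.ones(101)
        s[99], s[100] = 0.4, 0.3
        s[95:99] = np.linspace(0.9, 0.5, 4)
        s[:95] = 1.0
        table = lt.LifeTable(survivors=np.minimum.accumulate(s))
        rates = synth.generate_rate_table(["liver"], incidence_model=synth.constant_rate(100.0),
                                          mortality_model=synth.constant_rate(50.0))
        cfg = rk.RiskConfig(ddref=1.0)
        p = _params(beta=1.0, gamma=0.0, eta=0.0)
        D = 0.2
        lam = 1e-3
        expected = D * lam * (0.4 / 1.0) + D * lam * (0.3 / 1.0)
        got = rk.lar(D, 94, p, rates, table, cfg)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_latency_past_terminal_age_returns_zero(self, flat_rates, gompertz_table):
        assert rk.lar(0.1, 97, _params(), flat_rates, gompertz_table) == 0.0

    def test_matches_naive_oracle_on_random_toy_inputs(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            qx = rng.uniform(0.0, 0.1, size=100)
            lifetable = lt.survival_from_mortality(qx)
            level = float(rng.uniform(5, 200))
            site = rng.choice(["liver", "leukemia"])
            model = rng.choice(["ERR", "EAR"])
            rates = synth.generate_rate_table(
                [site], incidence_model=synth.constant_rate(level),
                mortality_model=synth.constant_rate(level / 2),
            )
            p = rk.RiskParams(site, "male", model, float(rng.uniform(0.1, 2.0)),
                              float(rng.uniform(-0.5, 0.0)), float(rng.uniform(-2.0, 3.0)))
            cfg = rk.RiskConfig(ddref=float(rng.uniform(1.0, 2.0)),
                                transport=model)
            e = int(rng.integers(0, 90))
            D = float(rng.uniform(0.001, 0.5))
            got = rk.lar(D, e, p, rates, lifetable, cfg)
            expected = naive_lar(D, e, p, rates, lifetable, cfg)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_linear_in_dose(self, flat_rates, gompertz_table):
        p = _params()
        one = rk.lar(0.01, 40, p, flat_rates, gompertz_table)
        assert rk.lar(0.02, 40, p, flat_rates, gompertz_table) == pytest.approx(2 * one, rel=1e-12)
        assert one > 0

    def test_ddref_unity_scales_solid_lar_by_1p5(self, flat_rates, gompertz_table):
        p = _params()
        base = rk.lar(0.1, 40, p, flat_rates, gompertz_table, rk.RiskConfig(ddref=1.5))
        boosted = rk.lar(0.1, 40, p, flat_rates, gompertz_table, rk.RiskConfig(ddref=1.0))
        assert boosted == pytest.approx(1.5 * base, rel=1e-12)

    def test_truncating_upper_age_never_increases_lar(self, flat_rates, gompertz_table):
        p = _params()
        vals = [rk.lar(0.1, 40, p, flat_rates, gompertz_table, rk.RiskConfig(upper_age=u))
                for u in (100, 90, 80, 70, 60)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_sex_symmetric_inputs_give_identical_lar(self, flat_rates, gompertz_table):
        pm = _params(sex="male")
        pf = _params(sex="female")
        m = rk.lar(0.1, 40, pm, flat_rates, gompertz_table)
        f = rk.lar(0.1, 40, pf, flat_rates, gompertz_table)
        assert m == pytest.approx(f, rel=1e-12)


class TestRiskCurves:
    def test_zero_dose_zeroes_all_three_curves(self, toy_params, flat_rates, gompertz_table):
        c = rk.risk_curves(0.0, 40, "liver", "male", toy_params, flat_rates, gompertz_table)
        assert np.all(c.err_values == 0) and np.all(c.m_values == 0)
        assert c.lar_cumulative == 0.0

    def test_curve_length_covers_latency_to_terminal(self, toy_params, flat_rates, gompertz_table):
        c = rk.risk_curves(0.01, 40, "liver", "male", toy_params, flat_rates, gompertz_table)
        assert len(c.attained_ages) == 100 - 45 + 1
        assert c.attained_ages[0] == 45 and c.attained_ages[-1] == 100

    def test_lar_finite_nonnegative_across_exposure_ages(self, toy_params, flat_rates,
                                                         gompertz_table):
        c = rk.risk_curves(0.01, 40, "liver", "male", toy_params, flat_rates, gompertz_table,
                           exposure_grid=range(0, 96, 5))
        assert np.all(np.isfinite(c.lar_by_exposure_age))
        assert np.all(c.lar_by_exposure_age >= 0)

    def test_config_snapshot_carries_engine_defaults(self, toy_params, flat_rates,
                                                     gompertz_table):
        c = rk.risk_curves(0.01, 40, "liver", "male", toy_params, flat_rates, gompertz_table)
        assert c.config["ddref"] == 1.5
        assert c.config["latency_solid_years"] == 5.0
        assert c.config["latency_leukemia_years"] == 2.0

    def test_missing_parameter_row_raises(self, toy_params, flat_rates, gompertz_table):
        with pytest.raises(rk.MissingParamsError):
            rk.risk_curves(0.01, 40, "pancreas", "male", toy_params, flat_rates, gompertz_table)


class TestShippedParams:
    def test_shipped_file_loads_with_expected_structure(self):
        params = rk.load_shipped_params()
        liver = params.get("liver", "male", "ERR")
        assert liver.gamma == pytest.approx(-0.30)
        assert liver.eta == pytest.approx(-1.4)
        assert {"liver", "stomach", "bladder", "thyroid", "kidney", "leukemia"} <= set(params.sites)

    def test_eligibility_is_parameter_row_availability(self):
        params = rk.load_shipped_params()
        organs = ["liver", "kidneys", "urinary_bladder", "thyroid", "heart_wall", "pancreas"]
        eligible = rk.eligible_organ_sites(organs, params, "male")
        assert set(eligible) == {"liver", "kidneys", "urinary_bladder", "thyroid"}
        assert eligible["kidneys"] == "kidney"
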