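import numpy as np
import pytest

from nmdrl import dosimetry as dosi
from nmdrl import risk as rk
from nmdrl.synth import generate_coefficient_table

AGES = np.array([1.0, 5.0, 10.0, 15.0, 18.0])


def _table(organ_coefs, effective=None, ages=AGES):
    effective = effective if effective is not None else 0.009 * np.ones(len(ages))
    return dosi.DoseCoefficientTable(
        radiopharmaceutical="SYNTH",
        anchor_ages=ages,
        organ_coefficients=organ_coefs,
        effective_coefficients=effective,
    )


class TestFitLogCurve:
    def test_recovers_exact_log_linear_anchors(self):
        alpha, beta = 0.5, -0.1
        coefs = alpha + beta * np.log(AGES)
        fit = dosi.fit_log_curve(AGES, coefs)
        assert fit.alpha == pytest.approx(alpha, abs=1e-9)
        assert fit.beta == pytest.approx(beta, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.mode == "log_fit"

    def test_constant_anchors_use_zero_variance_convention(self):
        fit = dosi.fit_log_curve(AGES, np.full(5, 0.02))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 1.0

    def test_discordant_anchor_triggers_piecewise_fallback(self):
        # four log-linear points plus one wildly off, as tabulated
        # coefficients sometimes are for small hollow organs
        coefs = 0.05 - 0.012 * np.log(AGES)
        coefs[2] *= 4.0
        fit = dosi.fit_log_curve(AGES, coefs, r2_threshold=0.90)
        assert fit.r_squared < 0.90
        assert fit.mode == "piecewise_log"

    def test_r_squared_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            coefs = np.abs(rng.normal(0.03, 0.01, size=5)) + 1e-3
            fit = dosi.fit_log_curve(AGES, coefs)
            x = np.log(AGES)
            pred = fit.alpha + fit.beta * x
            ss_res = np.sum((coefs - pred) ** 2)
            ss_tot = np.sum((coefs - coefs.mean()) ** 2)
            assert fit.r_squared == pytest.approx(
                min(max(1 - ss_res / ss_tot, 0.0), 1.0), abs=1e-10
            )

    def test_fewer_than_three_anchors_errors(self):
        with pytest.raises(ValueError):
            dosi.fit_log_curve([1.0, 18.0], [0.02, 0.01])


class TestCoefficientAtAge:
    def test_piecewise_mode_reproduces_every_anchor(self):
        coefs = np.array([0.06, 0.033, 0.021, 0.015, 0.011])
        table = _table({"liver": coefs})
        for age, c in zip(AGES, coefs):
            got = dosi.coefficient_at_age(table, "liver", age, mode="piecewise_log")
            assert got == pytest.approx(c, rel=1e-12)

    def test_adult_clamp(self):
        table = _table({"liver": np.array([0.06, 0.033, 0.021, 0.015, 0.011])})
        assert dosi.coefficient_at_age(table, "liver", 40.0) == pytest.approx(0.011)
        assert dosi.coefficient_at_age(table, "liver", 18.0) == pytest.approx(0.011)

    def test_infant_clamp(self):
        table = _table({"liver": np.array([0.06, 0.033, 0.021, 0.015, 0.011])})
        assert dosi.coefficient_at_age(table, "liver", 0.3) == pytest.approx(0.06)

    def test_piecewise_between_anchors_interpolates_log_log(self):
        # hand evaluation: ln c linear in ln age between (5, 0.02) and (10, 0.01)
        ages = np.array([1.0, 5.0, 10.0, 15.0, 18.0])
        coefs = np.array([0.05, 0.02, 0.01, 0.008, 0.007])
        table = _table({"o": coefs}, ages=ages)
        t = (np.log(7) - np.log(5)) / (np.log(10) - np.log(5))
        expected = np.exp(np.log(0.02) + t * (np.log(0.01) - np.log(0.02)))
        got = dosi.coefficient_at_age(table, "o", 7.0, mode="piecewise_log")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0142857, rel=1e-5)

    def test_log_fit_mode_exact_on_log_linear_anchors(self):
        coefs = 0.05 - 0.012 * np.log(AGES)
        table = _table({"o": coefs})
        got = dosi.coefficient_at_age(table, "o", 7.0, mode="log_fit")
        assert got == pytest.approx(0.05 - 0.012 * np.log(7.0), rel=1e-9)

    def test_unknown_organ_named_in_error(self):
        table = _table({"liver": np.full(5, 0.01)})
        with pytest.raises(dosi.UnknownOrganError, match="spleen"):
            dosi.coefficient_at_age(table, "spleen", 10.0)


class TestDose:
    @pytest.mark.parametrize(
        "activity,coef,expected",
        [(740.0, 0.011, 8.14), (0.0, 0.02, 0.0), (100.0, 0.02, 2.0)],
    )
    def test_absorbed_dose_is_activity_times_coefficient(self, activity, coef, expected):
        assert dosi.absorbed_dose(activity, coef) == pytest.approx(expected)

    def test_effective_dose_arithmetic_and_linearity(self):
        assert dosi.effective_dose(740.0, 0.009) == pytest.approx(6.66)
        assert dosi.effective_dose(2 * 740.0, 0.009) == pytest.approx(2 * 6.66)

    def test_millicurie_conversion(self):
        assert dosi.mci_to_mbq(20.0) == pytest.approx(740.0)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            dosi.absorbed_dose(-1.0, 0.01)


class TestDoseMapQuery:
    def test_worked_example_liver_dose_and_eligibility(self):
        table = dosi.load_shipped_table("MIBI-99mTc-rest")
        params = rk.load_shipped_params()
        eligible = rk.eligible_organ_sites(table.organs, params, "male")
        report = dosi.dose_map_query(table, 740.0, 40, "male", eligible_sites=eligible)
        assert report.organ_doses["liver"] == pytest.approx(8.14, abs=0.005)
        assert report.risk_eligible == {"liver", "kidneys", "urinary_bladder", "thyroid"}

    def test_zero_activity_zeroes_all_organs(self):
        table = generate_coefficient_table()
        report = dosi.dose_map_query(table, 0.0, 30, "female")
        assert all(v == 0.0 for v in report.organ_doses.values())
        assert report.effective_dose == 0.0

    def test_child_dose_exceeds_adult_for_decreasing_anchors(self):
        table = generate_coefficient_table()  # log-linear decreasing anchors
        young = dosi.dose_map_query(table, 500.0, 5, "male")
        adult = dosi.dose_map_query(table, 500.0, 40, "male")
        for organ in table.organs:
            assert young.organ_doses[organ] >= adult.organ_doses[organ]

    def test_dose_linear_in_activity_at_any_age(self):
        table = generate_coefficient_table()
        one = dosi.dose_map_query(table, 100.0, 12, "male")
        three = dosi.dose_map_query(table, 300.0, 12, "male")
        for organ in table.organs:
            assert three.organ_doses[organ] == pytest.approx(3 * one.organ_doses[organ])

    def test_unknown_radiopharmaceutical_raises_named_error(self):
        with pytest.raises(dosi.UnknownRadiopharmaceuticalError, match="XYZ"):
            dosi.load_shipped_table("XYZ")


class TestTableIO:
    def test_shipped_tables_all_load_and_validate(self):
        keys = dosi.available_radiopharmaceuticals()
        assert "MIBI-99mTc-rest" in keys and "FDG-18F" in keys
        for key in keys:
            table = dosi.load_shipped_table(key)
            assert table.organs
            assert np.all(table.effective_coefficients > 0)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "SYNTH-99mTc.csv"
        written = generate_coefficient_table(path=path)
        loaded = dosi.load_coefficient_table(path)
        assert loaded.radiopharmaceutical == "SYNTH-99mTc"
        for organ in written.organs:
            np.testing.assert_allclose(
                loaded.organ_coefficients[organ], written.organ_coefficients[organ]
            )
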