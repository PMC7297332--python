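"""Risk engine: coefficient scaling, full LAR integral, invariants."""

import numpy as np
import pytest

from cathlar import (
    ExposureScenario,
    LarMethod,
    Outcome,
    Role,
    Sex,
    lar_by_scaling,
    lar_full_integral,
    lar_ratio,
    risk_report,
)
from cathlar.risk import format_risk_report


def scen(sex="M", dose=10.0, start=18, end=65, role=None):
    return ExposureScenario(
        sex=sex, annual_dose_msv=dose, age_start=start, age_end=end, role=role
    )


class TestScaling:
    @pytest.mark.parametrize(
        "sex,dose,outcome,expected_pct",
        [
            ("M", 3.49, "incidence", 1.07),
            ("F", 3.49, "incidence", 1.50),
            ("M", 1.30, "incidence", 0.40),
            ("F", 1.30, "incidence", 0.56),
            ("M", 3.49, "mortality", 0.59),
            ("F", 3.49, "mortality", 0.83),
            ("M", 1.30, "mortality", 0.22),
            ("F", 1.30, "mortality", 0.31),
        ],
    )
    def test_occupational_percentages(self, params, sex, dose, outcome, expected_pct):
        res = lar_by_scaling(scen(sex, dose), Outcome(outcome), params)
        assert round(res.lar_percent, 2) == expected_pct

    def test_reference_dose_returns_chronic_coefficient(self, params):
        res = lar_by_scaling(scen("M", 10.0), Outcome.INCIDENCE, params)
        assert res.lar_per_100k == pytest.approx(3059.0)

    def test_zero_dose_zero_risk(self, params):
        assert lar_by_scaling(scen(dose=0.0), Outcome.INCIDENCE, params).lar_per_100k == 0

    def test_exactly_linear_in_dose(self, params):
        one = lar_by_scaling(scen(dose=1.0), Outcome.INCIDENCE, params).lar_per_100k
        seven = lar_by_scaling(scen(dose=7.0), Outcome.INCIDENCE, params).lar_per_100k
        assert seven == pytest.approx(7 * one, rel=1e-12)

    def test_non_default_age_range_directed_to_integral(self, params):
        with pytest.raises(ValueError, match="lar_full_integral"):
            lar_by_scaling(scen(start=30, end=60), Outcome.INCIDENCE, params)

    def test_percent_is_per_100k_over_1000(self, params):
        res = lar_by_scaling(scen("F", 2.0), Outcome.MORTALITY, params)
        assert res.lar_percent == pytest.approx(res.lar_per_100k / 1000.0)


class TestFullIntegral:
    def test_zero_dose_gives_exactly_zero(self, params, tables):
        res = lar_full_integral(scen(dose=0.0), Outcome.INCIDENCE, params, tables)
        assert res.lar_per_100k == 0.0

    def test_chronic_scenario_near_published_coefficients(self, params, tables):
        for sex, target in (("M", 3059.0), ("F", 4295.0)):
            res = lar_full_integral(scen(sex), Outcome.INCIDENCE, params, tables)
            assert res.lar_per_100k == pytest.approx(target, rel=0.10)

    def test_linear_on_solid_only_parameters(self, params, tables):
        solid = params.subset([s for s, k in params.kind.items() if k == "solid"])
        full = lar_full_integral(scen(dose=10.0), Outcome.INCIDENCE, solid, tables)
        half = lar_full_integral(scen(dose=5.0), Outcome.INCIDENCE, solid, tables)
        assert half.lar_per_100k == pytest.approx(full.lar_per_100k / 2, rel=1e-6)

    def test_monotone_in_dose(self, params, tables):
        values = [
            lar_full_integral(scen(dose=d), Outcome.INCIDENCE, params, tables).lar_per_100k
            for d in (0.0, 1.0, 5.0, 10.0, 50.0)
        ]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_dose_vector_matches_constant(self, params, tables):
        const = lar_full_integral(scen(dose=3.0), Outcome.INCIDENCE, params, tables)
        vector = ExposureScenario(sex=Sex.M, annual_dose_msv=np.full(47, 3.0))
        vec = lar_full_integral(vector, Outcome.INCIDENCE, params, tables)
        assert vec.lar_per_100k == pytest.approx(const.lar_per_100k, rel=1e-12)

    def test_integration_step_stability(self, params, tables):
        coarse = lar_full_integral(
            scen(), Outcome.INCIDENCE, params, tables, step=1.0
        ).lar_per_100k
        for step in (0.5, 0.25):
            fine = lar_full_integral(
                scen(), Outcome.INCIDENCE, params, tables, step=step
            ).lar_per_100k
            assert abs(fine - coarse) / coarse < 0.005

    def test_incidence_exceeds_mortality(self, params, tables):
        for sex in ("M", "F"):
            inc = lar_full_integral(scen(sex), Outcome.INCIDENCE, params, tables)
            mort = lar_full_integral(scen(sex), Outcome.MORTALITY, params, tables)
            assert inc.lar_per_100k > mort.lar_per_100k

    def test_female_incidence_exceeds_male_at_equal_dose(self, params, tables):
        m = lar_full_integral(scen("M"), Outcome.INCIDENCE, params, tables)
        f = lar_full_integral(scen("F"), Outcome.INCIDENCE, params, tables)
        assert f.lar_per_100k > m.lar_per_100k

    def test_by_site_decomposition_sums_to_total(self, params, tables):
        res, sites = lar_full_integral(
            scen(), Outcome.INCIDENCE, params, tables, by_site=True
        )
        assert sum(sites.values()) == pytest.approx(res.lar_per_100k)
        assert set(sites) == set(params.sites_for(Sex.M))


class TestTables:
    def test_survival_bounds_and_monotonicity(self, tables):
        ages = np.arange(101)
        for sex in ("M", "F"):
            s = tables.survival(sex, ages)
            assert s[0] == 1.0
            assert np.all((s >= 0) & (s <= 1))
            assert np.all(np.diff(s) <= 1e-12)
            ratio = s / tables.survival(sex, 18)
            assert np.all(ratio[18:] <= 1 + 1e-12) and np.all(ratio >= 0)

    def test_out_of_range_age_rejected(self, tables):
        with pytest.raises(ValueError):
            tables.survival("M", np.array([101.0]))

    def test_female_incidence_coefficient_exceeds_male(self, params):
        ci = params.chronic_coefficients
        assert ci[(Sex.F, Outcome.INCIDENCE)] > ci[(Sex.M, Outcome.INCIDENCE)]


class TestRatioAndReport:
    def test_ratio_of_published_primary_cells(self, params):
        inc = lar_by_scaling(scen("M", 3.49), Outcome.INCIDENCE, params)
        mort = lar_by_scaling(scen("M", 3.49), Outcome.MORTALITY, params)
        assert lar_ratio(inc, mort) == pytest.approx(1.07 / 0.59, abs=0.01)

    def test_identical_inputs_give_unit_ratio(self, params):
        res = lar_by_scaling(scen("F", 2.0), Outcome.INCIDENCE, params)
        assert lar_ratio(res, res) == 1.0

    def test_zero_mortality_rejected(self, params):
        inc = lar_by_scaling(scen(dose=1.0), Outcome.INCIDENCE, params)
        zero = lar_by_scaling(scen(dose=0.0), Outcome.MORTALITY, params)
        # doses differ but sex/role/method match
        with pytest.raises(ZeroDivisionError):
            lar_ratio(inc, zero)

    def test_mismatched_results_rejected(self, params):
        inc = lar_by_scaling(scen("M", 3.49), Outcome.INCIDENCE, params)
        mort = lar_by_scaling(scen("F", 3.49), Outcome.MORTALITY, params)
        with pytest.raises(ValueError):
            lar_ratio(inc, mort)

    def test_report_grid_covers_all_cells(self, params):
        scenarios = [
            scen(sex, dose, role=role)
            for role, dose in ((Role.PRIMARY, 3.49), (Role.ASSISTANT, 1.30))
            for sex in (Sex.M, Sex.F)
        ]
        report = risk_report(scenarios, params)
        assert len(report) == 8
        cells = {
            (r.sex, r.role, r.outcome): r.lar_percent_2dp for r in report.itertuples()
        }
        assert cells[("M", "PRIMARY", "incidence")] == 1.07
        assert cells[("F", "ASSISTANT", "mortality")] == 0.31
        text = format_risk_report(report)
        assert "1.07" in text and "PRIMARY" in text

    def test_empty_scenario_list_rejected(self, params):
        with pytest.raises(ValueError):
            risk_report([], params)

    def test_report_is_deterministic(self, params):
        scenarios = [scen("M", 3.49, role=Role.PRIMARY)]
        a = risk_report(scenarios, params).to_csv(index=False)
        b = risk_report(scenarios, params).to_csv(index=False)
        assert a == b
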