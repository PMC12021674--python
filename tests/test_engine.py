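import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crcscreen as cs
from crcscreen.engine import (
    CohortState,
    StrategyResult,
    apply_incidence,
    apply_stage_mortality,
    colonoscopy_round,
    expected_perforations,
    life_years_lost,
    screening_round,
    shifted_stage_distribution,
)


def neutral_params(defaults):
    """A screening test that can never change outcomes (except kit usage)."""
    neutral = dataclasses.replace(
        defaults.colotect,
        sensitivity_crc=0.0,
        specificity_crc=1.0,
        prevention_fraction=0.0,
    )
    return dataclasses.replace(defaults, colotect=neutral)


class TestRunCohort:
    def test_zero_incidence_no_cases(self, defaults, life_table):
        tiny = cs.gen_incidence(1e-300, 0.0)
        for name in cs.STRATEGY_NAMES:
            res = cs.run_cohort(name, defaults, tiny, life_table)
            assert res.crc_cases_total == pytest.approx(0.0, abs=1e-250)
            assert res.loss_of_life_years == pytest.approx(0.0, abs=1e-250)

    def test_unknown_strategy(self, defaults, incidence, life_table):
        with pytest.raises(ValueError):
            cs.run_cohort("sigmoidoscopy", defaults, incidence, life_table)

    def test_invalid_params_rejected(self, defaults, incidence, life_table):
        bad = cs.set_value(defaults, "stages.distribution", [0.5, 0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="invalid parameters"):
            cs.run_cohort("none", bad, incidence, life_table)

    def test_incidence_must_cover_ages(self, defaults, life_table):
        short = cs.gen_incidence(1e-3, 0.0, start_age=50, end_age=70)
        with pytest.raises(ValueError, match="incidence"):
            cs.run_cohort("none", defaults, short, life_table)

    def test_closed_form_cumulative_cases(self, defaults, zero_mortality_life):
        """26 annual draws at constant hazard: N * (1 - (1 - r)^26)."""
        inc = cs.gen_incidence(1e-3, 0.0)
        res = cs.run_cohort("none", defaults, inc, zero_mortality_life)
        expected = 100_000 * (1.0 - (1.0 - 1e-3) ** 26)
        assert res.crc_cases_total == pytest.approx(expected, abs=1.0)

    def test_neutral_screening_equals_no_screening(self, defaults, incidence, life_table):
        params = neutral_params(defaults)
        res_none = cs.run_cohort("none", params, incidence, life_table)
        res_neutral = cs.run_cohort("colotect", params, incidence, life_table)
        assert res_neutral.crc_cases_total == pytest.approx(res_none.crc_cases_total, abs=1e-6)
        assert res_neutral.crc_deaths_total == pytest.approx(res_none.crc_deaths_total, abs=1e-6)
        assert res_neutral.loss_of_life_years == pytest.approx(
            res_none.loss_of_life_years, abs=1e-6
        )
        assert res_neutral.colonoscopies_total == 0.0
        # costs differ only by the test kits (others agree to float precision)
        extra = {
            k: v for k, v in res_neutral.cost_ledger.items()
            if abs(v - res_none.cost_ledger.get(k, 0.0)) > max(1e-9, 1e-9 * abs(v))
        }
        assert set(extra) == {"kits_colotect"}

    def test_mass_conservation_all_strategies(self, baseline_results, defaults):
        for res in baseline_results.values():
            dev = max(abs(m - defaults.settings.cohort_size) for m in res.mass_audit)
            assert dev < 1e-6

    def test_cases_equal_stage_sum(self, baseline_results):
        for res in baseline_results.values():
            assert res.crc_cases_total == pytest.approx(
                float(res.crc_cases_by_stage.sum()), abs=1e-9
            )

    def test_colonoscopy_split_identity(self, baseline_results):
        for res in baseline_results.values():
            assert res.colonoscopies_total == pytest.approx(
                res.colonoscopies_diagnostic + res.colonoscopies_therapeutic, abs=1e-6
            )

    def test_therapeutic_fraction_is_polypectomy_rate(self, baseline_results, defaults):
        rate = defaults.colonoscopy.polypectomy_rate
        for res in baseline_results.values():
            assert res.colonoscopies_therapeutic == pytest.approx(
                rate * res.colonoscopies_total, abs=0.5
            )

    def test_prevention_monotone_in_cases(self, defaults, incidence, life_table):
        cases = []
        for prev in (0.0, 0.25, 0.6, 1.0):
            params = cs.set_value(defaults, "colotect.prevention", prev)
            cases.append(cs.run_cohort("colotect", params, incidence, life_table).crc_cases_total)
        assert all(a >= b - 1e-9 for a, b in zip(cases, cases[1:]))

    def test_compliance_monotone_in_tests(self, defaults, incidence, life_table):
        tests = []
        for c in (0.2, 0.5, 0.8, 1.0):
            params = cs.set_value(defaults, "colotect.compliance", c)
            tests.append(cs.run_cohort("colotect", params, incidence, life_table).primary_tests)
        assert all(a <= b + 1e-9 for a, b in zip(tests, tests[1:]))

    def test_discount_zero_equals_undiscounted(self, defaults, incidence, life_table):
        params = cs.set_value(defaults, "settings.discount_rate", 0.0)
        res = cs.run_cohort("colotect", params, incidence, life_table)
        assert res.loss_of_life_years == pytest.approx(
            res.loss_of_life_years_undiscounted, rel=1e-12
        )
        assert res.total_cost == pytest.approx(res.total_cost_undiscounted, rel=1e-12)

    def test_attendance_models_run_and_order(self, defaults, incidence, life_table):
        by_model = {}
        for model in ("independent_per_round", "once_ever", "geometric_attrition"):
            params = cs.set_value(defaults, "settings.attendance_model", model)
            by_model[model] = cs.run_cohort("colotect", params, incidence, life_table)
        # attrition uses strictly fewer kits than per-round independence
        assert (
            by_model["geometric_attrition"].primary_tests
            < by_model["independent_per_round"].primary_tests
        )
        for res in by_model.values():
            dev = max(abs(m - 100_000) for m in res.mass_audit)
            assert dev < 1e-6

    @given(
        sens=st.floats(0.0, 1.0),
        spec=st.floats(0.5, 1.0),
        compliance=st.floats(0.0, 1.0),
        prevention=st.floats(0.0, 1.0),
        poly=st.floats(0.0, 0.5),
    )
    @settings(max_examples=25, deadline=None)
    def test_conservation_under_random_parameters(
        self, defaults, incidence, life_table, sens, spec, compliance, prevention, poly
    ):
        params = cs.set_value(defaults, "colotect.sensitivity", sens)
        params = cs.set_value(params, "colotect.specificity", spec)
        params = cs.set_value(params, "colotect.compliance", compliance)
        params = cs.set_value(params, "colotect.prevention", prevention)
        params = cs.set_value(params, "colonoscopy.polypectomy_rate", poly)
        res = cs.run_cohort("colotect", params, incidence, life_table)
        assert max(abs(m - 100_000) for m in res.mass_audit) < 1e-6


class TestScreeningRound:
    def _state(self, defaults, well, undiag):
        state = CohortState.initial(well + undiag, defaults.settings)
        state.well = well
        state.undiagnosed = undiag
        return state

    def test_zero_compliance(self, defaults):
        state = self._state(defaults, 1000.0, 10.0)
        test = dataclasses.replace(defaults.colotect, compliance=0.0)
        cancer, clean, tests, protected = screening_round(state, test, defaults)
        assert (cancer, clean, tests) == (0.0, 0.0, 0.0)
        assert protected == 0.0

    def test_expected_positives(self, defaults):
        """1000 attendees, 10 with cancer, sens .88 / spec .92 -> 88 positives."""
        state = self._state(defaults, 990.0, 10.0)
        test = dataclasses.replace(
            defaults.colotect, compliance=1.0, sensitivity_crc=0.88, specificity_crc=0.92
        )
        cancer, clean, tests, _ = screening_round(state, test, defaults)
        assert cancer + clean == pytest.approx(88.0)
        assert cancer == pytest.approx(8.8)
        assert tests == pytest.approx(1000.0)

    def test_perfect_specificity_no_false_referrals(self, defaults):
        state = self._state(defaults, 1000.0, 0.0)
        test = dataclasses.replace(defaults.colotect, compliance=1.0, specificity_crc=1.0)
        cancer, clean, _, _ = screening_round(state, test, defaults)
        assert cancer == 0.0
        assert clean == 0.0


class TestColonoscopyRound:
    def test_perforation_expectation(self, defaults):
        """100,792 colonoscopies at 0.08% -> 80.6 expected perforations."""
        state = CohortState.initial(200_000, defaults.settings)
        state.well = 200_000.0
        res = StrategyResult("x", 50)
        colonoscopy_round(state, res, defaults, 100_792.0, 0.0, 0.0, disc=1.0)
        assert res.perforations == pytest.approx(100_792 * 0.0008)
        assert round(res.perforations) == 81

    def test_therapeutic_split(self, defaults):
        state = CohortState.initial(10_000, defaults.settings)
        state.well = 10_000.0
        res = StrategyResult("x", 50)
        colonoscopy_round(state, res, defaults, 1000.0, 0.0, 0.0, disc=1.0)
        assert res.colonoscopies_therapeutic == pytest.approx(140.5)
        assert state.surveillance[0] + state.pause[0] == pytest.approx(
            1000.0 * (1 - defaults.colonoscopy.perforation_mortality)
        )

    def test_zero_colonoscopies_noop(self, defaults):
        state = CohortState.initial(1000, defaults.settings)
        state.well = 1000.0
        before = state.total()
        res = StrategyResult("x", 50)
        colonoscopy_round(state, res, defaults, 0.0, 0.0, 0.0, disc=1.0)
        assert state.total() == before
        assert res.colonoscopies_total == 0.0
        assert res.cost_ledger == {}

    def test_expected_perforations_helper(self):
        assert expected_perforations(13_796, 0.0008) == pytest.approx(11.0368)


class TestApplyIncidence:
    def test_full_prevention_zero_cases(self, defaults):
        state = CohortState.initial(100_000, defaults.settings)
        new = apply_incidence(state, 1e-3, prevention=1.0, protected_well=state.well)
        assert new == 0.0

    def test_prevention_factor(self, defaults):
        """rate 1e-3 on 100k fully protected at 54% prevention -> 46 cases."""
        state = CohortState.initial(100_000, defaults.settings)
        new = apply_incidence(state, 1e-3, prevention=0.54, protected_well=state.well)
        assert new == pytest.approx(46.0)

    def test_unprotected_full_rate(self, defaults):
        state = CohortState.initial(100_000, defaults.settings)
        new = apply_incidence(state, 1e-3, prevention=0.54, protected_well=0.0)
        assert new == pytest.approx(100.0)


class TestStageDistribution:
    def test_baseline_split(self, defaults):
        """100 clinically detected cases split 11.2 / 24.5 / 31.5 / 32.8."""
        d = np.asarray(defaults.stages.stage_distribution)
        assert np.allclose(100 * d, [11.2, 24.5, 31.5, 32.8])

    def test_shift_preserves_total(self, defaults):
        d = shifted_stage_distribution(defaults.stages.stage_distribution, 0.5)
        assert d.sum() == pytest.approx(1.0)
        assert d[0] > 0.112 and d[1] > 0.245
        assert d[2] < 0.315 and d[3] < 0.328

    def test_shift_zero_is_identity(self, defaults):
        d = shifted_stage_distribution(defaults.stages.stage_distribution, 0.0)
        assert np.allclose(d, defaults.stages.stage_distribution)


class TestStageMortality:
    def test_stage_iv_mortality(self, defaults):
        state = CohortState.initial(1000, defaults.settings)
        state.well = 0.0
        state.advanced = 1000.0
        deaths = apply_stage_mortality(state, defaults.stages)
        assert deaths == pytest.approx(430.0)
        assert state.advanced == pytest.approx(570.0)

    def test_stage_i_mortality(self, defaults):
        state = CohortState.initial(1000, defaults.settings)
        state.well = 0.0
        state.stage[0, 0] = 1000.0
        deaths = apply_stage_mortality(state, defaults.stages)
        assert deaths == pytest.approx(10.0)

    def test_zero_mass(self, defaults):
        state = CohortState.initial(0, defaults.settings)
        assert apply_stage_mortality(state, defaults.stages) == 0.0


class TestLifeYearsLost:
    def test_death_at_start_age_undiscounted(self, zero_mortality_life):
        # e(80) under zero mortality and closing age 110 is 30
        assert life_years_lost({80: 1.0}, zero_mortality_life, 0.0, 80) == pytest.approx(30.0)

    def test_discounted_death_ten_years_in(self):
        table = cs.gen_life_table(0.0, 0.0, 0.0, start_age=50, closing_age=80)
        # death at 60: e = 20, discounted by 1.03^10
        got = life_years_lost({60: 1.0}, table, 0.03, 50)
        assert got == pytest.approx(20.0 / 1.03**10, rel=1e-12)
        assert got == pytest.approx(14.8819, abs=1e-3)

    def test_no_deaths(self, life_table):
        assert life_years_lost({}, life_table, 0.03, 50) == 0.0


class TestMicrosim:
    def test_seed_determinism(self, defaults, incidence, life_table):
        a = cs.microsim_run("fit", defaults, incidence, life_table, n=5_000, seed=123)
        b = cs.microsim_run("fit", defaults, incidence, life_table, n=5_000, seed=123)
        assert a.crc_cases_total == b.crc_cases_total
        assert a.total_cost == b.total_cost
        assert a.loss_of_life_years == b.loss_of_life_years

    def test_zero_incidence(self, defaults, life_table):
        tiny = cs.gen_incidence(1e-300, 0.0)
        res = cs.microsim_run("colotect", defaults, tiny, life_table, n=2_000, seed=1)
        assert res.crc_cases_total == 0.0

    def test_n_validation(self, defaults, incidence, life_table):
        with pytest.raises(ValueError):
            cs.microsim_run("none", defaults, incidence, life_table, n=0, seed=1)

    def test_agreement_with_cohort(self, defaults, incidence, life_table):
        n = 60_000
        ms = cs.microsim_run("colotect", defaults, incidence, life_table, n=n, seed=42)
        co = cs.run_cohort("colotect", defaults, incidence, life_table)
        for attr in ("crc_cases_total", "crc_deaths_total"):
            m, c = getattr(ms, attr), getattr(co, attr)
            p = c / defaults.settings.cohort_size
            se3 = 3 * math.sqrt(p * (1 - p) / n) * defaults.settings.cohort_size
            assert abs(m - c) < se3, f"{attr}: |{m:.1f} - {c:.1f}| >= {se3:.1f}"
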