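"""Catalog integrity and scenario-application mechanics."""

import numpy as np
import pytest

from gcea.engine import FEMALE
from gcea.interventions import (
    EffectParams,
    Scenario,
    UnknownInterventionError,
    apply_scenario,
    build_catalog,
    null_scenario,
)
from gcea.outcomes import build_dw_set
from gcea.synthetic import base_cervical_rates, default_costing, sample_dw_inputs
import gcea.synthetic as syn


@pytest.fixture(scope="module")
def catalog():
    return build_catalog()


@pytest.fixture()
def cervical_inputs(demo_profiles):
    sea = demo_profiles[0]
    rates = {"cervical": base_cervical_rates(sea)}
    inputs = sample_dw_inputs(np.random.default_rng(0))
    dws = {
        "cervical": {
            "untreated": build_dw_set(inputs, "cervical", treated=False),
            "treated": build_dw_set(inputs, "cervical", treated=True),
        }
    }
    return rates, dws, inputs


class TestCatalog:
    def test_fourteen_interventions_partitioned_9_3_2(self, catalog):
        assert len(catalog) == 14
        by_cancer = {}
        for iv in catalog:
            by_cancer.setdefault(iv.cancer, []).append(iv.label)
        assert len(by_cancer["cervical"]) == 9
        assert len(by_cancer["breast"]) == 3
        assert len(by_cancer["colorectal"]) == 2
        assert len({iv.label for iv in catalog}) == 14

    def test_combination_is_union_of_components(self, catalog):
        by = {iv.label: iv for iv in catalog}
        assert by["C1e"].components == ("C1a", "C1b")
        assert set(by["C1e"].effects) == set(by["C1a"].effects) | set(by["C1b"].effects)

    def test_vaccination_eligibility_is_girls_9_to_13(self, catalog):
        c1a = next(iv for iv in catalog if iv.label == "C1a")
        elig = c1a.effects[0].eligible
        assert elig.sexes == (FEMALE,)
        assert (elig.age_lo, elig.age_hi) == (9, 13)

    def test_screening_schedules_are_explicit_config(self, catalog):
        by = {iv.label: iv for iv in catalog}
        assert by["C1d"].screen_interval == 5.0  # HPV test every 5 years
        assert by["C2b"].screen_interval == 2.0  # mammography every 2 years


class TestNullScenario:
    def test_null_is_identity_on_rates_and_dws(self, cervical_inputs, catalog):
        rates, dws, _ = cervical_inputs
        r2, d2, plan = apply_scenario(rates, dws, null_scenario(), catalog)
        for e, arr in rates["cervical"].rates.items():
            assert np.array_equal(r2["cervical"].rates[e], arr)
        assert r2["cervical"].multipliers == {}
        assert d2["cervical"].weights == dws["cervical"]["untreated"].weights
        assert plan == []

    def test_zero_coverage_reduces_to_null(self, cervical_inputs, catalog):
        rates, dws, _ = cervical_inputs
        s = Scenario.of(C1a=0.0, C1b=0.0)
        r2, d2, plan = apply_scenario(rates, dws, s, catalog)
        for e, arr in rates["cervical"].rates.items():
            assert np.array_equal(r2["cervical"].rates[e], arr)
        assert plan == []


class TestApplyScenario:
    def test_full_vaccination_zeroes_1618_hazard_only(self, cervical_inputs, catalog):
        rates, dws, _ = cervical_inputs
        params = EffectParams(vaccine_efficacy_16_18=1.0)
        cat = build_catalog(params)
        s = Scenario.of(C1a=1.0)
        r2, _, _ = apply_scenario(
            rates, dws, s, cat, params=params, horizon=50, allow_any_coverage=True
        )
        mult = r2["cervical"].multipliers[("healthy", "hpv_16_18")]
        # vaccinated female cohorts see multiplier 0; males untouched
        assert mult[10, FEMALE, 12] == 0.0
        assert mult[10, FEMALE, 22] == 0.0  # vaccinated 10 years earlier
        assert mult[10, FEMALE, 40] == 1.0  # too old to have been vaccinated
        assert np.all(mult[:, 1, :] == 1.0)
        assert ("healthy", "hpv_high_risk") not in r2["cervical"].multipliers
        assert ("healthy", "hpv_low_risk") not in r2["cervical"].multipliers

    def test_screening_boosts_diagnosis_in_eligible_band_only(
        self, cervical_inputs, catalog
    ):
        rates, dws, _ = cervical_inputs
        s = Scenario.of(C1b=0.8)
        r2, _, plan = apply_scenario(rates, dws, s, catalog)
        base = rates["cervical"].rates[("pre_I", "clin_I")]
        new = r2["cervical"].rates[("pre_I", "clin_I")]
        assert np.all(new[FEMALE, 30:50] > base[FEMALE, 30:50])
        assert np.array_equal(new[FEMALE, :30], base[FEMALE, :30])
        assert np.array_equal(new[FEMALE, 50:], base[FEMALE, 50:])
        # screen-and-treat adds CIN -> HPV regression
        assert np.all(
            r2["cervical"].rates[("cin1", "hpv_16_18")][FEMALE, 30:50]
            > rates["cervical"].rates[("cin1", "hpv_16_18")][FEMALE, 30:50]
        )
        assert any(e["kind"] == "screening" for e in plan)
        assert any(e["kind"] == "lesion_treatment" for e in plan)

    def test_rate_modification_linear_in_coverage(self, cervical_inputs, catalog):
        """Modified rate at coverage c equals the c-weighted mixture of the
        coverage-0 and coverage-1 modifications."""
        rates, dws, _ = cervical_inputs
        edge = ("pre_II", "clin_II")

        def modified(cov):
            s = Scenario.of(C1b=cov)
            r2, _, _ = apply_scenario(
                rates, dws, s, catalog, allow_any_coverage=True
            )
            return r2["cervical"].rates[edge][FEMALE, 40]

        r0, r1 = modified(0.0), modified(1.0)
        for c in (0.5, 0.8, 0.95):
            assert modified(c) == pytest.approx((1 - c) * r0 + c * r1, rel=1e-12)

    def test_treatment_scales_early_stage_fatality(self, cervical_inputs, catalog):
        rates, dws, _ = cervical_inputs
        p = EffectParams()
        m = p.treatment_fatality_multiplier["cervical"]
        s = Scenario.of(C1h=0.8)
        r2, d2, plan = apply_scenario(rates, dws, s, catalog)
        for stage in ("I", "II"):
            base = rates["cervical"].rates[(f"clin_{stage}", "dead")][FEMALE]
            new = r2["cervical"].rates[(f"clin_{stage}", "dead")][FEMALE]
            assert np.allclose(new, base * (1 - 0.8 * (1 - m)))
        # stages III/IV untouched
        for stage in ("III", "IV"):
            assert np.array_equal(
                r2["cervical"].rates[(f"clin_{stage}", "dead")],
                rates["cervical"].rates[(f"clin_{stage}", "dead")],
            )
        # treated DW blended for stages I-II
        u = dws["cervical"]["untreated"].get("cervical", "clin_I")
        t = dws["cervical"]["treated"].get("cervical", "clin_I")
        assert d2["cervical"].get("cervical", "clin_I") == pytest.approx(
            0.2 * u + 0.8 * t
        )

    def test_palliative_mixes_terminal_dw(self, demo_profiles):
        inputs = sample_dw_inputs(np.random.default_rng(1))
        rates = {"colorectal": syn.base_colorectal_rates(demo_profiles[0])}
        dws = {
            "colorectal": {
                "untreated": build_dw_set(inputs, "colorectal", treated=False),
                "treated": build_dw_set(inputs, "colorectal", treated=True),
            }
        }
        s = Scenario.of(C3b=0.95)
        _, d2, plan = apply_scenario(rates, dws, s)
        got = d2["colorectal"].get("colorectal", "clin_IV")
        want = 0.95 * inputs.dw_terminal_with_med + 0.05 * inputs.dw_terminal_without_med
        assert got == pytest.approx(want)
        assert plan[0]["kind"] == "palliative"

    def test_coverage_and_label_validation(self, cervical_inputs, catalog):
        rates, dws, _ = cervical_inputs
        with pytest.raises(ValueError):
            apply_scenario(rates, dws, Scenario.of(C1a=0.6), catalog)
        with pytest.raises(UnknownInterventionError):
            apply_scenario(rates, dws, Scenario.of(C9z=0.5), catalog)
        with pytest.raises(ValueError):
            apply_scenario(
                rates, dws, Scenario((("C1a", 0.5), ("C1a", 0.8))), catalog
            )


class TestScenarioSemantics:
    def test_combination_equals_joint_components(self, catalog):
        s_combo = Scenario.of(C1e=0.8)
        s_parts = Scenario.of(C1a=0.8, C1b=0.8)
        assert s_combo.expanded(catalog) == s_parts.expanded(catalog)

    def test_combination_simulation_matches_joint(self, sea_report):
        """C1e's evaluation is the joint C1a+C1b simulation, not a sum of
        separate gains."""
        ev = {
            (r.label, dict(r.coverages).get("C1a", 0), dict(r.coverages).get("C1b", 0)): r
            for r in sea_report.evaluations["cervical/prevention"]
        }
        combo = ev[("CVC_C1e", 0.8, 0.8)]
        a = ev[("CVC_C1a", 0.8, 0)]
        b = ev[("CVC_C1b", 0, 0.8)]
        additive = a.hly + b.hly
        assert combo.hly != pytest.approx(additive, rel=1e-6)
        assert combo.hly > max(a.hly, b.hly)
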