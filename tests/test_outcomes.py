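"""Disability-weight derivation, HLY accounting and costing arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from gcea.engine import N_AGES, Trajectory
from gcea.outcomes import (
    CostingParams,
    DisabilityWeightSet,
    GbdDwInputs,
    build_dw_set,
    derive_dw,
    discount_factors,
    healthy_life_years,
    scenario_cost,
)

INPUTS = GbdDwInputs(
    dw_diagnosis_primary_therapy=0.3,
    dw_metastatic=0.45,
    dw_terminal_with_med=0.5,
    dw_terminal_without_med=0.6,
    dw_mastectomy=0.1,
    dw_stoma=0.1,
)


class TestDeriveDw:
    def test_terminal_uses_gbd_estimate_directly(self):
        assert derive_dw(INPUTS, "breast", "IV", treated=True) == 0.5
        assert derive_dw(INPUTS, "breast", "IV", treated=False) == 0.6

    def test_untreated_preterminal_inflation_ratio(self):
        # 0.3 x (0.6 / 0.5) = 0.36, for every cancer and pre-terminal stage
        for cancer in ("cervical", "breast", "colorectal"):
            for stage in ("CIS", "I", "II", "III"):
                if cancer == "colorectal":
                    continue  # stoma mixture handled separately
                assert derive_dw(INPUTS, cancer, stage, treated=False) == pytest.approx(0.36)

    def test_treated_cervical_first_year_correction(self):
        assert derive_dw(
            INPUTS, "cervical", "I", treated=True, frac_first_year=0.5
        ) == pytest.approx(0.15)
        # stage III: no correction
        assert derive_dw(
            INPUTS, "cervical", "III", treated=True, frac_first_year=0.5
        ) == pytest.approx(0.3)

    def test_treated_breast_mastectomy_average(self):
        got = derive_dw(
            INPUTS, "breast", "I", treated=True,
            frac_first_year=0.5, mastectomy_weight=0.5,
        )
        assert got == pytest.approx((0.5 * 0.3 + 0.5 * 0.1) * 0.5)

    def test_treated_colorectal_stoma_mixture_oracle(self):
        # independently coded mixture: stoma patients carry the stoma DW on
        # top of the (first-year-corrected) diagnosis DW
        got = derive_dw(
            INPUTS, "colorectal", "I", treated=True,
            frac_first_year=0.5, frac_stoma=0.05,
        )
        dx_part = 0.3 * 0.5
        want = 0.95 * dx_part + 0.05 * (0.1 + dx_part)
        assert got == pytest.approx(want) == pytest.approx(0.155)
        # stage III: no first-year correction on the diagnosis part
        got3 = derive_dw(
            INPUTS, "colorectal", "III", treated=True,
            frac_first_year=0.5, frac_stoma=0.05,
        )
        assert got3 == pytest.approx(0.95 * 0.3 + 0.05 * (0.1 + 0.3))

    def test_zero_with_med_rejected(self):
        bad = GbdDwInputs(0.3, 0.45, 0.0, 0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            derive_dw(bad, "breast", "I", treated=False)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        dx=st_.floats(0.05, 0.5),
        with_med=st_.floats(0.3, 0.6),
        ratio=st_.floats(1.0, 1.5),
        ffy=st_.floats(0.1, 1.0),
    )
    def test_treated_never_exceeds_untreated(self, dx, with_med, ratio, ffy):
        inputs = GbdDwInputs(dx, 0.45, with_med, min(1.0, with_med * ratio), 0.05, 0.08)
        for cancer in ("cervical", "breast", "colorectal"):
            for stage in ("CIS", "I", "II", "III", "IV"):
                t = derive_dw(inputs, cancer, stage, True, frac_first_year=ffy)
                u = derive_dw(inputs, cancer, stage, False, frac_first_year=ffy)
                assert t <= u + 1e-12


def _flat_trajectory(person_years_per_year: float, horizon: int) -> Trajectory:
    occ = np.zeros((horizon, 2, N_AGES, 2))
    occ[:, 0, 50, 0] = person_years_per_year
    return Trajectory(
        states=["healthy", "dead"],
        occupancy=occ,
        flows={},
        entrants=np.zeros((horizon, 2)),
        initial_population=occ[0],
    )


class TestHealthyLifeYears:
    def test_zero_dw_equals_person_years(self):
        t = _flat_trajectory(7.0, 10)
        dws = DisabilityWeightSet()
        und, disc = healthy_life_years(t, dws, "breast", discount_rate=0.0)
        assert und == pytest.approx(70.0)
        assert disc == pytest.approx(70.0)  # r = 0: discounted == undiscounted

    def test_full_disability_zero_hly(self):
        t = _flat_trajectory(5.0, 4)
        dws = DisabilityWeightSet()
        dws.set("breast", "healthy", 1.0)
        und, disc = healthy_life_years(t, dws, "breast")
        assert und == 0.0 and disc == 0.0

    def test_discounted_stream_matches_geometric_closed_form(self):
        t = _flat_trajectory(1.0, 100)
        und, disc = healthy_life_years(t, DisabilityWeightSet(), "breast", 0.03)
        v = 1.0 / 1.03
        closed_form = (1.0 - v**100) / (1.0 - v)
        assert und == pytest.approx(100.0, rel=1e-12)
        assert disc == pytest.approx(closed_form, rel=1e-9)

    def test_missing_clinical_dw_raises(self):
        occ = np.zeros((3, 2, N_AGES, 2))
        occ[:, 0, 50, 0] = 1.0
        t = Trajectory(
            states=["clin_I", "dead"],
            occupancy=occ,
            flows={},
            entrants=np.zeros((3, 2)),
            initial_population=occ[0],
        )
        with pytest.raises(KeyError):
            healthy_life_years(t, DisabilityWeightSet(), "breast")

    def test_dw_ordering_propagates_to_sets(self):
        for cancer in ("cervical", "breast", "colorectal"):
            u = build_dw_set(INPUTS, cancer, treated=False)
            tset = build_dw_set(INPUTS, cancer, treated=True)
            for (c, s), w in u.weights.items():
                assert tset.get(c, s) <= w + 1e-12


def _params(**kw):
    defaults = dict(
        unit_costs={
            "screen_via": 3.0,
            "visit": 0.0,
            "false_positive_workup": 50.0,
            "thing": 1.0,
        },
        screening_overhead_fraction=0.0,
        screening_specificity={"via": 0.9},
        discount_rate=0.0,
    )
    defaults.update(kw)
    return CostingParams(**defaults)


class TestScenarioCost:
    def test_empty_plan_costs_nothing(self):
        total, breakdown = scenario_cost([], _params(), {})
        assert total == 0.0 and breakdown == {}

    def test_false_positive_arithmetic(self):
        """100,000 screens at specificity 0.9 and I$50 follow-up cost
        I$500,000 in false-positive work-up before discounting."""
        plan = [
            {
                "component": "screening",
                "kind": "screening",
                "test": "via",
                "events_fn": lambda _: np.array([100_000.0]),
                "ingredients": {},  # isolate the false-positive stream
            }
        ]
        total, breakdown = scenario_cost(plan, _params(), {})
        assert breakdown["screening"][0] == pytest.approx(500_000.0)
        assert total == pytest.approx(0.5)  # million I$

    def test_screening_overhead_is_20_percent_of_programme_total(self):
        plan = [
            {
                "component": "s",
                "kind": "screening",
                "test": "via",
                "events_fn": lambda _: np.array([1000.0]),
                "ingredients": {"screen_via": 1.0},
            }
        ]
        p = _params(screening_overhead_fraction=0.20, screening_specificity={"via": 1.0})
        total, breakdown = scenario_cost(plan, p, {})
        patient_level = 1000.0 * 3.0
        programme_total = breakdown["s"][0]
        overhead = programme_total - patient_level
        assert overhead / programme_total == pytest.approx(0.20)

    def test_constant_stream_discounts_by_geometric_factor(self):
        c = 250.0
        plan = [
            {
                "component": "flat",
                "events_fn": lambda _: np.full(100, c),
                "ingredients": {"thing": 1.0},
            }
        ]
        p = _params(discount_rate=0.03)
        total, _ = scenario_cost(plan, p, {})
        v = 1.0 / 1.03
        assert total * 1e6 == pytest.approx(c * (1 - v**100) / (1 - v), rel=1e-9)

    def test_breakdown_adds_to_total(self):
        plan = [
            {
                "component": f"c{i}",
                "events_fn": lambda _, i=i: np.full(20, 10.0 * (i + 1)),
                "ingredients": {"thing": 1.0},
            }
            for i in range(4)
        ]
        p = _params(discount_rate=0.03)
        total, breakdown = scenario_cost(plan, p, {})
        disc = discount_factors(20, 0.03)
        recomputed = sum(float(s @ disc) for s in breakdown.values()) / 1e6
        assert total == pytest.approx(recomputed, rel=1e-12)

    def test_missing_unit_cost_raises(self):
        plan = [
            {
                "component": "x",
                "events_fn": lambda _: np.ones(3),
                "ingredients": {"unobtainium": 1.0},
            }
        ]
        with pytest.raises(KeyError):
            scenario_cost(plan, _params(), {})


def test_dw_inputs_validation():
    with pytest.raises(ValueError):
        GbdDwInputs(0.3, 0.45, 0.6, 0.5, 0.1, 0.1)  # without < with
    with pytest.raises(ValueError):
        GbdDwInputs(1.3, 0.45, 0.5, 0.6, 0.1, 0.1)
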