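"""Disability weights, healthy-life-year accounting and intervention costing.

Disability weights (DWs) follow the GBD-2010 derivation rules:

* untreated pre-terminal cancer (all cancers): the "cancer: diagnosis and
  primary therapy" DW inflated by the ratio of the terminal-phase DW without
  medication to the terminal-phase DW with medication, capped at 1;
* the terminal phase (clinical stage IV here) uses the GBD terminal estimate
  directly — with medication when palliative care reaches the patient,
  without otherwise;
* treated pre-terminal stages are cancer-specific: cervical stages 0–II get
  a first-year-of-treatment correction (stage III none); breast I–II use a
  weighted average with the mastectomy DW, first-year corrected; colorectal
  mixes in the stoma DW for the ~5% of patients with a stoma, first-year
  correcting the diagnosis component except in stage III.

Healthy life years (HLYs) are person-time summed over all non-dead states
down-weighted by ``1 - DW``, optionally discounted at rate ``r`` with year-t
flows weighted by ``(1 + r)^-t``.  Costing is ingredients-based: events
(doses, screens, treatment courses, palliative episodes) times unit costs,
with a programme-overhead loading on screening such that programme-level
components are ~20% of the screening programme total, plus false-positive
follow-up work-up costs.  Costs are carried in million I$ 2010 per 10
million population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Trajectory

EARLY = ("CIS", "I", "II")  # "stage 0" == CIS


@dataclass
class GbdDwInputs:
    """GBD-2010 disability-weight primitives, all in [0, 1]."""

    dw_diagnosis_primary_therapy: float
    dw_metastatic: float
    dw_terminal_with_med: float
    dw_terminal_without_med: float
    dw_mastectomy: float
    dw_stoma: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dw_terminal_without_med < self.dw_terminal_with_med:
            raise ValueError(
                "terminal DW without medication must be >= DW with medication"
            )


@dataclass
class DisabilityWeightSet:
    """DW per (cancer, state name); scenario machinery blends treated and
    untreated weights by the treated fraction."""

    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, cancer: str, state: str) -> float:
        try:
            return self.weights[(cancer, state)]
        except KeyError:
            raise KeyError(f"no disability weight for ({cancer}, {state})")

    def set(self, cancer: str, state: str, w: float) -> None:
        if not (0.0 <= w <= 1.0):
            raise ValueError("disability weights must lie in [0, 1]")
        self.weights[(cancer, state)] = w

    def copy(self) -> "DisabilityWeightSet":
        return DisabilityWeightSet(dict(self.weights))


def derive_dw(
    inputs: GbdDwInputs,
    cancer: str,
    stage: str,
    treated: bool,
    frac_first_year: float = 0.7,
    frac_stoma: float = 0.05,
    mastectomy_weight: float = 0.5,
) -> float:
    """Disability weight for one clinical cancer stage.

    ``stage`` is one of CIS, I, II, III, IV (IV is the terminal phase).
    ``frac_first_year`` is the fraction of prevalent cases in their first
    year of treatment (the stage DW applies to them only);
    ``mastectomy_weight`` is the weight given to the mastectomy DW in the
    breast early-stage average (equal weighting by default).
    """
    if inputs.dw_terminal_with_med == 0:
        raise ValueError(
            "dw_terminal_with_med must be positive (inflation ratio undefined)"
        )
    if not (0.0 <= frac_first_year <= 1.0 and 0.0 <= frac_stoma <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    dx = inputs.dw_diagnosis_primary_therapy

    if stage == "IV":  # terminal phase: GBD estimate used directly
        return inputs.dw_terminal_with_med if treated else inputs.dw_terminal_without_med

    ratio = inputs.dw_terminal_without_med / inputs.dw_terminal_with_med
    untreated = min(1.0, dx * ratio)
    if not treated:
        return untreated

    # treated weights are capped at the untreated weight: treatment never
    # adds net disability (relevant when the inflation ratio is ~1 and the
    # stoma add-on would otherwise tip the balance)
    if cancer == "cervical":
        w = dx * frac_first_year if stage in EARLY else dx
    elif cancer == "breast":
        if stage in EARLY:
            base = (1 - mastectomy_weight) * dx + mastectomy_weight * inputs.dw_mastectomy
            w = base * frac_first_year
        else:  # stage III: first-year-in-stage correction
            w = dx * frac_first_year
    elif cancer == "colorectal":
        dx_part = dx if stage == "III" else dx * frac_first_year
        w = (1 - frac_stoma) * dx_part + frac_stoma * (inputs.dw_stoma + dx_part)
    else:
        raise ValueError(f"unknown cancer {cancer!r}")
    return min(1.0, w, untreated)


def build_dw_set(
    inputs: GbdDwInputs,
    cancer: str,
    treated: bool,
    frac_first_year: float = 0.7,
    frac_stoma: float = 0.05,
    mastectomy_weight: float = 0.5,
) -> DisabilityWeightSet:
    """Full per-state DW set for one cancer model.

    Healthy, infection, precancer, preclinical (undiagnosed) and immune
    states carry zero disability; clinical stages get the derived weights.
    """
    dws = DisabilityWeightSet()
    for stage in ("CIS", "I", "II", "III", "IV"):
        dws.set(
            cancer,
            f"clin_{stage}",
            derive_dw(
                inputs,
                cancer,
                stage,
                treated,
                frac_first_year=frac_first_year,
                frac_stoma=frac_stoma,
                mastectomy_weight=mastectomy_weight,
            ),
        )
    return dws


def discount_factors(horizon: int, rate: float) -> np.ndarray:
    """(horizon,) year-t discount factors (1 + r)^-t, t = 0 .. horizon-1."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** -np.arange(horizon)


def healthy_life_years(
    traj: Trajectory,
    dws: DisabilityWeightSet,
    cancer: str,
    discount_rate: float = 0.03,
) -> tuple[float, float]:
    """(undiscounted, discounted) HLYs over the trajectory horizon.

    HLY = sum over non-dead states and years of person-time x (1 - DW);
    states absent from ``dws`` carry zero disability except that every
    *clinical* state must have a weight (missing ones raise).
    """
    w = np.zeros(len(traj.states))
    for i, s in enumerate(traj.states):
        if s == traj.dead_state:
            continue
        if (cancer, s) in dws.weights:
            w[i] = dws.get(cancer, s)
        elif s.startswith("clin_"):
            raise KeyError(f"no disability weight for occupied state {s}")
    keep = [i for i, s in enumerate(traj.states) if s != traj.dead_state]
    occ = traj.occupancy[..., keep]  # (H, 2, 101, S')
    healthy_time = occ * (1.0 - w[keep])
    per_year = healthy_time.sum(axis=(1, 2, 3))
    disc = discount_factors(traj.horizon, discount_rate)
    return float(per_year.sum()), float(per_year @ disc)


# ---------------------------------------------------------------------------
# costing
# ---------------------------------------------------------------------------


@dataclass
class CostingParams:
    """Ingredients-based unit costs and programme parameters (I$ 2010).

    ``unit_costs`` maps ingredient names (visit, bed_day, vaccine_dose,
    screen_via, screen_pap, screen_hpv_test, screen_mammography,
    lesion_treatment, treatment_course_<cancer>, palliative_episode,
    false_positive_workup, ...) to I$ per unit.
    """

    unit_costs: dict[str, float]
    screening_overhead_fraction: float = 0.20
    screening_specificity: dict[str, float] = field(default_factory=dict)
    discount_rate: float = 0.03
    currency: str = "I$ 2010"

    def __post_init__(self) -> None:
        for k, v in self.unit_costs.items():
            if v < 0:
                raise ValueError(f"unit cost {k} must be >= 0")
        if not (0.0 <= self.screening_overhead_fraction < 1.0):
            raise ValueError("overhead fraction must be in [0, 1)")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")

    def unit(self, name: str) -> float:
        try:
            return self.unit_costs[name]
        except KeyError:
            raise KeyError(f"no unit cost defined for {name!r}")


def scenario_cost(
    resource_plan: list[dict],
    params: CostingParams,
    traj_by_cancer: dict[str, Trajectory],
) -> tuple[float, dict[str, np.ndarray]]:
    """Total discounted cost (million I$) and per-component yearly streams.

    ``resource_plan`` entries are produced by
    :func:`gcea.interventions.apply_scenario`; each names a component and a
    rule for counting yearly events against the trajectories.  Screening
    components receive the programme-overhead loading (programme-level costs
    ~= ``screening_overhead_fraction`` of the component's total) and a
    false-positive follow-up stream.  All flows are discounted at
    ``params.discount_rate`` from programme start.
    """
    breakdown: dict[str, np.ndarray] = {}
    for item in resource_plan:
        events = item["events_fn"](traj_by_cancer)  # (horizon,) events / year
        stream = np.zeros_like(events, dtype=float)
        for ingredient, per_event in item["ingredients"].items():
            stream = stream + events * per_event * params.unit(ingredient)
        if item.get("kind") == "screening":
            spec = params.screening_specificity.get(item["test"], 1.0)
            fp = events * (1.0 - spec) * params.unit("false_positive_workup")
            stream = stream + fp
            f = params.screening_overhead_fraction
            stream = stream / (1.0 - f)  # overhead = f of programme total
        breakdown[item["component"]] = stream
    horizon = max((len(s) for s in breakdown.values()), default=0)
    disc = discount_factors(horizon, params.discount_rate) if horizon else np.array([])
    total = sum(float(s @ disc[: len(s)]) for s in breakdown.values())
    return total / 1e6, breakdown
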