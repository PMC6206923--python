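"""Synthetic region parameter sets.

The regional inputs of the real analysis (GLOBOCAN-style incidence targets,
GBD-2010 disability weights, ingredients-based unit costs, transmission and
natural-history rates) are emulated here so the whole pipeline runs with no
external data.  Natural progression/regression rates are cancer-specific
constants that do not vary by region; population-specific onset intensities
are calibrated against each profile's age-specific clinical-incidence
targets through :func:`gcea.engine.calibrate_onset_rates`.  All random draws
(disability-weight sampling) happen here, seeded per profile; the simulation
itself is fully deterministic.

Every value produced by this module is synthetic: plausible in magnitude,
internally consistent, but not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import states as st
from .engine import (
    FEMALE,
    MALE,
    N_AGES,
    Demography,
    RateSchedule,
    calibrate_onset_rates,
    expand_age_bands,
)
from .interventions import EffectParams
from .outcomes import CostingParams, DisabilityWeightSet, GbdDwInputs, build_dw_set
from .transmission import SUBTYPE_GROUPS, TransmissionParams

STAGES = st.STAGES


@dataclass
class RegionProfile:
    """Target epidemiology and price level of one synthetic region."""

    name: str
    # clinical diagnoses per 100,000 alive (females for cervical/breast,
    # both sexes for colorectal), by age band
    cervical_incidence: dict[tuple[int, int], float]
    breast_incidence: dict[tuple[int, int], float]
    colorectal_incidence: dict[tuple[int, int], float]
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: {"CIS": 0.05, "I": 0.15, "II": 0.25, "III": 0.30, "IV": 0.25}
    )
    hpv_attribution: tuple[float, float, float] = (0.70, 0.28, 0.02)
    cost_level: float = 1.0
    route_split: tuple[float, float] = (0.77, 0.23)
    population: float = 10_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for tgt in (
            self.cervical_incidence,
            self.breast_incidence,
            self.colorectal_incidence,
        ):
            if any(v < 0 for v in tgt.values()):
                raise ValueError("incidence targets must be non-negative")
        if abs(sum(self.stage_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("stage distribution must sum to 1")
        if sum(self.hpv_attribution) > 1.0 + 1e-9:
            raise ValueError("HPV attribution fractions must sum to <= 1")


@dataclass
class RegionBundle:
    """Everything the pipeline needs to evaluate one region."""

    name: str
    profile: RegionProfile
    graphs: dict[str, st.StateGraph]
    rates: dict[str, RateSchedule]
    demography: Demography
    transmission: TransmissionParams
    dw_inputs: GbdDwInputs
    dws: dict[str, dict[str, DisabilityWeightSet]]
    costing: CostingParams
    effect_params: EffectParams


# ---------------------------------------------------------------------------
# natural-history rate constants (per person-year, region-invariant)
# ---------------------------------------------------------------------------

# diagnosis intensities by stage (symptom-driven; screening adds to these)
_DIAGNOSIS = {
    "cervical": {"CIS": 0.02, "I": 0.08, "II": 0.25, "III": 0.60, "IV": 1.20},
    "breast": {"CIS": 0.03, "I": 0.12, "II": 0.30, "III": 0.70, "IV": 1.20},
    "colorectal": {"CIS": 0.02, "I": 0.08, "II": 0.25, "III": 0.60, "IV": 1.10},
}
# stage-to-next-stage progression intensities (preclinical and clinical)
_PROGRESSION = {
    "cervical": {"CIS": 0.35, "I": 0.30, "II": 0.30, "III": 0.35},
    "breast": {"CIS": 0.40, "I": 0.35, "II": 0.30, "III": 0.30},
    "colorectal": {"CIS": 0.35, "I": 0.30, "II": 0.30, "III": 0.30},
}
# untreated excess (cancer) mortality by stage
_FATALITY = {
    "cervical": {"CIS": 0.0, "I": 0.05, "II": 0.12, "III": 0.30, "IV": 0.80},
    "breast": {"CIS": 0.0, "I": 0.04, "II": 0.10, "III": 0.25, "IV": 0.60},
    "colorectal": {"CIS": 0.0, "I": 0.04, "II": 0.10, "III": 0.25, "IV": 0.60},
}

# equal transmissibility and clearance across subtype groups: the groups
# compete for the same susceptible pool, so equal R0 keeps all three endemic;
# oncogenicity differences live entirely in the progression rates
_CLEARANCE = {"HPV_16_18": 0.40, "HPV_high_risk": 0.40, "HPV_low_risk": 0.40}
_BETA = {"HPV_16_18": 0.8, "HPV_high_risk": 0.8, "HPV_low_risk": 0.8}
# assumed prevalence shares of the three groups among infections, used to
# translate cancer-attribution fractions into relative progression rates
_PREV_SHARE = (0.40, 0.40, 0.20)

CERVICAL_ONSET_EDGES = [(g.lower(), "cin1") for g in SUBTYPE_GROUPS]


def _stage_block_rates(r: RateSchedule, cancer: str, sexes) -> None:
    for phase in ("pre", "clin"):
        for s, nxt in zip(STAGES[:-1], STAGES[1:]):
            arr = np.zeros((2, N_AGES))
            for sex in sexes:
                arr[sex, :] = _PROGRESSION[cancer][s]
            r.set((f"{phase}_{s}", f"{phase}_{nxt}"), arr)
    for s in STAGES:
        diag = np.zeros((2, N_AGES))
        fat = np.zeros((2, N_AGES))
        for sex in sexes:
            diag[sex, :] = _DIAGNOSIS[cancer][s]
            fat[sex, :] = _FATALITY[cancer][s]
        r.set((f"pre_{s}", f"clin_{s}"), diag)
        r.set((f"pre_{s}", "dead"), fat)
        r.set((f"clin_{s}", "dead"), fat.copy())


def base_cervical_rates(profile: RegionProfile) -> RateSchedule:
    r = RateSchedule()
    att = profile.hpv_attribution
    for i, g in enumerate(SUBTYPE_GROUPS):
        gl = g.lower()
        r.set(("healthy", gl), 0.0)  # owned by the transmission model
        clear = np.zeros((2, N_AGES))
        clear[:, :] = _CLEARANCE[g]
        r.set((gl, "immune"), clear)
        # oncogenic progression, females only; scaled in calibration
        prog = np.zeros((2, N_AGES))
        prog[FEMALE, 15:] = 0.05 * att[i] / _PREV_SHARE[i]
        r.set((gl, "cin1"), prog)
    r.set(("immune", "healthy"), 1.0)
    cin = {
        ("cin1", "cin2_3"): 0.10,
        ("cin2_3", "pre_CIS"): 0.05,
        ("cin2_3", "cin1"): 0.12,
        ("cin1", "hpv_16_18"): 0.35 * 0.7,
        ("cin1", "hpv_high_risk"): 0.35 * 0.3,
    }
    for edge, v in cin.items():
        arr = np.zeros((2, N_AGES))
        arr[FEMALE, :] = v
        r.set(edge, arr)
    _stage_block_rates(r, "cervical", sexes=(FEMALE,))
    for name in ("healthy", "immune", "cin1", "cin2_3"):
        r.set((name, "dead"), 0.0)
    for g in SUBTYPE_GROUPS:
        r.set((g.lower(), "dead"), 0.0)
    return r


def base_breast_rates() -> RateSchedule:
    r = RateSchedule()
    onset = np.zeros((2, N_AGES))
    onset[FEMALE, 25:] = 3e-4  # calibration rescales per band
    r.set(("healthy", "pre_CIS"), onset)
    _stage_block_rates(r, "breast", sexes=(FEMALE,))
    r.set(("healthy", "dead"), 0.0)
    return r


def base_colorectal_rates(profile: RegionProfile) -> RateSchedule:
    r = RateSchedule()
    adenoma, de_novo = profile.route_split
    k = 4e-4
    onset_a = np.zeros((2, N_AGES))
    onset_d = np.zeros((2, N_AGES))
    onset_a[:, 40:] = k * adenoma
    onset_d[:, 40:] = k * de_novo
    r.set(("healthy", "polyp_small"), onset_a)
    r.set(("healthy", "pre_CIS"), onset_d)
    r.set(("polyp_small", "polyp_medium"), 0.15)
    r.set(("polyp_medium", "polyp_large"), 0.20)
    r.set(("polyp_large", "pre_CIS"), 0.06)
    r.set(("polyp_small", "healthy"), 0.12)
    r.set(("polyp_medium", "healthy"), 0.03)
    _stage_block_rates(r, "colorectal", sexes=(0, 1))
    for name in ("healthy", "polyp_small", "polyp_medium", "polyp_large"):
        r.set((name, "dead"), 0.0)
    return r


def default_transmission() -> TransmissionParams:
    activity = expand_age_bands(
        {
            (15, 19): 1.0,
            (20, 24): 1.4,
            (25, 29): 1.0,
            (30, 39): 0.6,
            (40, 49): 0.35,
            (50, 64): 0.15,
        }
    )
    pcr = np.vstack([activity, activity])
    return TransmissionParams.proportionate(
        beta=dict(_BETA),
        partner_change_rate=pcr,
        clearance_rate=dict(_CLEARANCE),
        immunity_waning_rate=1.0,
        seed_prevalence=0.02,
    )


def sample_dw_inputs(rng: np.random.Generator) -> GbdDwInputs:
    """Synthetic GBD-2010-plausible disability-weight primitives."""
    with_med = rng.uniform(0.45, 0.52)
    return GbdDwInputs(
        dw_diagnosis_primary_therapy=rng.uniform(0.24, 0.32),
        dw_metastatic=rng.uniform(0.40, 0.50),
        dw_terminal_with_med=with_med,
        dw_terminal_without_med=min(1.0, with_med * rng.uniform(1.05, 1.20)),
        dw_mastectomy=rng.uniform(0.03, 0.06),
        dw_stoma=rng.uniform(0.07, 0.10),
    )


_BASE_UNIT_COSTS = {
    "visit": 8.0,
    "bed_day": 25.0,
    "vaccine_dose": 18.0,
    "screen_via": 4.0,
    "screen_pap": 12.0,
    "screen_hpv_test": 28.0,
    "screen_mammography": 35.0,
    "lesion_treatment": 60.0,
    "treatment_course_cervical": 1600.0,
    "treatment_course_breast": 2400.0,
    "treatment_course_colorectal": 2600.0,
    "palliative_episode": 350.0,
    "false_positive_workup": 60.0,
}

_SPECIFICITY = {"via": 0.85, "pap": 0.95, "hpv_test": 0.90, "mammography": 0.92}


def default_costing(cost_level: float = 1.0, discount_rate: float = 0.03) -> CostingParams:
    return CostingParams(
        unit_costs={k: v * cost_level for k, v in _BASE_UNIT_COSTS.items()},
        screening_overhead_fraction=0.20,
        screening_specificity=dict(_SPECIFICITY),
        discount_rate=discount_rate,
    )


def generate_region_params(
    profile: RegionProfile, calibration_horizon: int = 90
) -> RegionBundle:
    """Complete, internally consistent parameter bundle for a region.

    Deterministic given ``profile.seed``.  Onset intensities are
    pre-calibrated so that simulating the bundle reproduces the profile's
    clinical-incidence targets (relative tolerance 1%); calibration failures
    propagate as :class:`gcea.engine.CalibrationError`.
    """
    rng = np.random.default_rng(profile.seed)
    demography = Demography.standard(profile.population)
    graphs = {
        "cervical": st.build_cervical_graph(),
        "breast": st.build_breast_graph(),
        "colorectal": st.build_colorectal_graph(profile.route_split),
    }
    tx = default_transmission()
    rates = {
        "cervical": base_cervical_rates(profile),
        "breast": base_breast_rates(),
        "colorectal": base_colorectal_rates(profile),
    }
    rates["breast"] = calibrate_onset_rates(
        graphs["breast"],
        rates["breast"],
        demography,
        profile.breast_incidence,
        sex=FEMALE,
        horizon=calibration_horizon,
    )
    rates["colorectal"] = calibrate_onset_rates(
        graphs["colorectal"],
        rates["colorectal"],
        demography,
        profile.colorectal_incidence,
        horizon=calibration_horizon,
    )
    rates["cervical"] = calibrate_onset_rates(
        graphs["cervical"],
        rates["cervical"],
        demography,
        profile.cervical_incidence,
        onset_edges=CERVICAL_ONSET_EDGES,
        sex=FEMALE,
        horizon=calibration_horizon,
        transmission=tx,
    )
    dw_inputs = sample_dw_inputs(rng)
    dws = {
        c: {
            "untreated": build_dw_set(dw_inputs, c, treated=False),
            "treated": build_dw_set(dw_inputs, c, treated=True),
        }
        for c in st.CANCERS
    }
    return RegionBundle(
        name=profile.name,
        profile=profile,
        graphs=graphs,
        rates=rates,
        demography=demography,
        transmission=tx,
        dw_inputs=dw_inputs,
        dws=dws,
        costing=default_costing(profile.cost_level),
        effect_params=EffectParams(),
    )


def make_two_region_demo() -> tuple[RegionProfile, RegionProfile]:
    """Two contrasting synthetic regions for the end-to-end demo.

    The "SEA-like" region has the lower cervical incidence and the higher
    price level; the "ESSA-like" region the higher cervical burden — so
    cervical prevention should come out more cost effective there.
    """
    sea = RegionProfile(
        name="SEA-like",
        cervical_incidence={(15, 100): 16.0},
        breast_incidence={(30, 49): 20.0, (50, 69): 45.0, (70, 100): 55.0},
        colorectal_incidence={(40, 59): 8.0, (60, 100): 22.0},
        cost_level=1.0,
        seed=11,
    )
    essa = RegionProfile(
        name="ESSA-like",
        cervical_incidence={(15, 100): 35.0},
        breast_incidence={(30, 49): 15.0, (50, 69): 30.0, (70, 100): 40.0},
        colorectal_incidence={(40, 59): 4.0, (60, 100): 12.0},
        cost_level=0.8,
        seed=12,
    )
    return sea, essa


def fixture_tables() -> dict[str, pd.DataFrame]:
    """Machine-readable copies of the published regional league and budget
    tables.  Used by arithmetic-consistency tests; values are exactly as
    printed (costs in million I$ 2010 in the league tables, plain I$ in the
    budget table)."""
    out = {}
    pkg = resources.files("gcea.data")
    for key, fname in (
        ("league_sea", "league_sea.csv"),
        ("league_essa", "league_essa.csv"),
        ("budget", "budget.csv"),
    ):
        with resources.as_file(pkg / fname) as path:
            out[key] = pd.read_csv(path)
    return out
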