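"""The 14-intervention catalog and scenario machinery.

Interventions (9 cervical, 3 breast, 2 colorectal) act on the natural
history through four mechanisms:

* **vaccination** — a susceptibility multiplier ``1 - coverage x efficacy``
  on the healthy→HPV-16/18 hazard of girl cohorts vaccinated at age 12 after
  programme start (take-type effect; no cross-protection against the other
  subtype groups; boys are not vaccinated);
* **screening** — an additive screen-detection hazard
  ``coverage / interval x sensitivity`` on the preclinical→clinical
  diagnosis edges of the eligible band, and (cervical) an additive
  screen-and-treat regression hazard returning CIN to the HPV state;
* **treatment** (stages I–II) — an excess-mortality multiplier < 1 on the
  treated fraction of clinical stages I and II, plus the treated disability
  weight for that fraction;
* **palliative care** — the terminal-phase disability weight switches from
  "without medication" to "with medication" for the covered fraction.

Coverage scales linearly: the covered fraction experiences the full
per-protocol effect, so the modified rate at coverage ``c`` is the
``c``-weighted mixture of the coverage-0 and coverage-1 rates.  Everything
at coverage 0 is the null: pure natural history, untreated disability
weights, no resource use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import N_AGES, FEMALE, RateSchedule
from .outcomes import DisabilityWeightSet

COVERAGE_LEVELS = (0.5, 0.8, 0.95)

CANCER_OF_PREFIX = {"C1": "cervical", "C2": "breast", "C3": "colorectal"}


@dataclass(frozen=True)
class Eligibility:
    """Who an effect applies to: sexes, age range, and states (None = any)."""

    sexes: tuple[int, ...]
    age_lo: int
    age_hi: int
    states: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sexes or not (0 <= self.age_lo <= self.age_hi <= 100):
            raise ValueError("eligibility must cover a non-empty population")


@dataclass(frozen=True)
class EffectSpec:
    """One mechanism of action on rates or disability weights."""

    target: str
    mechanism: str  # rate_multiplier | rate_multiplier_inverse | dw_substitute | fatality_multiplier
    efficacy: float
    eligible: Eligibility

    def __post_init__(self) -> None:
        if self.mechanism in ("rate_multiplier", "rate_multiplier_inverse"):
            if not (0.0 <= self.efficacy <= 1.0):
                raise ValueError("efficacy must be a fraction in [0, 1]")
        elif self.efficacy < 0:
            raise ValueError("multiplier must be positive")


@dataclass(frozen=True)
class Intervention:
    label: str
    cancer: str
    description: str
    effects: tuple[EffectSpec, ...]
    resource_profile: str
    family: str  # prevention | treatment | palliative
    components: tuple[str, ...] = ()  # combination labels expand to these
    screen_test: str | None = None
    screen_interval: float | None = None


@dataclass
class EffectParams:
    """Effect sizes and schedules (synthetic defaults; regions may override).

    Screening frequencies become annual screen probabilities
    ``coverage / interval``; intervals are explicit config so e.g. the
    "every 3–5 years" Pap-smear schedule resolves to a visible default.
    """

    vaccine_efficacy_16_18: float = 0.95
    vaccination_age: int = 12
    # sensitivity to (precancer, preclinical cancer) per test
    sens_precancer: dict[str, float] = field(
        default_factory=lambda: {"via": 0.55, "pap": 0.65, "hpv_test": 0.85}
    )
    sens_cancer: dict[str, float] = field(
        default_factory=lambda: {
            "via": 0.50,
            "pap": 0.60,
            "hpv_test": 0.70,
            "mammography": 0.75,
        }
    )
    lesion_treatment_effectiveness: float = 0.9
    screen_intervals: dict[str, float] = field(
        default_factory=lambda: {
            "via": 10.0,  # once per decade, ages 30-49
            "pap": 4.0,  # "every 3-5 years"
            "hpv_test": 5.0,
            "mammography": 2.0,
        }
    )
    # treated-to-untreated excess-mortality multiplier, clinical stages I-II
    treatment_fatality_multiplier: dict[str, float] = field(
        default_factory=lambda: {"cervical": 0.25, "breast": 0.25, "colorectal": 0.30}
    )
    # share of screen-treated CIN regressing to HPV 16/18 vs other high-risk
    cin_regression_attribution: tuple[float, float] = (0.7, 0.3)


_DESCRIPTIONS = {
    "C1a": "Vaccination against human papillomavirus (two doses) of 9-13-year-old girls",
    "C1b": "Prevention of cervical cancer by screening women aged 30-49 through visual inspection with acetic acid linked with timely treatment of pre-cancerous lesions",
    "C1c": "Prevention of cervical cancer by screening women aged 30-49 through Pap smear (cervical cytology) every 3-5 years linked with timely treatment of pre-cancerous lesions",
    "C1d": "Prevention of cervical cancer by screening women aged 30-49 through human papillomavirus test every 5 years linked with timely treatment of pre-cancerous lesions",
    "C1e": "Vaccination against human papillomavirus (two doses) of 9-13-year-old girls and prevention of cervical cancer by screening women aged 30-49 through visual inspection with acetic acid linked with timely treatment of pre-cancerous lesions",
    "C1f": "Vaccination against human papillomavirus (two doses) of 9-13-year-old girls and prevention of cervical cancer by screening women aged 30-49 through Pap smear (cervical cytology) every 3-5 years linked with timely treatment of pre-cancerous lesions",
    "C1g": "Vaccination against human papillomavirus (two doses) of 9-13-year-old girls and Prevention of cervical cancer by screening women aged 30-49 through human papillomavirus test every 5 years linked with timely treatment of pre-cancerous lesions",
    "C1h": "Treatment of cervical cancer stages I and II with either surgery or radiotherapy +/- chemotherapy",
    "C1i": "Basic palliative care for cancer: home-based and hospital care with multi-disciplinary team and access to opiates and essential supportive medicines",
    "C2a": "Treatment of breast cancer stages I and II with surgery +/- systemic therapy",
    "C2b": "Screening with mammography (once every 2 years for women aged 50-69 years) linked with timely diagnosis and treatment of breast cancer",
    "C2c": "Basic palliative care for cancer: home-based and hospital care with multi-disciplinary team and access to opiates and essential supportive medicines",
    "C3a": "Treatment of colorectal cancer stages I and II with surgery +/- chemotherapy and radiotherapy",
    "C3b": "Basic palliative care for cancer: home-based and hospital care with multi-disciplinary team and access to opiates and essential supportive medicines",
}


def _vaccination(label: str, p: EffectParams) -> Intervention:
    return Intervention(
        label=label,
        cancer="cervical",
        description=_DESCRIPTIONS[label],
        effects=(
            EffectSpec(
                target="healthy->hpv_16_18",
                mechanism="rate_multiplier",
                efficacy=p.vaccine_efficacy_16_18,
                eligible=Eligibility((FEMALE,), 9, 13),
            ),
        ),
        resource_profile="hpv_vaccination",
        family="prevention",
    )


def _cervical_screening(label: str, test: str, p: EffectParams) -> Intervention:
    elig = Eligibility((FEMALE,), 30, 49)
    return Intervention(
        label=label,
        cancer="cervical",
        description=_DESCRIPTIONS[label],
        effects=(
            EffectSpec("diagnosis", "rate_multiplier_inverse", p.sens_cancer[test], elig),
            EffectSpec(
                "precancer_regression",
                "rate_multiplier_inverse",
                p.sens_precancer[test] * p.lesion_treatment_effectiveness,
                elig,
            ),
        ),
        resource_profile=f"screening_{test}",
        family="prevention",
        screen_test=test,
        screen_interval=p.screen_intervals[test],
    )


def _treatment(label: str, cancer: str, p: EffectParams) -> Intervention:
    sexes = (0, 1) if cancer == "colorectal" else (FEMALE,)
    elig = Eligibility(sexes, 0, 100, ("clin_I", "clin_II"))
    return Intervention(
        label=label,
        cancer=cancer,
        description=_DESCRIPTIONS[label],
        effects=(
            EffectSpec(
                "clinical_early_mortality",
                "fatality_multiplier",
                p.treatment_fatality_multiplier[cancer],
                elig,
            ),
            EffectSpec("clinical_early_dw", "dw_substitute", 1.0, elig),
        ),
        resource_profile=f"treatment_{cancer}",
        family="treatment",
    )


def _palliative(label: str, cancer: str) -> Intervention:
    sexes = (0, 1) if cancer == "colorectal" else (FEMALE,)
    elig = Eligibility(sexes, 0, 100, ("clin_IV",))
    return Intervention(
        label=label,
        cancer=cancer,
        description=_DESCRIPTIONS[label],
        effects=(EffectSpec("terminal_dw", "dw_substitute", 1.0, elig),),
        resource_profile="palliative_care",
        family="palliative",
    )


def build_catalog(params: EffectParams | None = None) -> list[Intervention]:
    """All 14 interventions, partitioned 9/3/2 across the cancers."""
    p = params or EffectParams()
    cat = [
        _vaccination("C1a", p),
        _cervical_screening("C1b", "via", p),
        _cervical_screening("C1c", "pap", p),
        _cervical_screening("C1d", "hpv_test", p),
    ]
    for combo, screen in (("C1e", "C1b"), ("C1f", "C1c"), ("C1g", "C1d")):
        base = next(i for i in cat if i.label == screen)
        cat.append(
            replace(
                _vaccination(combo, p),
                description=_DESCRIPTIONS[combo],
                effects=cat[0].effects + base.effects,
                components=("C1a", screen),
                resource_profile="combination",
                screen_test=base.screen_test,
                screen_interval=base.screen_interval,
            )
        )
    cat += [
        _treatment("C1h", "cervical", p),
        _palliative("C1i", "cervical"),
        _treatment("C2a", "breast", p),
        Intervention(
            label="C2b",
            cancer="breast",
            description=_DESCRIPTIONS["C2b"],
            effects=(
                EffectSpec(
                    "diagnosis",
                    "rate_multiplier_inverse",
                    p.sens_cancer["mammography"],
                    Eligibility((FEMALE,), 50, 69),
                ),
            )
            + _treatment("C2a", p=p, cancer="breast").effects,
            resource_profile="screening_mammography",
            family="screening",
            screen_test="mammography",
            screen_interval=p.screen_intervals["mammography"],
        ),
        _palliative("C2c", "breast"),
        _treatment("C3a", "colorectal", p),
        _palliative("C3b", "colorectal"),
    ]
    return cat


@dataclass(frozen=True)
class Scenario:
    """A set of (intervention label, coverage); empty mapping is the null."""

    coverages: tuple[tuple[str, float], ...] = ()
    region: str = ""

    @classmethod
    def of(cls, region: str = "", **labels: float) -> "Scenario":
        return cls(tuple(sorted(labels.items())), region)

    @property
    def as_dict(self) -> dict[str, float]:
        return dict(self.coverages)

    def expanded(self, catalog: list[Intervention]) -> dict[str, float]:
        """Coverage per *atomic* label (combination labels expand)."""
        by_label = {i.label: i for i in catalog}
        out: dict[str, float] = {}
        for label, cov in self.coverages:
            iv = by_label[label]
            targets = iv.components or (label,)
            for t in targets:
                out[t] = max(out.get(t, 0.0), cov)
        return out


def null_scenario(region: str = "") -> Scenario:
    """The counterfactual: all current interventions removed."""
    return Scenario((), region)


class UnknownInterventionError(KeyError):
    pass


def _check_coverages(scenario: Scenario, catalog, allow_any: bool) -> None:
    labels = {i.label for i in catalog}
    seen = set()
    for label, cov in scenario.coverages:
        if label not in labels:
            raise UnknownInterventionError(label)
        if label in seen:
            raise ValueError(f"duplicate coverage for {label}")
        seen.add(label)
        if not allow_any and cov not in (0.0,) + COVERAGE_LEVELS:
            raise ValueError(
                f"coverage {cov} for {label} not in {{0, 0.5, 0.8, 0.95}}"
            )


# ---------------------------------------------------------------------------
# scenario application
# ---------------------------------------------------------------------------


def _eligible_mask(elig: Eligibility) -> np.ndarray:
    m = np.zeros((2, N_AGES))
    for sex in elig.sexes:
        m[sex, elig.age_lo : elig.age_hi + 1] = 1.0
    return m


def _vaccination_multiplier(
    coverage: float, efficacy: float, vac_age: int, horizon: int
) -> np.ndarray:
    """(horizon, 2, 101) multiplier on the healthy->HPV-16/18 hazard.

    A cohort is protected once it has passed the vaccination age in a
    programme year: at year t, ages ``vac_age <= a <= vac_age + t`` belong to
    cohorts vaccinated since the programme started.
    """
    mult = np.ones((horizon, 2, N_AGES))
    red = 1.0 - coverage * efficacy
    for t in range(horizon):
        hi = min(vac_age + t, N_AGES - 1)
        mult[t, FEMALE, vac_age : hi + 1] = red
    return mult


def apply_scenario(
    rates: dict[str, RateSchedule],
    dws: dict[str, dict[str, DisabilityWeightSet]],
    scenario: Scenario,
    catalog: list[Intervention] | None = None,
    params: EffectParams | None = None,
    horizon: int = 100,
    allow_any_coverage: bool = False,
) -> tuple[dict[str, RateSchedule], dict[str, DisabilityWeightSet], list[dict]]:
    """Translate a scenario into modified rates, DWs and a resource plan.

    ``dws[cancer]`` holds the ``{"untreated": ..., "treated": ...}`` pair;
    the returned DW set per cancer blends them by the treated fraction.
    The resource plan lists one entry per (intervention, component) with an
    ``events_fn`` that counts yearly events against simulated trajectories
    (consumed by :func:`gcea.outcomes.scenario_cost`).
    """
    catalog = catalog if catalog is not None else build_catalog(params)
    p = params or EffectParams()
    _check_coverages(scenario, catalog, allow_any_coverage)
    by_label = {i.label: i for i in catalog}

    out_rates = {c: r.copy() for c, r in rates.items()}
    out_dws = {c: pair["untreated"].copy() for c, pair in dws.items()}
    plan: list[dict] = []

    atomic = scenario.expanded(catalog)
    for label, cov in sorted(atomic.items()):
        if cov == 0.0:
            continue
        iv = by_label[label]
        cancer = iv.cancer
        r = out_rates[cancer]

        for eff in iv.effects:
            mask = _eligible_mask(eff.eligible)
            if eff.mechanism == "rate_multiplier" and eff.target == "healthy->hpv_16_18":
                mult = _vaccination_multiplier(
                    cov, eff.efficacy, p.vaccination_age, horizon
                )
                r.add_multiplier(("healthy", "hpv_16_18"), mult)
            elif eff.mechanism == "rate_multiplier_inverse" and eff.target == "diagnosis":
                screen_rate = cov / iv.screen_interval
                add = screen_rate * eff.efficacy * mask
                for u, v in _diagnosis_edges():
                    if (u, v) in r.rates:
                        r.rates[(u, v)] += add
            elif (
                eff.mechanism == "rate_multiplier_inverse"
                and eff.target == "precancer_regression"
            ):
                screen_rate = cov / iv.screen_interval
                add = screen_rate * eff.efficacy * mask
                w1618, whr = p.cin_regression_attribution
                r.rates[("cin1", "hpv_16_18")] += add * w1618
                r.rates[("cin1", "hpv_high_risk")] += add * whr
                r.rates[("cin2_3", "cin1")] += add
            elif eff.mechanism == "fatality_multiplier":
                # treated fraction cov sees multiplier m: linear mixture
                m_eff = 1.0 - cov * (1.0 - eff.efficacy)
                for state in eff.eligible.states or ():
                    edge = (state, "dead")
                    if edge in r.rates:
                        for sex in eff.eligible.sexes:
                            r.rates[edge][sex] *= m_eff
            elif eff.mechanism == "dw_substitute":
                for state in eff.eligible.states or ():
                    w_un = dws[cancer]["untreated"].get(cancer, state)
                    w_tr = dws[cancer]["treated"].get(cancer, state)
                    out_dws[cancer].set(
                        cancer, state, (1.0 - cov) * w_un + cov * w_tr
                    )

        plan.extend(_resource_entries(iv, cov, p))
    return out_rates, out_dws, plan


def _diagnosis_edges() -> list[tuple[str, str]]:
    return [(f"pre_{s}", f"clin_{s}") for s in ("CIS", "I", "II", "III", "IV")]


# -- resource counting ------------------------------------------------------


def _alive_nonclinical(traj, sexes, lo, hi) -> np.ndarray:
    idx = [
        i
        for i, s in enumerate(traj.states)
        if s != traj.dead_state and not s.startswith("clin_")
    ]
    occ = traj.occupancy[:, list(sexes), lo : hi + 1][..., idx]
    return occ.sum(axis=(1, 2, 3))


def _flows_into(traj, targets) -> np.ndarray:
    out = np.zeros(traj.horizon)
    for (u, v), f in traj.flows.items():
        if v in targets and u != v:
            out += f.sum(axis=(1, 2))
    return out


def _resource_entries(iv: Intervention, cov: float, p: EffectParams) -> list[dict]:
    cancer = iv.cancer
    entries: list[dict] = []
    if iv.resource_profile == "hpv_vaccination":

        def doses(trajs, cov=cov, age=p.vaccination_age):
            t = trajs[cancer]
            girls = t.alive()[:, FEMALE, age]
            return 2.0 * cov * girls

        entries.append(
            {
                "component": f"{iv.label}_vaccination",
                "kind": "vaccination",
                "events_fn": doses,
                "ingredients": {"vaccine_dose": 1.0, "visit": 1.0},
            }
        )
    elif iv.resource_profile.startswith("screening_"):
        test = iv.screen_test
        interval = iv.screen_interval
        elig = next(e.eligible for e in iv.effects if e.target == "diagnosis")

        def screens(trajs, cov=cov, interval=interval, elig=elig):
            t = trajs[cancer]
            pop = _alive_nonclinical(t, elig.sexes, elig.age_lo, elig.age_hi)
            return cov / interval * pop

        entries.append(
            {
                "component": f"{iv.label}_screening",
                "kind": "screening",
                "test": test,
                "events_fn": screens,
                "ingredients": {f"screen_{test}": 1.0, "visit": 1.0},
            }
        )
        if cancer == "cervical":
            sens_treat = p.sens_precancer[test] * p.lesion_treatment_effectiveness

            def lesions(trajs, cov=cov, interval=interval, s=sens_treat, elig=elig):
                t = trajs[cancer]
                idx = [t.state_index("cin1"), t.state_index("cin2_3")]
                cin = t.occupancy[:, FEMALE, elig.age_lo : elig.age_hi + 1][
                    ..., idx
                ].sum(axis=(1, 2))
                return cov / interval * s * cin

            entries.append(
                {
                    "component": f"{iv.label}_lesion_treatment",
                    "kind": "lesion_treatment",
                    "events_fn": lesions,
                    "ingredients": {"lesion_treatment": 1.0, "visit": 1.0},
                }
            )
        if cancer == "breast":  # mammography is linked to treatment
            entries.append(_treatment_entry(iv, cov, suffix="_linked_treatment"))
    elif iv.resource_profile.startswith("treatment_"):
        entries.append(_treatment_entry(iv, cov))
    elif iv.resource_profile == "palliative_care":

        def episodes(trajs, cov=cov):
            return cov * _flows_into(trajs[cancer], {"clin_IV"})

        entries.append(
            {
                "component": f"{iv.label}_palliative",
                "kind": "palliative",
                "events_fn": episodes,
                "ingredients": {"palliative_episode": 1.0},
            }
        )
    return entries


def _treatment_entry(iv: Intervention, cov: float, suffix: str = "_treatment") -> dict:
    cancer = iv.cancer

    def courses(trajs, cov=cov):
        t = trajs[cancer]
        out = np.zeros(t.horizon)
        for stage in ("I", "II"):
            e = (f"pre_{stage}", f"clin_{stage}")
            if e in t.flows:
                out += t.flows[e].sum(axis=(1, 2))
        return cov * out

    return {
        "component": f"{iv.label}{suffix}",
        "kind": "treatment",
        "events_fn": courses,
        "ingredients": {f"treatment_course_{cancer}": 1.0, "visit": 4.0, "bed_day": 10.0},
    }
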