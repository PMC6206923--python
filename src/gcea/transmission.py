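"""Two-sex, age-structured HPV transmission dynamics.

A frequency-dependent SIS-with-immunity formulation couples female and male
HPV prevalence: the per-year hazard of acquiring subtype group ``g`` for a
person of sex ``x`` and age ``a`` is

    lambda_g(x, a) = c(x, a) * sum_a' M(a, a') * beta_g * prev(other(x), a', g)

where ``c`` is the mean rate of new partnerships, ``M`` a row-normalized
age-mixing kernel (proportionate by default) and ``beta_g`` the per-partnership
annual transmission probability.  Infection clears into a short-term immune
state that wanes back to susceptible.  Three subtype groups are tracked
(16/18, other high-risk, low-risk); co-infection is not modelled.

Vaccination acts as a susceptibility multiplier on the 16/18 hazard of
vaccinated cohorts (applied by the scenario machinery through rate
multipliers, see :mod:`gcea.interventions`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import N_AGES

SUBTYPE_GROUPS = ("HPV_16_18", "HPV_high_risk", "HPV_low_risk")


@dataclass
class TransmissionParams:
    """Parameters of the heterosexual HPV transmission sub-model.

    Attributes
    ----------
    beta : dict group -> per-partnership transmission probability per year.
    partner_change_rate : (2, 101) mean new partners per year by sex and age.
    mixing : (101, 101) row-normalized age-mixing kernel (rows: own age,
        columns: partner age).  Rows whose ages have zero contact may be all
        zero.
    clearance_rate : dict group -> per-year natural clearance intensity.
    immunity_waning_rate : per-year immune -> healthy intensity
        (mean immune duration = 1 / rate; default one year).
    seed_prevalence : initial infected fraction per group in ages 15-49 used
        to start the epidemic when no endemic state is supplied.
    """

    beta: dict[str, float]
    partner_change_rate: np.ndarray
    mixing: np.ndarray
    clearance_rate: dict[str, float]
    immunity_waning_rate: float = 1.0
    seed_prevalence: float = 0.01

    def __post_init__(self) -> None:
        self.partner_change_rate = np.asarray(self.partner_change_rate, float)
        self.mixing = np.asarray(self.mixing, float)
        if self.partner_change_rate.shape != (2, N_AGES):
            raise ValueError("partner_change_rate must be (2, 101)")
        if self.mixing.shape != (N_AGES, N_AGES):
            raise ValueError("mixing kernel must be (101, 101)")
        for name, val in [
            ("beta", self.beta),
            ("clearance_rate", self.clearance_rate),
        ]:
            for g, x in val.items():
                if x < 0:
                    raise ValueError(f"{name}[{g}] must be >= 0")
        if self.immunity_waning_rate < 0 or self.seed_prevalence < 0:
            raise ValueError("rates must be non-negative")
        if np.any(self.partner_change_rate < 0) or np.any(self.mixing < 0):
            raise ValueError("rates must be non-negative")
        rowsum = self.mixing.sum(axis=1)
        bad = (np.abs(rowsum - 1.0) > 1e-9) & (rowsum > 0)
        if np.any(bad):
            raise ValueError("mixing rows must sum to 1 (or be all zero)")

    @classmethod
    def proportionate(
        cls,
        beta: dict[str, float],
        partner_change_rate: np.ndarray,
        clearance_rate: dict[str, float],
        **kw,
    ) -> "TransmissionParams":
        """Proportionate mixing: partners found in proportion to opposite-sex
        partnership activity (sex-averaged here, adequate for near-symmetric
        activity profiles)."""
        act = np.asarray(partner_change_rate, float).mean(axis=0)
        total = act.sum()
        mixing = np.zeros((N_AGES, N_AGES))
        if total > 0:
            mixing[:] = act / total
            mixing[act == 0] = 0.0
        return cls(
            beta=beta,
            partner_change_rate=partner_change_rate,
            mixing=mixing,
            clearance_rate=clearance_rate,
            **kw,
        )


def force_of_infection(
    prevalence: np.ndarray,
    groups: list[str],
    params: TransmissionParams,
    sex: int,
    age: int,
) -> np.ndarray:
    """Per-year infection hazard per subtype group for one (sex, age).

    ``prevalence`` is a (2, 101, G) fraction-infected field.  The hazard is
    zero whenever opposite-sex prevalence is zero.
    """
    field_ = force_of_infection_field(prevalence, groups, params)
    return field_[sex, age]


def force_of_infection_field(
    prevalence: np.ndarray,
    groups: list[str],
    params: TransmissionParams,
) -> np.ndarray:
    """Vectorized hazard field: (2, 101, G) for all sexes and ages."""
    prevalence = np.asarray(prevalence, float)
    if np.any(prevalence < -1e-12) or np.any(prevalence > 1 + 1e-12):
        raise ValueError("prevalence entries must be in [0, 1]")
    G = len(groups)
    out = np.zeros((2, N_AGES, G))
    beta = np.array([params.beta[g] for g in groups])
    for sex in (0, 1):
        other = 1 - sex
        # (101, G): mixing-weighted opposite-sex prevalence
        mixed = params.mixing @ prevalence[other]
        out[sex] = params.partner_change_rate[sex][:, None] * mixed * beta[None, :]
    return out


@dataclass
class PrevalenceField:
    """Infected fraction by sex x age x subtype group at one time step."""

    groups: list[str]
    prevalence: np.ndarray  # (2, 101, G)

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, float)
        if self.prevalence.shape != (2, N_AGES, len(self.groups)):
            raise ValueError("prevalence must be (2, 101, n_groups)")
        if np.any(self.prevalence < 0) or np.any(self.prevalence > 1):
            raise ValueError("prevalence entries must be in [0, 1]")
        if np.any(self.prevalence.sum(axis=2) > 1 + 1e-9):
            raise ValueError("per (sex, age) prevalence must sum to <= 1")


def step_infection(
    prevalence: PrevalenceField,
    params: TransmissionParams,
    dt: float = 1.0,
) -> np.ndarray:
    """Healthy→HPV per-cycle transition probabilities from current prevalence.

    Converts the hazard field to probabilities via ``p = 1 - exp(-h * dt)``;
    this is what the cohort engine applies every cycle so prevalence and
    incidence co-evolve.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = force_of_infection_field(prevalence.prevalence, prevalence.groups, params)
    return -np.expm1(-h * dt)
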