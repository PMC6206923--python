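"""Deterministic annual-cycle cohort simulation.

The engine advances an open population (steady annual birth cohorts,
single-year ages 0–100) through a :class:`~gcea.states.StateGraph` under an
age- and sex-specific :class:`RateSchedule` of transition intensities.
Intensities are converted to per-cycle probabilities by the exponential
formula ``p = 1 - exp(-rate * dt)`` with competing risks within a cycle
allocated proportionally to intensities.  There is no randomness anywhere:
identical inputs give bit-identical trajectories.

Sex is indexed 0 = female, 1 = male throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import StateGraph

N_AGES = 101  # single-year ages 0..100 (100 is an open bracket)
FEMALE, MALE = 0, 1

Edge = tuple[str, str]


class SimulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


def probability_from_rate(rate: float | np.ndarray, dt: float = 1.0):
    """Per-cycle transition probability from an annual intensity.

    ``1 - exp(-rate * dt)``.  When several intensities compete within one
    cycle the total exit probability is ``1 - exp(-sum(rates) * dt)`` and is
    split across destinations proportionally to the intensities.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("transition intensities must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = -np.expm1(-rate * dt)
    return float(out) if out.ndim == 0 else out


def expand_age_bands(band_values: dict[tuple[int, int], float]) -> np.ndarray:
    """Step-interpolate coarse age-band values onto single-year ages 0..100."""
    out = np.zeros(N_AGES)
    for (lo, hi), val in band_values.items():
        if not (0 <= lo <= hi <= 100):
            raise ValueError(f"bad age band ({lo}, {hi})")
        out[lo : hi + 1] = val
    return out


# ---------------------------------------------------------------------------
# rate schedules
# ---------------------------------------------------------------------------


@dataclass
class RateSchedule:
    """Annual transition intensities per edge, sex and single-year age.

    ``rates[(u, v)]`` is a ``(2, 101)`` array (sex x age).  Scenario machinery
    may attach time-varying multipliers per edge: ``multipliers[(u, v)]`` is a
    ``(horizon, 2, 101)`` array applied on top of the base intensity in the
    matching simulation year (used e.g. for cohort-tracked vaccination).
    """

    rates: dict[Edge, np.ndarray] = field(default_factory=dict)
    multipliers: dict[Edge, np.ndarray] = field(default_factory=dict)

    def set(self, edge: Edge, value, sex: int | None = None) -> None:
        arr = self.rates.setdefault(edge, np.zeros((2, N_AGES)))
        if sex is None:
            arr[:] = value
        else:
            arr[sex] = value

    def get(self, edge: Edge) -> np.ndarray:
        return self.rates[edge]

    def copy(self) -> "RateSchedule":
        return RateSchedule(
            rates={e: a.copy() for e, a in self.rates.items()},
            multipliers={e: a.copy() for e, a in self.multipliers.items()},
        )

    def scale_edge(self, edge: Edge, factor, sex: int | None = None) -> None:
        if sex is None:
            self.rates[edge] *= factor
        else:
            self.rates[edge][sex] *= factor

    def add_multiplier(self, edge: Edge, mult: np.ndarray) -> None:
        """Compose a (horizon, 2, 101) time-varying multiplier onto an edge."""
        if edge in self.multipliers:
            h = min(self.multipliers[edge].shape[0], mult.shape[0])
            self.multipliers[edge] = self.multipliers[edge][:h] * mult[:h]
        else:
            self.multipliers[edge] = mult.copy()

    def validate(self, graph: StateGraph) -> list[str]:
        problems = []
        for u, v, k in graph.edges:
            if k == "mortality":
                continue  # cause-specific mortality may be implicit zero
            if (u, v) not in self.rates:
                problems.append(f"no rate entry for edge ({u} -> {v})")
        for e, a in self.rates.items():
            if a.shape != (2, N_AGES):
                problems.append(f"rate array for {e} has shape {a.shape}")
            elif np.any(a < 0):
                problems.append(f"negative intensity on edge {e}")
        return problems


@dataclass
class Demography:
    """Open-population demography: steady births and background mortality."""

    births: np.ndarray  # (2,) annual birth-cohort size by sex
    background_mortality: np.ndarray  # (2, 101) annual all-cause intensity
    max_age: int = 100

    def __post_init__(self) -> None:
        self.births = np.asarray(self.births, dtype=float)
        self.background_mortality = np.asarray(self.background_mortality, float)
        if np.any(self.births <= 0):
            raise ValueError("birth cohorts must be positive")
        if np.any(self.background_mortality < 0):
            raise ValueError("mortality intensities must be non-negative")

    def survivorship(self) -> np.ndarray:
        """(2, 101) stationary person-years per single birth per age."""
        m = self.background_mortality
        surv = np.ones((2, N_AGES))
        q = 1.0 - np.exp(-m)
        for a in range(1, N_AGES):
            surv[:, a] = surv[:, a - 1] * (1.0 - q[:, a - 1])
        # open age bracket 100+: geometric tail under the age-100 hazard
        with np.errstate(divide="ignore"):
            tail = np.where(q[:, -1] > 0, (1.0 - q[:, -1]) / q[:, -1], 0.0)
        surv[:, -1] *= 1.0 + tail
        return surv

    def stationary_population(self) -> np.ndarray:
        """(2, 101) alive counts of the stationary open population."""
        return self.births[:, None] * self.survivorship()

    @classmethod
    def standard(cls, total_population: float = 10_000_000.0) -> "Demography":
        """Synthetic life table scaled so the stationary total is 10 million."""
        ages = np.arange(N_AGES)
        m = 0.003 + 2.5e-5 * np.exp(0.09 * ages)
        m[0] += 0.02  # infant mortality
        bg = np.vstack([m, m * 1.15])  # male excess
        d = cls(births=np.array([1.0, 1.0]), background_mortality=bg)
        scale = total_population / d.stationary_population().sum()
        d.births = d.births * scale
        return d


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """State occupancy and event flows from one simulation run.

    ``occupancy[t, sex, age, state]`` is person-years lived in the state
    during year ``t`` (annual cycles, no half-cycle correction).
    ``flows[(u, v)][t, sex, age]`` counts transitions made during year ``t``.
    """

    states: list[str]
    occupancy: np.ndarray  # (horizon, 2, 101, S)
    flows: dict[Edge, np.ndarray]  # (horizon, 2, 101)
    entrants: np.ndarray  # (horizon, 2) new births per year
    initial_population: np.ndarray  # (2, 101, S)
    dead_state: str = "dead"

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    def alive(self) -> np.ndarray:
        """(horizon, 2, 101) person-years alive (all non-dead states)."""
        keep = [i for i, s in enumerate(self.states) if s != self.dead_state]
        return self.occupancy[..., keep].sum(axis=-1)

    def person_years(self) -> float:
        return float(self.alive().sum())

    def deaths_per_year(self) -> np.ndarray:
        """(horizon,) total deaths per year from every flow into dead."""
        out = np.zeros(self.horizon)
        for (u, v), f in self.flows.items():
            if v == self.dead_state:
                out += f.sum(axis=(1, 2))
        return out

    def conservation_residual(self) -> float:
        """Max relative |entrants - (alive + cumulative deaths)| over years.

        The occupancy recorded for year t is the start-of-year population, so
        the book-keeping identity checked is: initially alive + births up
        to year t equals year-t alive occupancy plus deaths before year t.
        (Mass already in the dead state at t=0 — e.g. from a burn-in warm
        start — is outside the ledger.)
        """
        dead_i = self.states.index(self.dead_state)
        keep = [i for i in range(len(self.states)) if i != dead_i]
        total0 = self.initial_population[..., keep].sum()
        births = self.entrants.sum(axis=1)
        deaths = self.deaths_per_year()
        alive = self.alive().sum(axis=(1, 2))
        max_rel = 0.0
        cum_births = 0.0
        cum_deaths = 0.0
        for t in range(self.horizon):
            # births and deaths of year t first appear in year t+1 occupancy
            expected = total0 + cum_births - cum_deaths
            rel = abs(alive[t] - expected) / max(expected, 1.0)
            max_rel = max(max_rel, rel)
            cum_births += births[t]
            cum_deaths += deaths[t]
        return max_rel

    def diagnoses(self, graph: StateGraph) -> np.ndarray:
        """(horizon, 2, 101) clinical diagnoses (all preclinical->clinical)."""
        out = np.zeros((self.horizon, 2, N_AGES))
        for u, v in graph.edges_of("diagnosis"):
            if (u, v) in self.flows:
                out += self.flows[(u, v)]
        return out

    def incidence_per_100k(
        self,
        graph: StateGraph,
        age_bands: list[tuple[int, int]],
        last_n: int = 5,
        sex: int | None = None,
    ) -> np.ndarray:
        """Mean annual clinical diagnoses per 100,000 alive, by age band."""
        diag = self.diagnoses(graph)[-last_n:]
        alive = self.alive()[-last_n:]
        if sex is not None:
            diag, alive = diag[:, [sex]], alive[:, [sex]]
        out = np.zeros(len(age_bands))
        for i, (lo, hi) in enumerate(age_bands):
            d = diag[:, :, lo : hi + 1].sum()
            a = alive[:, :, lo : hi + 1].sum()
            out[i] = 1e5 * d / a if a > 0 else 0.0
        return out

    def to_frame(self):
        """Tidy long DataFrame (state, sex, age, year, person_years)."""
        import pandas as pd

        h, _, _, S = self.occupancy.shape
        idx = pd.MultiIndex.from_product(
            [range(h), ["female", "male"], range(N_AGES), self.states],
            names=["year", "sex", "age", "state"],
        )
        return pd.DataFrame(
            {"person_years": self.occupancy.reshape(-1)}, index=idx
        ).reset_index()


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


def _transition_tensor(Q: np.ndarray) -> np.ndarray:
    """Convert an intensity tensor (..., S, S) to per-cycle probabilities."""
    R = Q.sum(axis=-1)
    p_exit = -np.expm1(-R)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(R[..., None] > 0, Q / np.maximum(R[..., None], 1e-300), 0.0)
    T = p_exit[..., None] * share
    idx = np.arange(Q.shape[-1])
    T[..., idx, idx] += 1.0 - p_exit
    return T


def simulate(
    graph: StateGraph,
    rates: RateSchedule,
    demography: Demography,
    horizon: int,
    transmission=None,
    initial_occupancy: np.ndarray | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Run the annual-cycle state-transition simulation.

    Parameters
    ----------
    graph, rates, demography
        Model structure, intensities and population inflow/background
        mortality.  ``rates`` may carry time-varying multipliers.
    horizon
        Number of annual cycles (years of programme implementation).
    transmission
        Optional :class:`~gcea.transmission.TransmissionParams`; when given,
        the healthy→HPV intensities are recomputed every cycle from current
        opposite-sex prevalence (dynamic force of infection).
    initial_occupancy
        ``(2, 101, S)`` start population; defaults to the stationary
        population placed entirely in the healthy state (with a small seed
        of HPV prevalence when transmission is active).
    """
    from . import transmission as tx  # local import; avoids cycle

    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    problems = rates.validate(graph)
    if problems:
        raise SimulationError("; ".join(problems))

    states = graph.state_names
    S = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    dead = sidx[graph.dead_state]
    # births enter the healthy state (first listed state as a fallback for
    # abstract test graphs)
    healthy = sidx.get("healthy", 0)

    # static intensity tensor
    Q0 = np.zeros((2, N_AGES, S, S))
    for (u, v), arr in rates.rates.items():
        if u in sidx and v in sidx:
            Q0[:, :, sidx[u], sidx[v]] += arr
    # background mortality applies in every alive state
    for i in range(S):
        if i != dead:
            Q0[:, :, i, dead] += demography.background_mortality

    dyn_edges = {e for e in rates.multipliers}
    hpv_idx: dict[str, int] = {}
    if transmission is not None:
        hpv_idx = {g: sidx[g.lower()] for g in tx.SUBTYPE_GROUPS if g.lower() in sidx}

    if initial_occupancy is None:
        O = np.zeros((2, N_AGES, S))
        O[:, :, healthy] = demography.stationary_population()
        if transmission is not None:
            seed = transmission.seed_prevalence
            active = slice(15, 50)
            for g, gi in hpv_idx.items():
                moved = O[:, active, healthy] * seed
                O[:, active, gi] += moved
                O[:, active, healthy] -= moved
    else:
        O = np.array(initial_occupancy, dtype=float)
        if O.shape != (2, N_AGES, S):
            raise ValueError("initial_occupancy has wrong shape")

    static = transmission is None and not dyn_edges
    T = _transition_tensor(Q0 * dt) if static else None

    occupancy = np.zeros((horizon, 2, N_AGES, S))
    flows: dict[Edge, np.ndarray] = {
        (u, v): np.zeros((horizon, 2, N_AGES)) for (u, v, k) in graph.edges
    }
    entrants = np.zeros((horizon, 2))
    initial_population = O.copy()
    vacc_mult = rates.multipliers  # alias

    for t in range(horizon):
        occupancy[t] = O
        if not static:
            Q = Q0.copy()
            for (u, v), mult in vacc_mult.items():
                if u in sidx and v in sidx:
                    m = mult[min(t, mult.shape[0] - 1)]
                    Q[:, :, sidx[u], sidx[v]] = Q0[:, :, sidx[u], sidx[v]] * m
            if transmission is not None:
                alive = O.sum(axis=2) - O[:, :, dead]
                prev = np.zeros((2, N_AGES, len(hpv_idx)))
                order = list(hpv_idx)
                with np.errstate(invalid="ignore", divide="ignore"):
                    for j, g in enumerate(order):
                        prev[:, :, j] = np.where(
                            alive > 0, O[:, :, hpv_idx[g]] / np.maximum(alive, 1e-300), 0.0
                        )
                foi = tx.force_of_infection_field(prev, order, transmission)
                for j, g in enumerate(order):
                    base = foi[:, :, j]
                    edge = ("healthy", g.lower())
                    if edge in vacc_mult:
                        m = vacc_mult[edge][min(t, vacc_mult[edge].shape[0] - 1)]
                        base = base * m
                    Q[:, :, healthy, hpv_idx[g]] = base
            T = _transition_tensor(Q * dt)

        # flows this cycle
        for (u, v, k) in graph.edges:
            iu, iv = sidx[u], sidx[v]
            if iu != iv:
                flows[(u, v)][t] = O[:, :, iu] * T[:, :, iu, iv]

        O = np.einsum("xas,xast->xat", O, T)

        # age everyone one year; the top age is an open bracket
        aged = np.zeros_like(O)
        aged[:, 1:, :] = O[:, :-1, :]
        aged[:, -1, :] += O[:, -1, :]
        entrants[t] = demography.births
        aged[:, 0, healthy] = demography.births
        O = aged

    return Trajectory(
        states=states,
        occupancy=occupancy,
        flows=flows,
        entrants=entrants,
        initial_population=initial_population,
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibrate_onset_rates(
    graph: StateGraph,
    rates: RateSchedule,
    demography: Demography,
    target_incidence: dict[tuple[int, int], float],
    onset_edges: list[Edge] | None = None,
    sex: int | None = None,
    horizon: int = 90,
    rel_tol: float = 0.01,
    max_iter: int = 100,
    transmission=None,
) -> RateSchedule:
    """Rescale onset intensities until simulated clinical incidence matches.

    ``target_incidence`` maps age bands to annual clinical diagnoses per
    100,000 alive (both sexes unless ``sex`` restricts).  Onset intensities
    on ``onset_edges`` (default: the graph's onset-kind edges) are rescaled
    per age band by iterative proportional fitting; progression and diagnosis
    rates stay fixed.  Raises :class:`CalibrationError` with the final
    residuals when the 1% relative tolerance is not reached in ``max_iter``
    iterations.
    """
    bands = sorted(target_incidence)
    targets = np.array([target_incidence[b] for b in bands], dtype=float)
    if np.any(targets < 0):
        raise ValueError("target incidence must be non-negative")
    if onset_edges is None:
        onset_edges = graph.edges_of("onset")

    work = rates.copy()
    if np.all(targets == 0):
        for e in onset_edges:
            work.rates[e][:] = 0.0
        return work

    # ensure a positive starting intensity wherever a positive target exists
    for e in onset_edges:
        arr = work.rates[e]
        rows = [sex] if sex is not None else [0, 1]
        for (lo, hi), tgt in target_incidence.items():
            if tgt > 0:
                for r in rows:
                    band = arr[r, lo : hi + 1]
                    band[band <= 0] = max(band.max(), 1e-5)

    residuals = None
    for _ in range(max_iter):
        traj = simulate(graph, work, demography, horizon, transmission=transmission)
        sim = traj.incidence_per_100k(graph, bands, sex=sex)
        with np.errstate(divide="ignore", invalid="ignore"):
            residuals = np.where(targets > 0, np.abs(sim - targets) / targets, sim)
        if np.all(residuals <= rel_tol):
            return work
        ratio = np.where(sim > 0, targets / np.maximum(sim, 1e-300), np.nan)
        if np.any(np.isnan(ratio) & (targets > 0)):
            raise CalibrationError(
                "simulated incidence is zero where the target is positive "
                "(onset cannot reach diagnosis — check diagnosis rates)",
                residuals=residuals,
            )
        ratio = np.clip(np.nan_to_num(ratio, nan=0.0), 0.0, 10.0)
        for e in onset_edges:
            for i, (lo, hi) in enumerate(bands):
                if sex is None:
                    work.rates[e][:, lo : hi + 1] *= ratio[i]
                else:
                    work.rates[e][sex, lo : hi + 1] *= ratio[i]
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(max residual {float(np.max(residuals)):.4f})",
        residuals=residuals,
    )
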