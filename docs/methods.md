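# Methods

This note documents the model, its assumptions, the defaults and the design
choices made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Cohort engine

A deterministic state-transition (Markov) cohort simulation over an **open
population**: single-year ages 0–100 (age 100 is an open bracket), two
sexes, annual cycles, no half-cycle correction.  A constant birth cohort
enters the healthy state each year; the synthetic life table is scaled so
the stationary population totals 10 million alive, which makes all outputs
directly "per 10 million population".  Background (all-cause, non-modelled)
mortality applies in every alive state; cancer states additionally carry
stage-specific excess mortality.

Annual transition intensities are converted to per-cycle probabilities by
`p = 1 − exp(−rate)`; competing risks inside a cycle are allocated
proportionally to intensities.  This makes row sums of the transition matrix
exactly 1, so person-years are conserved to machine precision (the
`conservation_residual` check, asserted < 1e-9 in tests, observed ~1e-15).
The engine contains no randomness: identical inputs give bit-identical
trajectories.  For time-homogeneous closed cohorts the engine is verified
against explicit transition-matrix powers.

Coarse age-band parameters are expanded to single-year ages by step
interpolation.  Programme horizon is 100 years; person-time beyond year 100
is truncated (a reporting convention: cohorts vaccinated near the end of the
window contribute only their within-window person-time).

All scenario simulations start from the end state of a 100-year **null
burn-in**, so disease prevalence — including the HPV epidemic — is at its
endemic level when the programme begins; the accumulated dead mass of the
burn-in is dropped from the ledger.

## State spaces

* **Cervical (women):** healthy; three HPV infection states (16/18, other
  high-risk, low-risk — one at a time, co-infection is not represented);
  CIN1 and CIN2-3 precancer; preclinical and clinical CIS, I–IV; a
  short-term immune state on the regression path (clearance → immunity →
  waning back to healthy, mean immune duration 1 year — the duration is not
  identified by available evidence, so it is an explicit config default);
  dead.  Regression toward health exists only for infection and CIN; CIN
  regression returns women to the *infected* state (screen-and-treat
  likewise regresses CIN to HPV), which keeps them exposed to re-progression
  — this choice matters for reinfection dynamics and is therefore
  deliberately explicit.
* **Men** carry a reduced model (healthy, three HPV states, immune, dead):
  they participate in transmission but never develop the modelled cancers.
  Implementation detail: the engine simulates both sexes on the full
  cervical graph with all male progression intensities beyond infection set
  to zero; the reduced male graph is also built and validated as structural
  documentation.
* **Breast (women):** healthy → preclinical CIS → I–IV with per-stage
  diagnosis edges; no precancer states, no regression.
* **Colorectal (both sexes):** two onset routes — an adenoma pathway with
  three polyp size classes (≤5 mm, 6–9 mm, ≥10 mm; small/medium polyps can
  regress to healthy) and a direct de-novo route to CIS.  Onset rate mass is
  split 77%/23% between the routes (configurable).
* Clinical stage IV doubles as the **terminal phase** for disability-weight
  purposes; no separate terminal state is created (minimal state space
  consistent with the GBD weight labels).
* Whether clinically diagnosed patients progress between clinical stages is
  not empirically settled here; the default allows clinical progression at
  the same stage-to-stage intensities, flagged for sensitivity analysis.

## HPV transmission

A two-sex, age-structured, frequency-dependent SIS-with-immunity model —
the simplest structure consistent with the qualitative requirements
(heterosexual transmission, subtype groups, clearance, short-term
immunity).  The hazard of acquiring group *g* at sex *x*, age *a* is

    λ_g(x, a) = c(x, a) · Σ_a′ M(a, a′) · β_g · prev(other(x), a′, g)

with partner-change rate `c` (synthetic schedule peaking at 1.4/yr at ages
20–24, zero outside 15–64), proportionate mixing kernel `M` (rows normalized
to activity shares), and per-partnership-year transmission probability
`β_g = 0.8`.  Clearance is 0.4/yr for every group: the groups compete for
one susceptible pool, so unequal R0 drives near-exclusion of the weaker
groups; equal transmission parameters keep all three endemic (~8% prevalence
each in the active ages) and locate all oncogenicity differences in the
progression rates, which are scaled so cancers attribute ≈70/28/2% to
16/18 / other-high-risk / low-risk.  The epidemic threshold of the
implementation is verified by bisection against the analytic SIS condition
`c·β > clearance`.

Vaccination is **take-type**: a susceptibility multiplier
`1 − coverage × efficacy` (efficacy 0.95 against 16/18 only, no
cross-protection) applied to the 16/18 hazard of female cohorts that passed
the vaccination age (12) after programme start.  Boys are not vaccinated;
men benefit only through reduced female prevalence.  An all-or-nothing
formulation was rejected because coverage scaling would become nonlinear.

## Interventions

Coverage scales **linearly**: the covered fraction experiences the full
per-protocol effect, so every modified rate at coverage c is the c-weighted
mixture of the coverage-0 and coverage-1 rates (asserted as an invariant).
Screening frequencies convert to annual screen probabilities
`coverage / interval`; intervals are explicit configuration — VIA 10 years
(once per decade in ages 30–49), Pap 4 years (the "every 3–5 years"
ambiguity resolved to its midpoint), HPV test 5 years, mammography 2 years
(ages 50–69).  Screening adds `screen rate × sensitivity` to the
preclinical→clinical diagnosis intensities of the eligible band, and (for
cervical) a screen-and-treat regression intensity from CIN back to HPV.
Test sensitivity/specificity are synthetic parameters; false positives
enter costing only, never state dynamics.

Treatment (stages I–II) multiplies the excess mortality of clinical stages
I and II by 0.25–0.30 for the treated fraction and switches that fraction to
the treated disability weight; stage III/IV treatment is not in the catalog
(only palliative care addresses late stage).  Mammography is "linked to
timely diagnosis and treatment", so it carries both the diagnosis boost and
the early-stage treatment effect plus the associated treatment costs.
Palliative care switches the terminal-phase weight from "without" to "with
medication" for the covered fraction.

Combination labels (C1e–C1g) expand to their components and are simulated
**jointly** — the combination's health gain is one simulation, not a sum of
single-intervention gains.

## Disability weights and HLYs

From six GBD-2010-style primitives (diagnosis/primary therapy, metastatic,
terminal with/without medication, mastectomy, stoma):

* untreated pre-terminal stages (all cancers): diagnosis weight inflated by
  the ratio (terminal without medication) / (terminal with medication) —
  the grammatically ambiguous "ratio between the two terminal estimates" is
  resolved as without/with, the only reading giving a ratio ≥ 1;
* terminal phase: the GBD estimate used directly;
* treated cervical 0–II: diagnosis weight × fraction-in-first-year-of-
  treatment (stage III uncorrected); treated breast I–II: equal-weight
  average of diagnosis and mastectomy weights, first-year corrected (the
  exact averaging weights are not published; equal weighting is the exposed
  default); treated colorectal: 5% stoma fraction carries the stoma weight
  additively, diagnosis part first-year-corrected except stage III;
* treated weights are capped at their untreated counterpart, so treatment
  never adds net disability (binding only when the inflation ratio is ≈1).

The first-year correction is operationalized as a prevalence-fraction
multiplier (default 0.7) on the stage weight rather than explicit
time-in-state tracking.  Undiagnosed (preclinical), infection, precancer and
immune states carry zero disability.

`HLY = Σ_{state≠dead} Σ_t occupancy × (1 − DW)`, discounted variant weights
year-t terms by `(1+r)^{−t}`, r = 0.03 default; r = 0 makes both identical
exactly.  ACER/ICER denominators use undiscounted HLYs (consistent with the
budget-table identity ACER = total cost / total undiscounted HLY); the
discounted totals are computed and reported alongside.

## Costing

Ingredients-based: yearly event streams (vaccine doses, screens, lesion
treatments, treatment courses, palliative episodes) counted from the
simulated trajectory, multiplied by synthetic unit costs (I$ 2010; the
regional price level is a scalar).  Screening programmes are loaded so that
programme-level components are 20% of the programme total
(`patient cost / (1 − 0.20)`), and add false-positive follow-up =
screens × (1 − specificity) × work-up cost; vaccination and treatment carry
their own itemized costs without the 20% rule.  All flows discount at 3%
from programme start; league tables carry costs in million I$ (the budget
table in plain I$ — the two printed conventions are reconciled this way).

## Frontier and expansion path

Ratios are rounded half-up: integers for league-table ACERs/ICERs, two
decimals for programme ACERs — this policy reproduces every published ratio
from its printed cost/HLY inputs (for the palliative rows, whose HLY
denominators are small, the million-rounding of printed costs limits
agreement to ±0.5e6/HLY; the tests annotate this as an expected deviation
rather than forcing a match).

The expansion path is a greedy walk over independent **technology-family
arms** (per cancer: prevention, screening, treatment, palliative): at each
step the feasible candidates are the packages retaining every adopted
technology at the same or higher coverage, and the lowest-ICER candidate
(against its arm's current point) is adopted.  Family-level independence
mirrors the published tables, where treatment and palliative rows carry
ICER = ACER; within the cervical prevention family, vaccination+screening
packages are simulated jointly.  The walk is verified against an
exhaustive-enumeration oracle on small instances.  Extended dominance is
implemented (standard CEA practice) even though only simple dominance is
strictly required; dominated packages are reported, not dropped.

## Synthetic regions

`RegionProfile` holds incidence targets (per 100,000, GLOBOCAN-like in
magnitude), stage distribution, HPV attribution, a price level and a seed.
`generate_region_params` builds the full bundle and calibrates onset
intensities by iterative proportional fitting until simulated age-band
clinical incidence matches the targets within 1% (hard bound 2%; observed
closure ≤0.6% on the demo).  For cervical disease the healthy→HPV edges are
owned by the transmission model, so calibration scales the HPV→CIN1
progression intensities instead — the first cancer-pathway step.  Parameter
recovery is verified: calibrating against incidence simulated from known
onset rates recovers those rates within 2%.

The only randomness in the package is the disability-weight sampling here
(seeded per profile); GBD-plausible ranges are used because the underlying
supplementary values are not published.  The two-region demo contrasts a
lower-cervical-incidence, higher-price "SEA-like" region with a
higher-incidence, lower-price "ESSA-like" region.

**What passing tests do and do not show.**  The synthetic regions emulate
the *structure* of real inputs (age-specific incidence, stage-specific
progression, ingredients-based prices), not their values: absolute costs,
HLY gains and ratios from the demo are not estimates for any real region.
What the suite establishes is internal validity (conservation, closed
forms, oracle equivalence, calibration recovery) and that the pipeline
reproduces the published *qualitative* orderings — cervical prevention
enters the path before mammography, early-stage breast treatment is cheaper
per HLY than mammography screening, and cervical prevention is markedly
more cost effective in the high-incidence region — together with the exact
arithmetic of every published ratio when fed the published cost/HLY inputs.

## Numerical choices and limitations

* Annual cycles without half-cycle correction keep results bit-reproducible
  and match the 1-year rate resolution of the inputs.
* Tie-breaks: equal-ICER path candidates resolve by label; coverage ladders
  of a linear intervention have equal rung ICERs, so ladder rungs may merge
  or appear in single jumps depending on floating-point noise — both are
  valid frontiers.
* Degenerate inputs: zero-HLY denominators raise (`acer`) or signal
  dominance (`icer`); calibration against targets unreachable under zero
  diagnosis rates reports non-convergence with residuals.
* Not modelled: molecular subtypes (e.g. HER2+), catch-up vaccination,
  HPV-related non-cervical cancers, stochastic/probabilistic sensitivity
  analysis, willingness-to-pay classification, country-level budget impact.
* Problem sizes: 101 ages × 2 sexes × ≤18 states, 100-year burn-in +
  100-year horizon, ~40 package evaluations per region — the full two-region
  analysis runs in seconds on one CPU, chosen so the whole suite iterates
  quickly.
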