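# gcea — generalized cost-effectiveness analysis of cancer control programmes

`gcea` implements a WHO-CHOICE-style **generalized cost-effectiveness
analysis (GCEA)** of breast, cervical and colorectal cancer interventions as
a reusable, tested Python pipeline.  It is aimed at health economists and
epidemiological modellers who want a transparent, fully synthetic-data-driven
reimplementation of the classic sectoral league-table / expansion-path
machinery: every intervention is compared against a hypothetical **null**
scenario in which the effects of all current interventions are removed, and
an optimal step-wise adoption sequence is derived.

## What it computes

1. **Natural history.**  Each cancer is a multi-state Markov model over
   single-year ages 0–100 for an open population (steady birth cohorts,
   10 million alive at baseline).  Cervical: dynamic two-sex HPV
   transmission (subtype groups 16/18, other high-risk, low-risk),
   CIN1 → CIN2-3 precancer with regression and short-term immunity, then
   preclinical/clinical CIS → I → II → III → IV.  Breast: onset directly as
   carcinoma in situ.  Colorectal: a 77%/23% split between an adenoma
   (three polyp size classes) and a de-novo route.  Diagnosis is a modelled
   preclinical → clinical transition; regression toward health exists only
   for pre-cancerous states.

2. **Interventions.**  The 14-intervention catalog (9 cervical, 3 breast,
   2 colorectal): HPV vaccination of 9–13-year-old girls, cervical screening
   by VIA / Pap smear / HPV test linked to treatment of pre-cancerous
   lesions, vaccination+screening combinations, mammography screening,
   early-stage (I–II) treatment, and basic palliative care — each evaluated
   at 50/80/95% coverage over a 100-year programme horizon.

3. **Outcomes and costs.**  Healthy life years
   `HLY = Σ_states Σ_years person-time × (1 − DW)` with GBD-2010-style
   disability weights (treated/untreated derivation rules, terminal phase
   with/without medication), reported undiscounted and at 3% p.a.;
   ingredients-based costing in I$ 2010 with a 20% programme overhead on
   screening and false-positive follow-up costs.

4. **The frontier.**  `ACER = cost / HLY-gain-vs-null`,
   `ICER = Δcost / ΔHLY` along a greedy expansion path under technology
   lock-in (an adopted technology is never dropped or scaled down), simple
   and extended dominance filtering, league tables, and the budget share per
   cancer at full coverage.

Since the original regional parameter sets are not public, the
`gcea.synthetic` module generates complete, internally consistent **synthetic
regions** (incidence targets hit by onset-rate calibration to <1%), including
a packaged two-region demo contrasting a lower-incidence/higher-cost
"SEA-like" with a higher-incidence/lower-cost "ESSA-like" region.

## Worked example

```python
from gcea import generate_region_params, make_two_region_demo
from gcea.pipeline import analyse_region

sea, essa = make_two_region_demo()
report = analyse_region(generate_region_params(essa))
print(report.league.drop(columns=["description"]).head(4).to_string(index=False))
print("budget shares:", report.budget_shares)
```

prints (ESSA-like demo region):

```
  label  coverage_pct  cost_million_I$  hly_undiscounted  acer  icer
CVC_C1a            50        44.052027      9.780395e+05  45.0  45.0
CVC_C1a            80        70.483243      1.211786e+06  58.0 113.0
CVC_C1a            95        83.698851      1.287280e+06  65.0 175.0
CVC_C1e            95       165.324894      1.692527e+06  98.0 201.0
budget shares: {'cervical': 20, 'breast': 79, 'colorectal': 2}
```

Reading: HPV vaccination (`C1a`) enters the path first at 50% coverage —
I$ 44M (discounted, per 10 million population) buys ≈ 0.98M healthy life
years versus the null, an average cost-effectiveness of I$ 45 per HLY.  It
is scaled up (ICERs 113, 175) before VIA screening joins it in the
combination `C1e`; mammography, with the highest ICER, enters last.  In the
lower-incidence SEA-like region the same vaccination step costs I$ 135 per
HLY — cervical prevention is markedly more cost effective where incidence is
high.

The numbered drivers under `analysis/` run the same steps as a narrative
sequence (graph construction → region generation/calibration → null
baseline → package evaluations → expansion path), writing their tables under
`results/`.  A thin CLI is also available: `gcea demo`, `gcea simulate`,
`gcea evaluate --scenario 'C1e=0.8,C1i=0.95'`, `gcea path`.

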