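# Methods

## Model structure

The model is an individual-level (microsimulation) state-transition
model with 1-year cycles and four health states: *no new fracture*,
*post-fracture*, *post-hip-fracture*, and *dead*. Individual memory is
carried by tracker variables rather than state proliferation: per-type
fracture counts and histories, hip-fracture count (capped at two),
long-term-care status, and treatment status. A woman enters at her
start age (65, 70, 75, or 80) and is simulated until death or age 105.

Within a cycle the event order is: death draw, fracture draw (at most
one fracture per cycle), tracker/treatment updates, cost and utility
accrual. Death-first ordering is the conservative standard for
annual-cycle microsimulations; an individual who dies in a cycle
accrues nothing that cycle, and the dead state is absorbing. No
half-cycle correction is applied: events and accruals belong to the
cycle in which they occur, consistent with the end-of-cycle
persistence rule below.

### Fracture risk

Per-type probability in a cycle:

```
p_k = incidence_k(age) · RR_pv,k · RR_op,k · RR_treat,k     (clamped to [0,1])
```

where `RR_pv` is the risk elevation for prior vertebral fracture
(2.3/4.4/1.4/1.8 for hip/vertebral/wrist/other), `RR_op` the elevation
for densitometric osteoporosis (synthetic defaults, see below), and
`RR_treat` the effective treatment relative risk. The any-fracture
probability is `1 − Π_k(1 − p_k)`; conditional on a fracture the type
is drawn proportional to `p_k`. After two hip fractures the hip
probability is set to zero without renormalising the other types.

### Mortality

Annual death probabilities come from an age-indexed life table
(65–105). After any hip fracture a lifelong excess-mortality relative
risk applies, attenuated to its attributable fraction:
`q' = q · (1 + f·(RR − 1))` with `f = 0.25`. Clinical vertebral
fractures carry no excess mortality.

### Treatment, persistence, adherence

Strategies: *sequential* (teriparatide 2 years, then alendronate 10
years), *alendronate alone* (10 years), and *no treatment* (used for
model-validation runs). Women who discontinue teriparatide do **not**
begin alendronate — only completers of the 2-year course start the
second drug, with a fresh persistence draw; non-starters/discontinuers
never re-initiate.

Persistence curves pass through (0 months, 1.0) and the observed
12-/24-month values, continue on the 12→24-month slope to month 60
(clamped at 0), and are flat thereafter. Adherence follows the same
linear extension by treatment year, with the year-5 value carried
forward from year 6 on. Each woman's discontinuation time is drawn
once at course start by inverse-CDF on the persistence curve; she
receives a cycle's protection only if she persists to that cycle's
end. The year-specific adherence value (not the 12-month value) feeds
the efficacy scaling each year.

Community efficacy: `RR_community = 1 − min(1, a/0.80)·(1 − RR_trial)`
with a trial-reference adherence of 0.80 for both drugs. The cap at 1
prevents above-trial adherence from amplifying efficacy.

Offset (washout): after stopping, the effective RR returns linearly to
1 over `W = W_planned · years_completed / planned_duration`
(`W_planned` = 10 years for alendronate, 1 year for teriparatide, so a
full teriparatide course protects through year 3). The offset RR is
evaluated at mid-cycle (`j − 0.5` years since stopping in the j-th
post-stop year), which is the natural discretisation of a linear
return in an annual-cycle model. When several protection sources
overlap (teriparatide washout during alendronate years), the strongest
(minimum RR) applies rather than multiplying, to avoid double-counting
the anti-fracture effect.

### Costs

2018 USD throughout; no internal inflation adjustment. Components and
sectors (impact-inventory style):

| component | rule | sector |
|---|---|---|
| drug | annual cost × adherence while persisting; one 3-month fill for first-year discontinuers; prorated by time on drug in a later discontinuation year | formal health care |
| physician visits | 2/yr on teriparatide, 1/yr on alendronate, while persisting | formal health care |
| DXA | end of teriparatide year 2; alendronate years 5 and 10, while persisting | formal health care |
| fracture treatment | per event: 29,986 / 8,325 / 4,577 / 14,144 | formal health care |
| long-term care, acute | 6 months × $7,159 × 25% attributable, charged to the 12% drawn into LTC in the hip-fracture year | non-health care |
| long-term care, steady state | $2,577/yr (= 7,159·12·0.12·0.25, population-averaged) to everyone post-hip, from the cycle after the fracture | non-health care |
| unpaid productivity | 8 weeks × $757 × labor-force participation (27.9%/16.6%/5.9% for 65–69/70–74/75–80), hip-fracture year only, none past 80 | non-health care |

The acute LTC charge is restricted to the individuals actually drawn
into long-term care (an independent 12% Bernoulli per hip fracture) so
that its population average per hip fracture equals
6·monthly·0.12·0.25 — the same averaging convention that produces the
$2,577 annual figure. The health-care-sector perspective drops the
non-health-care components; societal cost therefore dominates
health-care-sector cost trajectory by trajectory.

Drug pricing: annual cost = unit price × fills/year × payment factor
(alendronate: 52 weekly tablets, generic at 27% of AWP, brand at 64%;
teriparatide: 13 × 28-day pens at 62% of WAC), blended by generic
share. All arithmetic is full-precision internally; only reported
figures are rounded (dollars to the nearest dollar, QALYs to two
decimals, ICERs to the nearest $100).

### Utilities

Cycle utility = baseline utility(age) × product of active disutility
multipliers. A fracture this cycle contributes its first-year
multiplier; each previously fractured type contributes its
subsequent-year multiplier (1.0 for wrist/other, which have no
disutility beyond the first year). Concurrent histories combine
multiplicatively, which keeps utility in (0, 1] and is the
conservative convention.

### Discounting and comparison

Costs and QALYs are discounted at 3%/year, first cycle undiscounted.
ICER = ΔC/ΔE with dominance labels when signs disagree. Per-strategy
seeds fan out from a single master seed through named substreams via
`numpy.random.SeedSequence(master, spawn_key=(stream, i))`; common
random numbers (the same individual seed in both strategies) are on by
default and can be disabled. Because each individual's uniforms are
pre-drawn in a fixed shape, pairing is exact regardless of path.

## Sensitivity analyses

*One-way:* a single scalar (addressed by a dotted path such as
`costs.annual_drug_cost.teriparatide`) is substituted and both
strategies re-run with paired seeds.

*Threshold:* the generic/biosimilar teriparatide discount runs over
the grid 30%…95% in 5% steps at shares {0.9, 0.75, 0.6}; the reported
threshold is the smallest grid discount with ICER at or below the
willingness-to-pay value.

*Probabilistic:* two-level Monte Carlo. The outer loop draws every
parameter carrying a distribution (the printed-table rows: 8 efficacy
RRs, 8 persistence/adherence values, 8 cost rows, 3 productivity
rows, 4 prior-vertebral RRs); the inner loop runs both strategies with
paired seeds and records (ΔC, ΔE). Inner trials reuse the same seed
set in every outer simulation, so with all distributions collapsed to
point masses the PSA reproduces the base case exactly. Parameters are
sampled independently (no correlation structure is specified); two
repairs keep draws structurally valid: 24-month persistence/adherence
is clamped to its 12-month draw, and risk-elevation RRs are floored at
1. The CEAC reports, per willingness-to-pay value, the fraction of
outer draws with non-negative net monetary benefit `wtp·ΔE − ΔC`.

Distribution fitting from a (base, low, high) row: **triangular** —
support [low, high], mode at base (used for the ±50% ranges, where the
range is clearly the support); **beta** — support [low, high], mean at
base, the range width read as ±1.96 sd; **log-normal** — median at
base, (low, high) as a central 95% interval on the log scale;
**gamma** — mean at base, (high − low)/3.92 as the sd; **point mass**
— the base value.

## Synthetic inputs

Fracture incidence, baseline utilities, disutility multipliers, the
life table, the osteoporosis RRs, and the hip excess-mortality RR are
available only from external sources, so the package generates
deterministic synthetic stand-ins:

- **Life table**: Gompertz `q(age) = min(1, a·e^{b(age−65)})` with
  a = 0.011, b = 0.105, chosen so ≥99.9% of a 65-year-old cohort dies
  by 105 (the model-validation benchmark) with a plausible remaining
  life expectancy.
- **Incidence**: `base_k · e^{slope_k(age−65)}` with bases
  0.0030/0.0042/0.0050/0.0050 and slopes 0.080/0.050/0.010/0.040 for
  hip/vertebral/wrist/other — steep exponential age gradient for hip,
  nearly flat for wrist, as in observed female fracture epidemiology.
- **Utilities**: baseline 0.81 at 65 declining 0.004/year; first-year
  multipliers 0.70/0.80/0.95/0.91 and subsequent-year 0.90/0.95/1/1.
- **Risk modifiers**: osteoporosis RRs 2.0/2.0/1.4/1.5; hip
  excess-mortality RR 2.0.

Under these defaults the untreated high-risk 65-year-old's lifetime
hip-fracture risk is ≈44% (within the 40–75% plausibility band) and
the base-case ICER at the $20,161 teriparatide cost is far above
$150,000/QALY, so the model's qualitative conclusion holds end to end.
The generators emulate the *structure* of the real inputs (monotone
mortality, rising incidence, declining utility), not their values:
passing tests demonstrate correct model mechanics and internal
identities, not numeric fidelity of ICERs to the published base case,
which additionally depends on the unpublished appendix tables. The
drug-pricing arithmetic, by contrast, uses only printed primitives and
reproduces every printed dollar figure to within $1.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [0, 1] after multiplication; parameter
  validation additionally rejects any input set whose modified
  per-type incidence reaches 1 at any age.
- A zero washout window (no completed treatment years) means an
  immediate return to baseline risk.
- Flat persistence beyond month 12 means the inverse-CDF draw can only
  discontinue within the first year or complete the course.
- `ΔE = 0` yields an undefined-ICER signal rather than a division
  error; dominant/dominated labels replace the ratio when signs
  disagree.
- Uniform draws are pre-allocated per individual (2 persistence draws
  + 4 per cycle), making trajectories bit-reproducible given a seed
  and keeping common-random-number pairing exact across strategies.

## Problem sizes

The reference configuration is 100,000 individuals per strategy for
base cases and 1000 × 10,000 for PSA. The shipped defaults and
`scripts/acceptance.py` use reduced sizes chosen as the package's own
balance of precision and runtime: 20,000 individuals per strategy for
base-case ICERs and lifetime risks (Monte-Carlo SE on ΔE ≈ 0.002
QALYs with paired seeds), 3,000 per strategy per grid point for the
threshold search, and 150 × 1,000 for PSA acceptability estimates. All
sizes are arguments and can be raised to the reference values.

## Known limitations

- Adverse events, contraindications, patient time costs, future
  unrelated medical costs, and alternative comparators (denosumab,
  abaloparatide) are out of scope.
- The four-state labelling collapses vertebral vs wrist/other history
  into trackers; any behavioural distinction beyond utilities/costs
  encoded here is not represented.
- No within-year event timing; no switching or re-initiation after
  discontinuation; no time-varying generic price erosion.
- PSA samples parameters independently; correlated uncertainty (e.g.
  persistence with adherence) is not modelled beyond the monotonicity
  repair.
- Synthetic inputs make absolute cost/QALY levels and ICERs
  illustrative; only the pricing arithmetic and the model's internal
  identities are quantitatively faithful.
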