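# osteosim

Individual-level Markov (microsimulation) cost-effectiveness model
comparing **sequential teriparatide/alendronate** (daily s.c.
teriparatide for 2 years followed by weekly oral alendronate for 10
years) with **alendronate alone** (10 years) in community-dwelling
osteoporotic women with a prior vertebral fracture, including the
drug-pricing model for generic/biosimilar teriparatide scenarios,
deterministic and probabilistic sensitivity analyses, and
cost-effectiveness acceptability curves.

It is written for health-economics researchers and modellers who want
a tested, scriptable re-implementation of this class of analysis:
annual-cycle state-transition microsimulation with individual memory
(fracture trackers, treatment status), real-world persistence and
adherence, treatment offset (washout) effects, two costing
perspectives, and two-level probabilistic sensitivity analysis.

## The model in brief

Each woman is simulated one cycle (year) at a time from her start age
(65/70/75/80) until death or age 105. Per cycle, in order: a death
draw (with lifelong excess mortality after hip fracture, only 25% of
the excess attributed to the fracture, `q' = q·(1 + 0.25·(RR−1))`);
at most one fracture among {hip, clinical vertebral, wrist, other
osteoporotic} with `P(any) = 1 − Π_k(1 − p_k)` and the type chosen
proportional to `p_k`; tracker updates (maximum two hip fractures,
12% of hip fractures enter long-term care); and cost/utility accrual
discounted at 3%/year.

Per-type fracture probability is multiplicative:

```
p_k(age) = incidence_k(age) · RR_prior_vertebral,k · RR_osteoporosis,k · RR_treatment,k
```

Trial efficacy is attenuated for community adherence *a* against an
80% trial reference: `RR_community = 1 − min(1, a/0.8)·(1 − RR_trial)`
(so 60%/80% gives a scaling of 0.75). Each woman's discontinuation
time is drawn once per course by inverting the persistence curve
(observed at 12/24 months, linear to month 60, flat after); after
stopping, protection returns linearly to none over a washout window
proportional to the completed fraction of the course (10 years after a
full alendronate course, 1 year after the 2-year teriparatide course).

Drug costs are built from list-price primitives — e.g. annual brand
teriparatide `$27,618 = $3426.50 · 13 · 0.62` — blended by
generic/biosimilar market share (base case: 30% discount, 90% share,
giving `$20,161 = $19,332·0.9 + $27,618·0.1`) and charged
proportionally to adherence while persisting (first-year discontinuers
pay one 3-month fill). Costs carry a sector tag: long-term care and
unpaid lost productivity count only under the societal perspective.

Strategies are compared by the incremental cost-effectiveness ratio
(ICER, $/QALY); the PSA reports the probability of cost-effectiveness
at willingness-to-pay thresholds of $50,000/$100,000/$150,000 per QALY.

Age-indexed inputs (fracture incidence, baseline utilities, the life
table) and the osteoporosis risk modifiers ship as clearly-labelled
**synthetic** defaults generated by `osteosim.synthetic` — plausible
for a high-risk cohort but not published values. All printed-table
inputs (efficacy, persistence/adherence, unit costs, prior-vertebral
RRs, pricing primitives) are encoded verbatim.

## Worked example

```python
import osteosim as osm

model = osm.CostEffectivenessModel(start_age=65)
res = model.fit(n_individuals=20_000, seed=1)
print(res.summary().to_string(index=False))
icer = res.icer()
print(f"incremental cost  ${icer.delta_cost:,.0f}")
print(f"incremental QALYs {icer.delta_qaly:.4f}")
print(f"ICER              ${icer.icer:,.0f} per QALY")
```

prints

```
       perspective          strategy  cost  qaly      icer    se_cost  se_qaly     n
          societal alendronate_alone 29771  9.98 Reference 202.606199 0.025482 20000
          societal        sequential 42121  9.99   935,200 206.562185 0.025483 20000
health_care_sector alendronate_alone 22997  9.98 Reference 137.845007 0.025482 20000
health_care_sector        sequential 35466  9.99   944,200 144.976210 0.025483 20000
incremental cost  $12,350
incremental QALYs 0.0132
ICER              $935,197 per QALY
```

Reading the table: under the synthetic default inputs the sequential
strategy adds about $12,350 in discounted lifetime cost (mostly two
years of teriparatide at $20,161/year, prorated by adherence) and
about 0.013 QALYs, an ICER far above a $150,000/QALY willingness to
pay — the strategy is not cost-effective at the base-case teriparatide
price. `se_cost`/`se_qaly` are Monte-Carlo standard errors; seeds are
paired across strategies (common random numbers), so incremental
estimates are much more precise than the per-strategy errors suggest.

A command-line interface mirrors the library:

```bash
osteosim base-case --n 10000 --seed 1 --out results/
osteosim pricing-grid --out results/          # discount x share cost grid
osteosim threshold --wtp 150000 --out results/
osteosim psa --n-simulations 100 --n-trials 1000 --out results/
osteosim ceac --pairs results/psa_pairs.csv --out results/
```

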