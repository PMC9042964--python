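# osteocea

A lifetime Markov cohort cost-utility model for osteoporosis treatment
sequences in postmenopausal women at very high risk of fracture, from a
Canadian public-payer (optionally societal) perspective. It compares one year
of the bone-forming agent romosozumab sequenced to alendronate against
alendronate alone and risedronate alone (5 years of treatment in every arm),
and reports discounted costs, QALYs, fracture counts, incremental
cost-utility ratios, dominance, and net monetary benefit, with full
probabilistic, deterministic and scenario uncertainty analysis.

## The model

A cohort of women (mean age 74, femoral-neck T-score ≤ −2.5, prior fragility
fracture) moves through seven health states on a 6-month cycle: *at risk*,
*hip fracture*, *post-hip*, *clinical vertebral fracture*, *post-vertebral*,
*"other" fragility fracture*, and *dead*. States are ordered by severity
(hip > vertebral > other) and occupancy only moves toward equal-or-higher
severity; fractures of lower severity that the hierarchy cannot hold as
occupancy are counted by multiplying higher-state occupancy with the lower
type's incidence. Internally the hip and vertebral states carry 8-year
tunnels so mortality can depend on time since the event.

Key quantities, per cycle *j* of length 0.5 y:

- fracture hazard: `r_j(type) = r_gen(age_j, type) · RR_prior · RR_SD^gap · RR_j(treat, type)`,
  with per-cycle probability `1 − exp(−0.5 · Σr)` apportioned across
  competing exits;
- time-dependent efficacy: the sequence's RR versus its comparator is derived
  cycle-by-cycle from parametric survival fits per arm (family chosen by
  AIC; BIC and second-best-AIC as scenarios), anchored to placebo by the
  comparator's constant network-meta-analysis RR;
- offset: after treatment stops, the risk *reduction* wanes linearly to zero
  over the offset period, `rr_eff(t) = 1 − (1 − RR)·max(0, 1 − t/T_offset)`;
- excess mortality: `RR_eff = 1 + 0.3·(RR − 1)` on the hazard scale for 8
  years after hip/vertebral fracture (1 year after other);
- valuation: QALYs = occupancy × age-band utility × state multiplier × 0.5;
  costs cover drug acquisition, monitoring/administration, age-banded
  first-year and subsequent-year fracture costs, and long-term care (37% of
  hip-fracture survivors at $184.96/day); discounting at 1.5%/year;
- decision metrics: ICUR = ΔC/ΔQ, dominance labels, NMB(λ) = λ·ΔQ − ΔC, and
  CEACs over λ = 0–200,000 CAD/QALY from a 5000-iteration PSA.

Published point values from the source tables (per-cycle RR schedule,
anchored RRs with CIs, utilities, multipliers, unit costs) are embedded in
the bundled reference configuration. Inputs that exist only in appendix
tables — general-population fracture incidence, the life table, post-fracture
mortality RRs, risk-adjustment RRs, societal wage/time-off — are **synthetic
stand-ins**, generated by `osteocea.synthetic`, flagged in the configuration,
and watermarked in every report. Absolute outputs therefore characterise the
model mechanics, not any published cohort.

## Worked example

```python
from osteocea import MarkovCohortModel

model = MarkovCohortModel.reference_case()
res = model.fit()                       # deterministic point estimates
pw = res.pairwise("romosozumab/alendronate", "alendronate")
print(round(pw["delta_qalys"], 3), round(pw["delta_cost"]), pw["label"])
```

prints

```
0.133 -6457 dominant
```

— on the stand-in epidemiology the sequence gains 0.133 discounted QALYs and
saves $6,457 per person versus alendronate, so it *dominates* (more health,
less money); fewer hip and vertebral fractures more than pay for the higher
drug cost. `res.summary()` prints the full disaggregated table (fracture
counts per 1000, cost components, life-years, QALYs, incremental block) with
the stand-in watermark, and

```python
psa = model.fit(method="psa", n_iterations=5000, seed=1)
psa.ceac()                              # acceptability curves, lambda 0-200k
model.run_dsa()                         # one-way INMB tornado
model.run_scenarios()                   # the full scenario battery
```

run the probabilistic model, the tornado, and scenarios (alternative
sequence, societal perspective, 0%/3% discounting, BIC/second-AIC survival
selection, 1-year offset, altered excess-mortality assumptions, alternative
disutilities and risedronate price).

The same workflow is available from the shell:

```sh
osteocea fixture --out run.yaml
osteocea run run.yaml --mode psa --iterations 5000 --seed 1 --out results/
```

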