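# Methods

## Model structure

The model is a Markov cohort state-transition model with a 6-month cycle and
a lifetime horizon, following a closed cohort of postmenopausal women at very
high fracture risk (mean age 74, T-score ≤ −2.5, 50/50 single/multiple prior
fragility fracture). Seven reporting states — at risk, hip fracture,
post-hip, clinical vertebral fracture, post-vertebral, other fragility
fracture, dead — are expanded internally to 38 states: the hip and vertebral
branches carry half-year tunnel layers to a depth of 8 years (the acute
fracture state is the first two layers, i.e. exactly 1 year), followed by a
"late" post state with no residual excess mortality; the other-fracture state
lasts two cycles and returns to at-risk. Severity is ordered hip > vertebral
> other: hip-family states admit only hip re-fracture, vertebral-family
states admit hip or vertebral, at-risk and other-fracture states admit all
three. Re-fracture of an admissible type re-enters the acute state and resets
the tunnel clock.

Because the hierarchy cannot hold lower-severity events as occupancy, they
are counted separately: each cycle, hip-family occupancy × the standalone
per-cycle vertebral and other incidence, and vertebral-family occupancy × the
other incidence, are added to the fracture ledger. These corrected events
carry costs and a one-year disutility (spread pro-rata over two cycles) but
do not move occupancy. Whether they should also add excess mortality is not
determinate from the sources; the reference case says no, and a config switch
(`corrected_events_affect_mortality`) enables an expected-extra-hazard
approximation instead.

### Transition probabilities

All per-cycle probabilities are built on the hazard-rate scale. For a state
with admissible fracture rates `r_i` and death rate `m`, the total exit
probability is `1 − exp(−0.5·(Σr_i + m))`, apportioned to each exit in
proportion to its rate; the residual follows tunnel aging. This competing-risk
construction avoids order-of-application bias, keeps every row of the
transition matrix summing to 1 exactly, and makes mass conservation hold to
1e−12. There is no half-cycle correction in the reference case (a config
switch enables midpoint occupancy); accruals use start-of-cycle occupancy and
events are valued at the start of their cycle.

Baseline fracture rates come from age-indexed general-population tables
(linearly interpolated, linearly extrapolated, floored at 0), multiplied by a
prior-fracture RR and a per-SD-of-BMD RR raised to the T-score gap between
the cohort and the age-matched general population. Mortality converts the
life-table annual probability to a rate, applies the attributable
excess-mortality RR `1 + f·(RR − 1)` (f = 0.30) while the occupant is within
the excess window of its fracture type (8 years for hip/vertebral with
separate first-year and later-years RR bands, 1 year for other), and converts
back to a 6-month probability. The rate-scale application was chosen over the
probability scale (the sources do not say) because it cannot produce
probabilities above 1.

The cohort runs to age 100 and then closes out under mortality alone until
living occupancy falls below 1e−6 per 1000 or age 110.

## Treatment efficacy

Comparator regimens carry constant placebo-anchored RRs (with 95% CIs) for
the 5-year treatment period. The bone-forming sequence has time-dependent
efficacy: its per-cycle RR versus the active comparator (a published 10-cycle
schedule in the reference configuration) is multiplied by the comparator's
constant placebo-anchored RR. When the schedule is instead derived from
time-to-event data, parametric survival curves (exponential, Weibull,
Gompertz, log-logistic, log-normal; generalized gamma available on request)
are fitted per arm by maximum likelihood with right censoring, one family is
selected by AIC (BIC or the second-smallest AIC in scenarios; ties break to
fewer parameters, then name), and the per-cycle RR is the ratio of
conditional cycle incidences `(S(t_{j−1}) − S(t_j))/S(t_{j−1})`. Fits use a
single scipy-based likelihood machinery across all families, in years (cycle
boundaries are exact multiples of 0.5 y, so no unit conversion error arises);
the asymptotic covariance from a finite-difference Hessian feeds PSA
resampling of fit parameters. lifelines is used in the test suite as an
independent oracle for the Weibull/exponential fits and the Kaplan–Meier
convergence check. The vertebral schedule is never derived from fits (the
source analysis fitted curves only for hip and non-vertebral endpoints); it
is consumed as a step schedule.

After the 5-year treatment period the risk *reduction* wanes linearly:
`rr_eff(t) = 1 − (1 − RR_end)·max(0, 1 − t/T_offset)` with `T_offset` = the
treatment duration (5 years) in the reference case. The formula applies
equally when `RR_end > 1` (the late-cycle non-vertebral RRs exceed 1), pulling
the RR back to 1 over the offset.

## Valuation

QALYs: occupancy × age-band general-population utility × state multiplier ×
0.5 per cycle, with first-year multipliers (hip 0.55, vertebral 0.68, other
0.83) in the acute layers and subsequent-year multipliers (hip 0.86,
vertebral 0.85) in all later post layers, for life.

Costs (2020 CAD): drug acquisition and monitoring/administration accrue to
alive persons during the 10 treatment cycles at the published annual sums
(monitoring $310 for the injectable year, $119 for oral-bisphosphonate
years — the printed sums are taken verbatim rather than re-derived from the
fee schedule, whose biennial BMD item does not obviously reproduce them; the
$191 nurse-visit figure is likewise consumed as printed). First-year fracture
costs are age-banded and attach to events (direct and corrected), spread over
the two cycles of the first post-fracture year; subsequent-year costs accrue
to post-hip ($5,171/y) and post-vertebral ($235/y) occupancy. Long-term care
is a scalar side-stream rather than an extra state: 37% of hip-fracture
survivors × $184.96/day. Since every hip-family occupant has had at least one
hip fracture and shares the family's mortality, LTC occupancy equals the
entry fraction times hip-family occupancy; this reproduces the expected cost
without enlarging the state space. LTC adds to (rather than replaces)
post-hip medical cost by default; `ltc_additive=False` switches to
replacement for the LTC fraction. The societal perspective adds productivity
losses per event (hourly wage × type-specific time off) and a $20
out-of-pocket fee per scheduled visit.

Costs and QALYs are discounted at 1.5%/year, `(1+r)^{−t}` at start-of-cycle
times. Comparison is fully incremental: regimens ordered by QALYs, strictly
and extendedly dominated options labelled, ICURs on the efficiency frontier,
NMB at a reference λ of $50,000/QALY.

## Uncertainty analysis

PSA: independent joint draws per iteration — lognormal RRs with the point
estimate as the median (log-sd from the 95% CI where published, e.g. log-sd
= (ln 0.90 − ln 0.42)/3.92 ≈ 0.194 for the hip anchor; otherwise from a
±25% interval); beta for utilities, multipliers and proportions and gamma for
costs, both matched to the point estimate as mean with sd = 0.25·mean/1.96;
one lognormal multiplier per fracture type for the sequence's cycle schedule
(or normal resampling of survival-fit parameters when the schedule is
fit-derived). Drug list prices are fixed by default. The CEAC is the fraction
of iterations in which each regimen maximises NMB on a λ grid of 0–200,000
CAD in steps of 1,000, ties resolved toward the cheaper regimen. Headline
probabilistic results are means over iterations; deterministic results are
reported alongside. Identical (config, n, seed) runs are bit-identical.

DSA: one parameter at a time at its CI bounds or ±25%, INMB of the sequence
versus alendronate at $50,000/QALY (the λ is a package choice; the sources do
not state one), tornado ordered by bar width.

Scenarios re-run the model with named overrides: the
romosozumab-to-risedronate sequence (placebo-anchored efficacy equal to the
alendronate sequence during the two bone-forming cycles, thereafter the
vs-active schedule applied to the risedronate anchor), societal perspective,
0%/3% discounting, BIC and second-AIC survival selection (refitted on the
bundled synthetic trial data), a 1-year offset, excess-mortality duration
5/10 years, attributable fraction 10%/50%, hip-only first-year excess
mortality, an alternative disutility set (stand-in values), and risedronate
at $617/year.

## Synthetic stand-ins

Inputs that exist only in appendix tables or as patient-level trial data are
generated, seed-deterministically, by `osteocea.synthetic`, and flagged in
`standin_inputs` so every report watermarks them:

- fracture incidence: exponential age growth per type, anchored so crude
  rates are of the order of the published 16 fragility fractures per 1000
  persons 50+ per year (hip 0.3/1000 at 50, doubling every 6 y; vertebral
  1.5/1000, 10 y; other 5/1000, 16 y);
- mortality: Gompertz annual hazard 0.0015·e^(0.100·(age−50)), chosen to
  match Canadian female life-table magnitudes (≈0.017 at 74, ≈0.08 at 90);
- post-fracture mortality RRs: age-declining bands in the shape of published
  Canadian estimates (hip first year 6→2 across ages 50–100, later years
  2.2→1.4; vertebral 4→1.6 and 1.8→1.2; other first year 1.8→1.1);
- risk adjustment: prior-fracture RR 2.0 and per-SD BMD RRs 2.6/1.8/1.4
  (hip/vertebral/other) over a 1.0-SD T-score gap — literature-typical
  magnitudes, fixed once;
- trial records: two-arm Weibull time-to-first-event data with independent
  exponential plus administrative censoring, sized like a large fracture RCT
  (2046/arm, 3 y), generating parameters carried in metadata for recovery
  tests.

What passing tests show — and what they do not: the suite verifies the model
*mechanics* (mass conservation, hierarchy, oracle equivalence against a
200,000-individual microsimulation, parameter recovery, degenerate-limit
identities, seed reproducibility) and the embedded published point values.
Because the appendix epidemiology is replaced by stand-ins, absolute outputs
(total fractures ≈ 2,960/1000, total discounted cost ≈ $172k, ΔQALY ≈ 0.13
vs alendronate) are *not* reproductions of the published reference case
(2,561/1000, $86k, 0.103), and the acceptance test asserting the published
headline numbers fails by design under the stand-ins. The qualitative
result — the sequence dominates both comparators, and remains so across the
scenario battery except under short offset assumptions — is reproduced.

## Numerical choices and limitations

- Cohort size 1000; occupancy conserved to 1e−12 per cycle.
- The rate↔probability round trip is exact to 1e−12 for annual rates ≤ 2;
  for extreme rates (per-cycle probability → 1) float cancellation limits
  the inverse to ~1e−8 relative.
- Survival-fit optimisation: Nelder–Mead followed by BFGS polish from an
  exponential-consistent start; non-convergence raises an error naming the
  family. The generalized-gamma family is excluded from the default
  candidate set (flat likelihood at trial scale).
- Bundled script sizes are desk-scale package choices: 1000 PSA iterations
  in `scripts/acceptance.py`, 400 in the reproduction test, 200,000
  microsimulated individuals in the oracle check.
- No persistence modelling (full 5-year persistence assumed), no wholesaler
  or dispensing fees, no male/mixed-sex population, no secular mortality
  trends, no EVPI, no parameter correlation beyond joint survival-fit
  resampling, no recency-of-fracture risk stratification.
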