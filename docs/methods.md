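# Methods

This note documents the model, its assumptions, the places where the
published analysis left the design open, and what the test suite does and
does not establish. It states no empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Model structure and time conventions

Eight mutually exclusive health states: active disease, complete remission
(CR), partial remission (PR), relapse, hemodialysis (HD), peritoneal
dialysis (PD), kidney transplant (KT), death (absorbing). The cohort starts
with all mass in active disease.

Time is discretised into 30-day cycles, 12 per model year (a 360-day model
year, so annual rates and cycles align exactly; the ≈1.4% calendar
shortfall is negligible at a 5-year horizon, the configurable maximum).
Costs and QALYs are discounted at 5%/year, applied per cycle as
`(1.05)^(−t/12)` for accrual in cycle `t` (so a unit cost at cycle 12 is
worth exactly 1/1.05). State membership is valued at cycle start; there is
no half-cycle correction by default (`half_cycle_correction` switches to
averaging start/end occupancy). With 30-day cycles the correction shifts
cumulative QALYs by well under one cycle's accrual and no published value
depends on it.

## Transition probabilities

Annual probabilities convert to per-cycle values by constant-hazard
compounding, `p_c = 1 − (1 − p_a)^{1/m}`; the 10-year post-transplant
mortality (0.425) is first reduced to an annual probability the same way
(no time-varying hazard is published).

Downstream wiring: HD↔PD switching (0.1633, 0.0032/yr), transplantation
from either dialysis modality (0.0794/yr), dialysis mortality (0.0422,
0.0388/yr), and dialysis entry (HD 0.0002, PD 0.00003/yr) from the active
and relapse states only — progression to end-stage disease is modelled from
sustained active disease, not from remission. The aggregate "dialysis
incidence" input (0.0002/yr) is loaded but unused; the modality-split
entries carry the information. No background mortality is applied outside
the dialysis/transplant states: the source populations are young-to-middle
aged and the horizon is five years, so all-cause mortality is second-order
against the modelled hazards.

**Remission calibration (the main closure).** The per-cycle active→CR and
active→PR probabilities, and the remission→relapse hazard, were never
published. They are recovered from each arm's 12-month outcome proportions:
the relapse hazard by scalar constant-hazard inversion of the 12-month
relapse proportion, and the two competing remission probabilities by a
vectorised Newton solve so that CR and PR occupancy of the **full**
eight-state matrix after 12 cycles matches the published proportions to
1e-6. The relapse row reuses the active-disease row (relapsed patients are
re-treated and can re-remit); all calibrated probabilities are held constant
beyond month 12 — the minimal-assumption constant-hazard closure.

The 12-month classes are stored exclusively: for the comparator arm the
published CR count (8/35) consists entirely of patients who subsequently
relapsed, so the registry keeps CR = 0 with a `relapse_within_cr` flag and
reconstructs the published marginal (8/35) for calibration and tables. For
the RTX arm the published counts (34 CR, 12 PR, 5 NR, 2 relapse of 53) are
already exclusive.

## Utilities

CR/PR 0.86, active disease 0.738, HD 0.68, PD 0.71, KT 0.82, death 0. The
relapse state has no published utility; it defaults to the active-disease
value 0.738 (configurable via `utility.relapse`), since a relapse is a
return to nephrotic-range disease. The published "end-stage kidney disease"
and "conservative treatment" utilities correspond to no model state and are
loaded but unused.

## Cost schedules

All costs in ¥ at the study price year; no inflation or currency
adjustment.

**Both arms:** HD ¥40,678/yr, PD ¥31,145/yr and KT ¥10,278.8/yr as per-cycle
state costs (annual/12); evaluation visits at months 1, 3, 6, 9, 12
(urinalysis 47 + rapid proteinuria 44 + quantitative proteinuria 9 + liver
function 55 = ¥155/visit, charged to the surviving fraction).

**RTX:** 375 mg/m² weekly × 4 per induction course; with the default body
surface area 1.73 m² a dose is 648.75 mg, dispensed as 7 whole 100 mg vials
(¥1,366.2 each), so one course costs 4 × 7 × 1,366.2 = ¥38,253.6, charged
across cycles 1–2. A second full course is charged at cycle 6, weighted by
the cohort fraction then in PR (the published re-treatment rule: ≥25%
proteinuria reduction without CR at month 6). Expected adverse-event cost
(Σ incidence × cost over rash/fever/GI infection/pneumonia ≈ ¥150.20) is
charged once per course with the same weights. BSA, vial size, doses per
course and the course cycles are all configuration knobs.

**TAC:** the published six-month drug costs are spread uniformly per cycle
and attached to states — ¥9,976/6 mo for CR/PR occupancy, ¥10,626/6 mo for
active/relapse occupancy — and accrue over the whole horizon
(`tac_drug_duration_cycles: null`); setting the knob to 12 confines them to
the first year. The whole-horizon default reads the regimen as long-course
maintenance, consistent with the published analysis's persistent yearly
comparator costs. Methylprednisolone (¥0.878 per 4 mg tablet ≡ 5 mg
prednisolone) follows the published taper — 0.5 mg/kg/day (60 kg default)
for 8 weeks, −5 mg/day every 4 weeks to a 10 mg/day maintenance dose —
through month 12. The expected adverse-event cost (severe pneumonia costed
as pneumonia, lung abscess, interstitial pneumonia, hyperglycemia ≈
¥1,248.37) is charged once at cycle 1.

**What this reproduces and what it cannot.** The published year-by-year
cost table and the exact ICER (¥124,631.14/QALY) depend on per-cycle
treatment-cost assumptions that were never printed and are not recoverable;
no parameterisation of the printed inputs was found that reproduces
near-equal ¥31–39k/yr accruals in *both* arms across all five years. This
package's schedule reproduces the decision (RTX cost-effective at
¥257,094/QALY), QALY totals within ~1% of the published ones, and the
monotone rise of the acceptability curve with horizon — but at five years
it makes RTX *dominant* (cheaper and more effective) rather than ¥7,341
costlier, because the comparator keeps accruing drug costs after the RTX
courses end. The published worked example is therefore kept as a separate
arithmetic fixture on the printed cumulative values.

## Distribution fitting and sensitivity analyses

Published ranges are read as 95% intervals: `sd = (high − low)/3.92`. Beta
parameters by moments (`α+β = m(1−m)/v − 1`) for probabilities, utilities
and incidences; Gamma (`shape = (m/sd)², scale = v/m`) for costs. Every
fitted distribution's analytic mean equals the published mean to 1e-6
relative. Inputs without a published range (the annual dialysis rates, WTP,
discount rate) get a ±20% band for one-way analysis and are held fixed in
PSA — the published text says ranges came from confidence intervals but
does not print them.

**One-way (tornado):** each parameter with a usable range is set to its low
and high bound with all others at their means, the full pipeline is rerun,
and the signed ΔC/ΔE ratio recorded; entries are sorted by span.

**PSA:** every non-fixed parameter is drawn jointly and independently
(no correlation structure is published). The six 12-month outcome
proportions are themselves sampled from Beta fits of their Wilson 95%
binomial intervals (counts 34/53, 12/53, 2/53, 8/35, 17/35, 8/35) and the
remission dynamics recalibrated per draw. Draws whose sampled CR+PR targets
exceed what any stochastic transition row can reach — including the cap
imposed by a large sampled relapse hazard — are rejected and resampled with
the count reported (≈8% at the default distributions). The CEAC point per
horizon is the fraction of draws with higher net monetary benefit for RTX
at ¥257,094/QALY. Runs are bit-exact reproducible for a fixed seed and
iteration count; the default iteration count is 100,000 (CLI
`--iterations`), while the acceptance script and tests use 10,000 for
desk-scale runtime.

**Chi-square tests.** 2×2 Pearson tests with one degree of freedom, closed
form, with the Yates continuity correction `(|ad−bc| − N/2)²`. The API
default `auto` applies the correction when any expected cell count is below
5. The published p-values mix conventions (relapse 0.016 and overall 0.131
are Yates-corrected; PR 0.011 and NR 0.019 are uncorrected), so the
published-table reproduction records an explicit per-row mode
(`PUBLISHED_TEST_MODES`) rather than inventing a single rule the original
analysis did not follow.

## Synthetic cohort generator

Emulates the hospital-information-system extract: per patient an arm, age
(truncated normal at the published arm means/SDs), sex, onset time,
a 12-month outcome class (multinomial at the published proportions),
semicolon-separated adverse events (independent Bernoulli at the published
incidences), and per-visit proteinuria at months 0–12. Trajectories are a
log-linear decline to a class-dependent endpoint (relapse: nadir at month 6
then rebound) with lognormal noise — they make the record format realistic
but classification thresholds are *not* re-derived from them, and they are
never used as evidence. `fixture` mode emits exactly the published counts
with no sampling. Adverse events are drawn independently of outcome class
(no joint structure is published). Generation is byte-for-byte reproducible
per seed.

Because the generator emulates only the marginal structure the analysis
consumes (class frequencies, AE incidences, covariate moments), passing
tests establish the pipeline's correctness on data *with that structure* —
not calibration against real PMN cohorts, real proteinuria kinetics, or any
outcome–AE dependence.

## Numerical choices and edge cases

- Calibration: Newton with finite-difference Jacobian (ε = 1e-8), iterates
  clamped so the active row stays stochastic (margin 1e-6 > ε), residual
  tolerance 1e-10 with a hard 1e-6 acceptance bound; infeasible targets
  raise, or are masked for the PSA rejection loop.
- Transition rows whose exits exceed 1 raise a named error; residual mass
  is assigned to "stay", never silently rescaled.
- ICER sign patterns: dominant / dominated / indifferent flags instead of a
  meaningless ratio; the NMB rule decides cost-effectiveness in all cases.
- Degenerate inputs: empty AE profiles cost 0; empty arms yield NaN rates;
  a single-patient cohort estimates with a maximal-width Wilson interval;
  zero-margin 2×2 tables are rejected as undefined.

## Problem sizes used in tests and acceptance

Property tests run 1,000 random joint parameter sets for trace
conservation, a 10⁶-patient microsimulation oracle on a three-state toy
chain (3 standard-error agreement), 10⁵ marginal draws for PSA sample-mean
checks, 10⁴ full PSA draws for the CEAC-by-horizon trend, and 500 replicate
cohorts for the 95%-CI coverage (≥93%) of the generator's parameter
recovery at the published arm sizes; recovery accuracy is checked at 5,000
patients per arm (±2 percentage points).

## Known limitations

- The published cost trajectory and exact ICER are not reproducible from
  printed inputs (see above); the cost schedule is the package's own
  documented closure.
- Constant per-cycle hazards throughout; no time-varying treatment effect
  beyond the cost schedule's phase structure, no patient-level
  microsimulation in the pipeline (it exists only as a test oracle).
- Two-strategy comparison only; no efficiency frontier, no EVPI, no
  scenario analysis beyond one-way DSA and PSA.
- No currency conversion, inflation adjustment, or societal costs.
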