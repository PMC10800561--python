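# mncea — cost-effectiveness of rituximab vs tacrolimus in membranous nephropathy

`mncea` is a pharmacoeconomic analysis pipeline for comparing rituximab (RTX)
against a tacrolimus + prednisolone regimen (TAC) in primary membranous
nephropathy (PMN), from the perspective of the Chinese health system. It is
aimed at health-economics and nephrology researchers who want a tested,
scriptable re-implementation of the published TreeAge-style analysis: the
clinical efficacy/safety statistics, the Markov cohort model, and both
deterministic and probabilistic sensitivity analyses, driven entirely by the
published input-parameter table plus a synthetic patient-cohort generator
standing in for the hospital records.

## The model

An eight-state Markov cohort model with 30-day cycles (12 per model year):

> active disease → {complete remission (CR), partial remission (PR)} →
> relapse → … → hemodialysis / peritoneal dialysis / kidney transplant →
> death (absorbing)

Everyone enters in active disease. Annual transition probabilities `p_a` are
converted to per-cycle values by constant-hazard compounding,
`p_c = 1 − (1 − p_a)^{1/12}`. The unprinted remission dynamics are calibrated
so that 12-cycle cohort occupancy of CR and PR matches each arm's published
12-month outcome proportions, with the remission→relapse hazard obtained by
the same inversion from the published relapse rate.

Per cycle `t`, with occupancy vector `x_t` (valued at cycle start), utilities
`u`, and cost rate `c_t`:

- QALY accrual: `x_t·u / 12`, discounted by `(1+r)^{−t/12}`, `r = 0.05`
- cost accrual: dialysis/transplant state costs + the arm's drug, monitoring
  and expected adverse-event schedule, discounted identically
- outcomes: cumulative discounted cost `C` and QALYs `E` per arm,
  `ICER = ΔC/ΔE`, net monetary benefit `NMB = λ·E − C` at the
  willingness-to-pay threshold `λ = 3 × GDP per capita = ¥257,094/QALY`

Uncertain inputs carry Beta (probabilities, utilities, incidences) or Gamma
(costs) distributions fitted by moments from the published mean and range
(read as a 95% interval). Probabilistic sensitivity analysis samples all of
them jointly and independently, recalibrates the transition dynamics per
draw, and summarises the incremental cloud as cost-effectiveness
acceptability curves (CEAC) over 1–5-year horizons.

## Worked example

```sh
mncea --seed 1 --out-dir out run-base
```

prints (5-year horizon, default configuration):

```
delta cost = -48,192 CNY, delta QALY = 0.071, ICER = nan (dominant), cost-effective at WTP 257,094: True
```

RTX accrues 3.738 discounted QALYs over five years against 3.648 for TAC
(ΔQALY = +0.071): faster, deeper remission and a fivefold lower relapse rate.
Under the package's cost schedule — RTX charged as induction courses
(4 × 375 mg/m², whole 100 mg vials, a second course for the fraction still in
partial remission at month 6) versus state-dependent TAC drug costs accruing
while treatment continues — RTX is *dominant* at five years (cheaper and more
effective), hence trivially below the WTP threshold. At a 1-year horizon RTX
is costlier for a small QALY gain and is not cost-effective; the probability
of cost-effectiveness therefore rises steeply with horizon:

```sh
mncea --seed 1 --out-dir out psa --iterations 10000
 horizon      wtp  probability
       1 257094.0       0.0511
       2 257094.0       0.5866
       3 257094.0       0.7908
       4 257094.0       0.8510
       5 257094.0       0.8759
```

mirroring the monotone published sequence (46.9% → 80.6%). Applying the
ICER formula to the published year-5 cumulative table itself gives
ΔC = ¥7,341, ΔE = 0.058, ICER ≈ ¥126.6k/QALY < ¥257,094/QALY — the same
decision. The published cost trajectory depends on per-cycle treatment-cost
assumptions that were never printed; see `docs/methods.md` for what is and
is not reproducible.

Other entry points: `mncea tornado` (one-way sensitivity),
`mncea clinical-stats` (efficacy/safety tables with chi-square tests),
`mncea synth` (synthetic cohort + parameter recovery), and
`mncea reproduce-all` (everything, one manifest).

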