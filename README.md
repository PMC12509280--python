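# capscreen

Microsimulation and cost-effectiveness analysis of colorectal cancer (CRC)
screening strategies, built around colon capsule endoscopy (CCE) as a
primary test, a triage test after an intermediate stool-test result, and a
follow-up test after a positive stool test — compared against biennial
faecal immunochemical testing (FIT) and 10-yearly colonoscopy.

The package is aimed at health-economic modellers and screening-programme
analysts who want a transparent, fully tested re-implementation of this
kind of evaluation: every stage — natural history, test application,
screening pathways, discounting, dominance analysis, probabilistic
sensitivity analysis — is an importable, individually tested component.

## The model

**Natural history.** Each simulated person may develop adenomas according
to an age-dependent onset hazard λ(a) (piecewise constant over 10-year
bands). A lesion progresses small (≤5 mm) → medium (6–9 mm) → large
(≥10 mm) with exponential sojourn times, may transform into preclinical
cancer, and then progresses through stages I–IV while a per-stage hazard
of symptomatic presentation competes with progression. After diagnosis,
CRC survival is exponential with a stage-specific mean, competing with
other-cause mortality from a life table. Two free scale parameters — an
onset multiplier and a CRC death-hazard multiplier — are calibrated so
that the unscreened cohort reproduces a lifetime CRC incidence of 79 and
mortality of 36 per 1000.

**Screening.** Eight strategies invite from age 55 to 75: biennial FIT at
cutoffs 47 and 15 µg Hb/g, biennial and triennial CCE, CCE triage of the
15–47 µg Hb/g band, CCE after a positive FIT at either cutoff, and
10-yearly colonoscopy. Test sensitivity is per lesion class; endoscopic
reach is interpolated piecewise-linearly along the instrument's travel
order (capsule: cecum → rectum; colonoscope: rectum → cecum). Positive
findings are verified by colonoscopy, which removes adenomas and triggers
the surveillance pathway. All randomness is keyed by
(person, age, channel), so strategies are compared on *common random
numbers* — paired differences are nearly free of Monte-Carlo noise.

**Economics.** Outcomes are discounted at 3% to the first invitation age:
life years, QALYs (life years minus per-event and per-disease-phase
utility decrements), and healthcare costs (unit costs per test, and
phase-of-care treatment costs: initial year, ongoing years, terminal year
by cause of death; EUR 2018). Strategies are classified by strong and
extended dominance; the efficient frontier carries incremental
cost-effectiveness ratios (ICERs), and the optimal strategy is the
frontier member with the highest ICER under the willingness-to-pay
threshold (€20 000/QALY). A probabilistic sensitivity analysis draws all
unit costs from gamma distributions (method of moments, 95% CI = half to
double the mean), and a threshold search locates the capsule unit cost at
which a CCE strategy becomes cost effective.

## Worked example

```python
from capscreen import ScreeningCEAModel

model = ScreeningCEAModel()          # 8 strategies, 100% adherence
results = model.fit(n=200_000, calibration_size=100_000, seed=1)
print(results.summary())
```

prints (abridged):

```
Natural-history calibration
===============================================
incidence /1000 (target)                   79.0
incidence /1000 (achieved)                79.60  (MC se 0.61)
mortality /1000 (target)                   36.0
mortality /1000 (achieved)                36.29  (MC se 0.42)
===============================================

                 life_years  qalys  ly_gained  qaly_gained     cost  cost_per_qaly
biennial_fit15        70778  70751        129          160  1231548          17.41
biennial_fit47        70764  70734        115          142  1301506          18.40
cce_triage            70772  70743        123          152  1409115          19.92
...
biennial_cce          70786  70752        136          161  5775524          81.63

Efficient frontier: biennial_fit15 -> colonoscopy_10y
Optimal at WTP: biennial_fit15
```

Reading the table: per 1000 simulated persons, biennial FIT15 gains 129
discounted life years and 160 QALYs over no screening while *saving*
money (screening averts expensive late-stage cancer care); biennial CCE
gains a similar amount but at €5.8M per 1000 because of the €600 capsule
and its false-positive colonoscopies, so every capsule strategy is
dominated. `results.frontier()`, `results.run_psa()`,
`results.cce_cost_threshold()` and `results.reductions()` expose the
decision analyses; `capscreen report config.yaml` drives the same
pipeline from a YAML configuration on the command line.

The published base-case outcome table for the Dutch setting ships in
`capscreen.reference_tables` and feeds the decision arithmetic directly:
applying `efficient_frontier` to it reproduces the published conclusion —
frontier {FIT47, FIT15, 10-yearly colonoscopy}, every capsule strategy
dominated, colonoscopy ICER ≈ €10.3k/QALY and therefore optimal at the
€20 000 threshold.

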