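# Methods

## Disease model

The natural history follows the adenoma–carcinoma sequence. For each
person, adenomas arise as a Poisson process with a piecewise-constant
hazard over 10-year age bands (zero before age 20, rising to about
1.5%/year in old age before calibration scaling). Each lesion is assigned
a colorectal segment from a fixed distribution over six locations
(rectum, rectosigmoid, sigmoid, descending, transverse,
ascending+cecum). Progression small→medium→large adenoma and
large→preclinical stage I uses independent exponential sojourns; within
each preclinical stage an exponential symptomatic-presentation hazard
competes with exponential progression to the next stage, so cancers can
surface clinically at any stage. Stage IV does not progress further and
is eventually detected if the person lives long enough.

Survival after diagnosis is exponential with a stage-specific mean (150,
60, 25 and 2 years before calibration). The long early-stage means act
as a cure-fraction proxy: most stage I–II patients die of other causes
first, which reproduces realistic stage-specific case fatality without an
explicit cure parameter. Other-cause mortality comes from a synthetic
Gompertz–Makeham life table (`LifeTable.gompertz_makeham`, hazard
A + B·cˣ with A = 4·10⁻⁴, B = 2.7·10⁻⁵, c = 1.098; life expectancy
≈ 80 years), configurable via YAML.

Default hazards encode round-number dwell times — mean 17 y small→medium,
14 y medium→large, 20 y large→cancer, and a mean preclinical sojourn of
roughly 4–5 years — chosen once as representative of slow adenoma
pathways; their absolute level is then calibrated.

### Latent-trajectory representation and replay

All event times of a life history are materialised up front from
counter-based uniforms (splitmix64) keyed by (seed, person, lesion,
channel). Consequences:

* simulating person *i* is independent of cohort size or chunking
  (partition invariance);
* a history can be *replayed* under interventions: removing an adenoma at
  polypectomy deletes its downstream cancer, and a screen-detected cancer
  re-uses the lesion's survival uniform at the earlier stage, so the
  benefit of stage shift is evaluated on the same underlying randomness;
* two strategies evaluated with the same seed share participation,
  test-result and reach draws wherever their pathways coincide (common
  random numbers), making paired comparisons nearly noise-free.

### Calibration

Two scalars are fitted: a multiplier on the onset hazard (drives
incidence) and a multiplier on the CRC death hazard (drives case
fatality). Phase 1 runs a damped fixed-point iteration on the log scales
with one fixed simulation seed until lifetime incidence and mortality per
1000 are within tolerance (default 2%) of the targets (79 and 36).
Phase 2 polishes with four further damped updates under fresh seeds and
averages the log-scale iterates, which removes most of the Monte-Carlo
realisation bias of the phase-1 seed; the reported achieved values come
from a fresh-seed evaluation at twice the fitting size. Calibrating on
2·10⁵ persons reproduces the targets within 2% on an independent
10⁶-person cohort across seeds. Non-convergence raises with the full
iteration trace attached.

## Screening tests

Sensitivity is per lesion class (small/medium/large adenoma, early/late
preclinical cancer); small adenomas are invisible to the stool and
capsule tests. Preclinical cancer counts as "late" for FIT when its
simulated clinical surfacing lies within 5 years (configurable horizon),
reflecting the rising probability of bleeding as diagnosis approaches.

The two FIT cutoffs are evaluated with one nested latent draw per screen:
a per-lesion uniform compared against the 15- and 47-cutoff
sensitivities, so positivity at 47 implies positivity at 15, and the
15–47 band is their difference. Background (non-neoplastic) bleeding —
the 1 − specificity channel — determines the result only when the person
has no FIT-detectable lesion; with this convention the band probability
for a person with one large adenoma is exactly 0.550 − 0.368 and the
false-positive rate for people with at most small adenomas is exactly
1 − specificity. False positives are redrawn each round (no persistent
bleeders).

Endoscopic reach uses one uniform per procedure: the instrument
visualises a prefix of its travel order, a segment being reached exactly
when the uniform is below its (monotone non-increasing) reach
probability. Unanchored segments are interpolated linearly by ordinal
position between anchors — e.g. for the capsule, sigmoid 0.814 and
rectosigmoid 0.686 between descending (0.942) and rectum (0.558).
Perforation risk (10⁻⁵ per colonoscopy) applies to every colonoscopy;
complications are modelled as costly and quality-of-life reducing but not
fatal.

## Strategy pathways

Invitations run from 55 to 75 at the strategy interval; participation is
an independent Bernoulli per invitation at the modality's adherence rate,
while diagnostic follow-up and surveillance are always attended.
Colonoscopy removes all detected adenomas (one polypectomy charge per
procedure with ≥1 removal) and diagnoses detected cancers at their
current stage. Pathway rules:

* positive FIT at the operative cutoff → colonoscopy; in the triage
  strategy, ≥47 → colonoscopy and 15–47 → CCE; in the follow-up
  strategies a positive FIT → CCE;
* CCE finding of a large adenoma or cancer (or a false-positive
  suspicion) → colonoscopy; a medium adenoma → repeat CCE after 3 years;
  negative primary CCE → re-invitation after 10 years;
* in the *biennial* CCE strategy both capsule intervals collapse to the
  2-year round — with a 10-year negative interval the biennial and
  triennial capsule strategies would consume nearly identical numbers of
  capsules, contradicting the published ~4:1 ratio of capsule counts;
* medium/large adenoma removed at colonoscopy → surveillance colonoscopy
  after 5 years; negative endoscopy (or small adenomas only) → return to
  the routine schedule no earlier than 10 years later; surveillance may
  cross age 75 once;
* a negative triage/follow-up CCE returns the person to the routine
  schedule (the dedicated triage pathway figure is not public; FIT
  consumption in the published triage arm is close to the plain FIT arms,
  implying no long FIT holiday);
* after any CRC diagnosis the person leaves the programme; subsequent
  care is captured by phase-of-care costs.

## Economics

Discounting is 3%/year relative to age 55 for every arm, with years
before 55 undiscounted; the reference point is a convention and cancels
from all incremental quantities. Life years are integrated continuously;
QALYs subtract per-event decrements (FIT positive/negative, CCE
finding/negative, colonoscopy, perforation) and per-phase annual
decrements keyed to stage. Care years are walked as whole years from
diagnosis: year 0 is the initial phase, the last year is terminal
(cause-of-death specific), intermediate years are ongoing; when diagnosis
and death fall within the same year the terminal phase takes precedence.
The terminal utility decrement and the ongoing phase scale with the
fraction of the year actually lived; initial and terminal *costs* are
lump sums. In the triage strategy a 15–47 band result carries the
"positive FIT" decrement, since the person is referred onward.

The frontier computation removes strong dominance, then extended
dominance while building the convex hull in QALY order, leaving strictly
increasing ICERs; exact ties merge onto one representative
(lowest name) so classification is invariant to input order. The optimal
strategy is the frontier member with the highest ICER not exceeding the
willingness-to-pay, defaulting to the cheapest member.

The PSA freezes each strategy's discounted *counts* of every cost item
(tests, polypectomies, perforations, phase-of-care years by stage and
cause) and re-prices them under 1000 independent gamma draws per item
(k = µ²/σ², θ = σ²/µ, with σ = (2µ − µ/2)/3.92 from the half/double 95%
interval). The threshold search bisects the capsule unit cost (to €0.5)
at which a capsule strategy joins the frontier or becomes optimal,
spot-checking monotonicity of the criterion on the bracket.

## Problem sizes

Defaults chosen for desk-scale reproducibility: calibration on 2·10⁵
persons, strategy evaluation on 2–4·10⁵, verification on 10⁶ (the
original evaluation used 10⁸). Per-1000 normalisation makes results
scale-free up to Monte-Carlo error, which is reported as binomial
standard errors alongside the calibration summary.

## What the synthetic generator does and does not emulate

The generator reproduces the published no-screening aggregates, the state
structure (three adenoma sizes, four preclinical stages, six segments),
and competing mortality. It does **not** reproduce the original model's
proprietary calibrated parameter set: age-, stage- and location-specific
incidence, adenoma multiplicity clustering (no frailty term — adenomas
arise independently), sex differences, or the serrated pathway.
Consequently absolute strategy outcomes (test counts, per-strategy case
counts, total costs) differ from the published tables, and screening
appears *more* effective here than in the published setting — the
simulated reductions are larger and closer together across strategies,
and at desk scale the FIT15 arm reaches the frontier ahead of
colonoscopy. Tests therefore pin (a) exact arithmetic on published
quantities, (b) calibration targets, and (c) structural/ordering
properties (dominance of more-sensitive cutoffs, demand orderings,
QALY-gain > LY-gain direction) rather than absolute counts.

## Known limitations

* Exponential dwell times have no age dependence beyond onset; no
  adenoma-multiplicity frailty.
* CCE specificity and reach are applied independently; incomplete
  capsule excretion is folded into reach.
* Complications are never fatal; only colonoscopy carries procedural
  risk.
* Persistent non-attenders are not modelled (participation is
  independent per round).
* In this model's calibrated world, biennial CCE remains dominated at
  every capsule unit price because of its false-positive colonoscopy
  burden; the capsule-cost threshold therefore exists only for the triage
  strategy at desk scale.
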