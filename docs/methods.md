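# Methods

## Model

`crcsim` simulates individual life histories through the
adenoma-carcinoma sequence on annual cycles from age 40 until death or
age 80.  Seven health conditions are tracked with eight runtime codes:
no colorectal lesion, non-advanced adenoma (NAA), advanced adenoma
(AA, ≥10 mm or high-grade dysplasia or villous component), preclinical
(asymptomatic, screen-detectable) cancer, diagnosed cancer split by
detection mode (screen-detected vs symptom-detected), cancer death and
other-cause death.

Assumptions:

1. without intervention, states only progress, one step per cycle at
   most, in the severity order above;
2. preclinical cancer left unscreened eventually surfaces as
   symptom-detected cancer;
3. a colonoscopy (primary or after referral) removes adenomas found
   (state returns to lesion-free) and converts preclinical cancer into
   screen-detected cancer; these are the only two edits screening makes;
4. cancer-specific death applies only to diagnosed individuals, with an
   annual probability `q_j` depending on the year `j` since diagnosis;
5. a diagnosed individual alive more than 5 years after diagnosis is a
   *survivor*: no further cancer-specific hazard (cure assumption).

Each individual carries exactly one state per cycle (a single-lesion
model: the most severe lesion defines the state).

### Cycle order

Within one annual cycle the engine applies, in this order: scheduled
screening, natural progression, the cancer-death draw, the
other-cause-death draw, then the birthday.  The order is a modelling
choice: placing screening first means a lesion found and removed cannot
also progress within the same cycle, which is the intended reading of a
"detect and remove" intervention on an annual grid.  A cancer detected
by screening in a cycle is exposed to that cycle's first-year death
probability, exactly as a symptom-detected cancer would be.

### Mortality

Non-cancer death uses the competing-risk decomposition
`P = 1 − exp(−(P_all − P_CRC))` applied to a sex/age life table, which
keeps the result a valid probability for any consistent table
(`P_CRC ≤ P_all ≤ 1` is enforced at load time).

The five annual cancer-death probabilities `q1..q5` are estimated in a
source population whose 5-year survival differs from the modelled one.
They are rescaled by the proportional-hazards factor
`k = ln(S5_target)/ln(S5_source)` applied per year as
`q' = 1 − (1−q)^k`.  This transform is exactly "multiply the discrete
hazard by k": it preserves [0, 1], is the identity at `k = 1`, and
reproduces the target 5-year survival to machine precision whenever the
unadjusted profile implies the source survival (the default profile
fixes `q5` so this holds by construction).  With the default pair
(0.622 source, 0.527 target) the factor is `k = 1.3491`.

Screen-detected cancers receive an additional hazard multiplier
(default 0.7, configurable).  The natural-history literature the model
draws on distinguishes the two diagnosed states without quantifying a
survival difference; a multiplicative hazard advantage for earlier
detection is the simplest mechanism that lets the mortality benefit of
screening exceed its incidence benefit, and 0.7 produces a
mortality-vs-incidence hazard-ratio gap of the size seen in screening
trials.  Setting it to 1 disables the distinction.

## Screening

Three tests are modelled, each with per-lesion-class sensitivity and a
specificity against a lesion-free colon:

| test          | NAA  | AA   | cancer | specificity | defaults from |
|---------------|------|------|--------|-------------|----------------|
| FIT           | 0.05 | 0.26 | 0.76   | 0.95        | published stool-test accuracy studies |
| sigmoidoscopy | 0.59 | 0.59 | 0.61   | 0.92        | published endoscopy meta-analysis     |
| colonoscopy   | 0.95 | 0.95 | 0.95   | 1.0         | near-perfect reference standard       |

Pathways: a positive FIT leads to a diagnostic colonoscopy with
probability 0.76 (referral completion); a positive FIT whose referral
is missed is not tracked further.  A sigmoidoscopy removes NAA on the
spot; AA or cancer findings trigger a colonoscopy referral completed
with probability 0.96.  A *negative primary* screening colonoscopy
defers further scheduled colonoscopies for 10 years (guideline rescreen
interval); diagnostic colonoscopies do not reschedule anything.

Participation defaults: 0.94 per FIT offer and 0.425 per primary
colonoscopy offer (real-world programme rates).  Two participation
models are exposed: an independent Bernoulli draw per offer
(`per_round`, the default) and a single lifetime attender draw per test
type (`ever_attender`); the choice matters most for repeat-colonoscopy
strategies, and programme data to pick one is thin, so both remain
available.

The eight standard comparison strategies: (1) no screening; (2) annual
FIT at 50–69; (3) biennial FIT at 50–69; (4) annual FIT at 50–54;
(5) FITs at 50, 52, 54; (6) annual FIT 50–54 plus colonoscopy at 55 and
65; (7) FITs at 50, 52, 54 plus colonoscopy at 55 and 65;
(8) colonoscopy at 50 and 60.

## Random numbers and reproducibility

Every draw comes from a counter-based stream keyed by
`(seed, purpose, cycle)` with one uniform per cohort position, rather
than one sequential stream per individual.  Consequences: results are
bit-reproducible and independent of iteration order, and two strategies
run under the same seed share every natural-history and screening
random number — *common random numbers* — so between-scenario
differences are attributable to the intervention.  With participation
forced to zero, any strategy reproduces the no-screening run bit for
bit; the test suite asserts this.

## Person-years

Individuals alive through a cycle contribute a full year; the cycle of
death (or, for incidence denominators, of diagnosis) contributes half a
year.  Incidence and mortality keep separate accumulators: incidence
exposure is censored at diagnosis.  In the trial's fractional final
period (0.2 of a year) hazards are scaled as `1 − (1−p)^0.2` and the
exposure credit is 0.2 (0.1 when the event falls inside it).

## Trial emulation

The two-arm sigmoidoscopy comparison recruits from the simulated birth
cohort: entry ages uniform over 55–64, anyone dead or already diagnosed
at entry is ineligible and replaced from an oversampled pool.  The
screened arm receives one sigmoidoscopy at entry with 100% attendance
(per-protocol analysis conditions on attendance); the control arm is
untouched.  Follow-up is 11.2 years (the trial's median).  Hazard
ratios are person-year rate ratios; with a single summary per arm no
survival-curve fit is attempted, and the rate-ratio reading of the
trial's hazard ratios is recorded as an interpretation.

## Scenario summaries: two metrics

Scenario tables are reported on a 5-year age grid under two
conventions: a true cumulative count per 100,000 entrants
(non-decreasing by construction) and an annualized event rate per
100,000 person-years over the 5-year window ending at each grid age.
Published scenario tables of this kind are often labelled cumulative
while containing series that dip once screening clears the prevalent
lesion pool — behaviour only a rate can show — so both conventions are
computed and every ratio operation takes the convention as an argument.
Hazard ratios are value ratios at an age (reported to 3 decimals);
percent reductions are rounded to integer percent.

## Calibration

`model_summaries` reduces a no-screening cohort to band summaries:
lesion prevalence among the alive at the band midpoint age, and
diagnosis/death rates per 100,000 person-years over the band.  The
objective is a weighted sum of squared deviations standardized by each
target's CI half-width (a prediction on a CI bound contributes 1.0 per
unit weight).  The search is a Latin-hypercube screen over the free
parameters followed by coordinate-wise quadratic (three-point parabola)
descent with a halving step, all evaluated under a fixed simulation
seed so the objective is deterministic.  Free parameters are named
either as global per-transition multipliers or as single (sex, band)
cells.  Agreement with registry-style rates uses log-scale rate ratios
with Poisson standard errors, pooled by DerSimonian–Laird
random-effects meta-analysis, and equivalence is declared by two
one-sided tests at a 20% margin (rate ratio within [0.8, 1.2]; both
one-sided p < 0.05).  The margin bounds default to
`(ln 0.8, ln 1.2)`; symmetric log-scale bounds can be passed
explicitly.

## Synthetic parameter generation

The exact calibrated transition probabilities and source life tables
the defaults emulate are not redistributable, so `crcsim.fixtures`
generates all inputs: a Gompertz life table (all-cause mortality
doubling roughly every 8 years from ~0.2% at age 40 for men), a steeper
exponential for the cancer-specific component, and per-band transition
probabilities tuned once so the no-screening cohort's 5-year-window
diagnosis rate rises from about 13 to about 86 per 100,000 person-years
between ages 40 and 80 with men about 1.3× women — a plausible Chinese
age-incidence schedule.  The tuning targeted shape plausibility, not
any exact published series; tests hold the defaults only to a ±50%
envelope at age 80.  What the generator does *not* emulate: serrated or
microsatellite-instability pathways, anatomical location, birth-cohort
trends, stage at diagnosis, and correlated test results across rounds.
Passing tests therefore demonstrate internal correctness and realistic
orderings, not agreement with any particular registry.

## Problem sizes and tolerances

The shipped analyses use 20,000 individuals per screening scenario,
one fifth of the published arm sizes for the trial emulation
(22,588 / 8,124), and 20,000-individual evaluations with a 30-candidate
budget for the calibration recovery experiment; these sizes keep every
Monte-Carlo check inside a few binomial/Poisson standard errors while
the whole pipeline completes in seconds.  Stochastic assertions use
3-standard-error bands; exact assertions (common-random-number
identities, determinism, survival-adjustment round trips) use machine
precision or 1e-12.

Degenerate inputs are rejected early with named violations: life-table
rows with `p_crc > p_all_cause`, transition-band gaps, probabilities
outside [0, 1], zero CI half-widths, zero event counts in rate ratios.
A single-band equivalence test falls back to the fixed-effect estimate
with a warning rather than failing.

## Known limitations

- One lesion per person; no polyp multiplicity or size growth model.
- No surveillance after polypectomy beyond the 10-year negative-
  colonoscopy interval; no endoscopy complications, costs or utilities.
- Trial hazard ratios are rate ratios, not partial-likelihood fits.
- The screen-detected survival multiplier is a stylised mechanism, not
  an estimate from stage-shift data.
- Calibration recovers low-dimensional parameterizations (multipliers,
  single cells); fitting all 32 band cells at once is out of scope for
  the default search budget.
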