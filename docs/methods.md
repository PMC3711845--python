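# Methods

This note records the model's assumptions, the conventions the code
commits to where the underlying study design left room, and what the
test suite does and does not establish. Everything quantitative stated
here is computed by the package's tests or scripts.

## Cohort structure and timing

A closed cohort of unaffected mutation carriers enters at age 25 and is
propagated in 6-month cycles to age 100 (150 cycles; results are
insensitive to a 95 vs 100 horizon at the <0.5% level, checked in
tests). State membership is evaluated at cycle end and there is **no
half-cycle correction**: a woman who dies during a cycle accrues nothing
for that cycle, while survivors accrue a full half-year. Screening and
work-up costs, and the two-week work-up disutility, are exceptions: they
attach to the screening event itself and are kept even if the woman dies
later in the same cycle. Discounting multiplies every accrual by
`(1 + r)^(−t)` with `t` the years from cohort entry to the end of the
accruing cycle and `r = 0.035/yr` for both costs and QALYs.

## Screening schedules

* Combined arm: MRI at every whole age in 25–64, mammography at every
  half age whose year falls in 30–79. The two alternate every six months
  through ages 30–64; women 25–29 receive only annual MRI, women 65–79
  only annual mammography. The first event is an MRI at age 25.
* Mammography-alone arm: one mammogram at every whole age in 30–79.

Women exit screening permanently at diagnosis; second primary cancers
and prophylactic surgery are outside the model's scope, as is
overdiagnosis (no non-progressive detectable lesions are modelled).

## Onset, detection and diagnosis

Band-level 10-year risks convert to per-cycle onset probabilities under
a constant hazard within the band; the last band's hazard is held for
ages above it and risk is zero below age 20. A cancer arising in a cycle
is screenable at that cycle's event with the modality's marginal
sensitivity. If missed (or if the cycle has no event), one further cycle
is allowed: a screen there uses the conditional sensitivity given the
opposite modality's false negative — derived from the marginal and
either-test sensitivities through the joint-detection identity, so a
full MRI+mammography round detects with exactly the combined
sensitivity — or the marginal sensitivity if no screen preceded. A
cancer still undetected after that further cycle surfaces clinically in
the same cycle (maximum preclinical sojourn: one year) and draws its
stage from the non-screen distribution; screen-detected cancers draw
from their detecting modality's distribution, independent of screening
history. All diagnoses — true positives and clinical presentations —
incur one diagnostic work-up (cost and two-week utility decrement),
as do false positives among cancer-free screenees at rate
`1 − specificity`.

Specificities are applied per event. The published *combined-programme*
specificity (77%) describes a full annual round and is carried in the
configuration for reference but not used by the engine, which needs
per-screen false-positive rates; the per-modality values (86% MRI, 95%
mammography) govern. Age-specific mammography performance is used in the
mammography-alone arm and for mammography above the MRI age range in the
combined arm; the fixed meta-analytic values are used where the two
modalities alternate. The last printed age band extends upward to cover
screening past 70.

## Post-diagnosis pathway

Treatment occupies the three cycles after diagnosis (stage-specific
cost total split in equal thirds — the original interval split is
unpublished — and stage-specific treatment utility). Cycles 4–20 carry
the remission utility at no cost. Survivors at 10 years are cured:
utility 1, background mortality only. Stage-specific cancer death
follows the two-point Weibull exactly through the published 5- and
10-year anchors (in-situ disease carries no excess mortality); the
death density is discretised per cycle and truncated by the cure rule.
Deaths within 3 cycles of diagnosis go directly to dead; later deaths
spend their final 3 cycles in progressive disease, where end-of-life
costs (equal thirds) and the progression utility override the
treatment/remission assignment. This implements the 18-month
progressive-disease lead time as a terminal-pathway override rather
than a shift of the survival curve, which keeps the printed survival
anchors literally true.

Cancer and background death compete independently within a cycle;
cancer death takes bookkeeping precedence. The engine evaluates all of
this in expectation by convolving per-stage accrual streams with the
diagnosis-incidence vector; an independent individual-level
microsimulation (10⁶ women per arm, every transition sampled) reproduces
the engine's per-arm discounted costs and QALYs within three Monte-Carlo
standard errors and is the primary correctness oracle in the test suite.

## Competing mortality

Background mortality is Gompertz, `h(age) = a·e^(b·age)`, with
`b = 0.09/yr` (a typical adult-female log-hazard slope) and `a` solved
by bisection so that all-cause mortality by age 65 in the
mammography-alone arm equals 20.9% — the published validation anchor for
this population (roughly a fifth of carriers dying by 65 from breast
cancer or non-ovarian causes). The underlying life-table schedule used
originally is not published, so this one-parameter calibration keeps the
model self-contained; its level is held fixed across PSA draws. The
published survival-to-65 figures therefore validate the calibration
rather than test it independently.

## Parameter uncertainty

Families follow standard PSA practice: Beta for probabilities and
utilities, Gamma for costs, Dirichlet for stage rows, Beta for the
band-level incidence risks; structural constants are fixed. Scalar
distributions are calibrated by holding the printed mean exact and
matching the printed 95% CI endpoints in least squares over the
remaining degree of freedom (concentration or shape). Two kinds of
imperfection are possible and are recorded as warnings in the loaded
spec rather than hidden: intervals bounded at 1.0 (utilities) and the
symmetric ±50% interval on the in-situ treatment cost cannot be matched
within 10% relative error by a two-parameter family with a pinned mean.
Dirichlet effective sample sizes are fitted to the widest printed
per-component CI of each row (≈142 for MRI-detected, ≈67 for
mammography-detected, ≈1470 for the registry-based non-screen row).
Survival anchors are sampled (resampling enforces S(10) < S(5)) and the
Weibull refitted per draw; the screen-sensitivity triple is sampled and
the conditionals re-derived per draw so the joint-detection identity
holds in every draw. All draws come from one master generator in a
documented order; results are bit-reproducible given (config
fingerprint, seed, n).

The one-way/tornado defaults vary the MRI price over its published
one-way range ($200–$700), MRI sensitivity and specificity over their
printed CIs, the discount rate over 0–5%/yr, and the MRI-detected stage
row by moving its in-situ share across its CI with the invasive shares
renormalised — moving every component to a CI extreme at once would
leave the joint 95% region and is not a meaningful one-way perturbation.

## Synthetic data

The original calibration inputs are administrative: per-patient
treatment costs in three 6-month intervals (n = 68) and registry
survival with linked deaths. The generators emulate their *structure* —
gamma totals with a front-loaded Dirichlet interval split (the real
split is unpublished; the model's equal-thirds allocation is independent
of this choice), and Weibull event times under administrative censoring
mirroring a seven-year registry window. They do not emulate treatment
pathway composition, cost-survival correlation, or loss to follow-up;
parameter-recovery tests (gamma mean within 2% and shape within 10% at
n = 10⁴; Weibull shape/scale within 5% under ≤50% censoring) therefore
establish that the calibration *code* is correct, not that the published
inputs themselves are unbiased.

## Numerical choices

Quantile-matching searches run on a log scale with bounded scalar
minimisation; Beta concentrations are capped at 10⁷ (narrow CIs
degenerate to point masses). Stage rows printed as 101% from rounding
are renormalised proportionally; rows off by more than 2% are rejected.
Infeasible sensitivity triples and anchor pairs raise calibration errors
naming the offending values; PSA draws violating engine preconditions
are resampled with a 1% failure budget. Occupancy conservation holds to
10⁻¹⁰ per cycle (tested); ICER ties in the net-monetary-benefit rule
count as cost-effective; per-draw ICERs with ΔE ≤ 0 are reported as
dominance labels, and the headline ICER is the ratio of mean ΔC to mean
ΔE.

## Known limitations

* The model is an idealised programme: full adherence from 25, exact
  schedules, no dynamic entry/exit.
* Undetected cancers do not die of cancer before clinical surfacing
  (their sojourn is at most one year) and do not alter background
  mortality.
* The competing-mortality schedule is a one-parameter calibration; its
  age shape above 65 is an assumption, and survival-based outputs
  inherit it.
* The PSA reproduces the printed input CIs but the original analysis'
  distribution families and stage-row concentrations are unknown; the
  lower tail of the incremental-QALY distribution is sensitive to those
  choices, so tail-probability outputs (e.g. the share of draws where
  the MRI arm loses QALYs) are less transferable than the central
  cost-effectiveness results.
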