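# Methods

## Model structure

`bcscreen` is a deterministic annual-cycle Markov cohort model over 17
health states: Healthy; preclinical DCIS; preclinical (undiagnosed)
invasive stages I–IV; treated DCIS and treated stages I–IV;
diagnosed-but-untreated stages I–IV (populated only when treatment uptake
< 1); breast-cancer death; other-cause death. Death states are absorbing;
treated states never return to preclinical states and do not progress
between stages — their only exits are the stage-specific post-treatment
fatality and other-cause death.

The cohort enters healthy at age 40 and is followed to age 100, after
which survivorship is negligible and the horizon is truncated. Each cycle
applies five events in a fixed order, each conditioned on the earlier
events not firing:

1. other-cause death at the life-table probability;
2. breast-cancer death (untreated/diagnosed-untreated stage IV at 0.23;
   treated stages at 0.006/0.042/0.093/0.275);
3. the screening round, when the strategy schedules one at this age;
4. symptomatic presentation of preclinical invasive disease
   (0.004/0.014/0.38/0.98 per stage-year); DCIS is asymptomatic;
5. onset (healthy → preclinical stage I at the age-band incidence × the
   high-risk relative risk 2; healthy → DCIS at 0.12 × that; DCIS →
   stage I at 2.02 × the invasive onset probability) and one-stage-per-year
   progression (0.06/0.11/0.15), also for diagnosed-untreated disease.

This sequential-conditional convention keeps every annual matrix exactly
row-stochastic with no renormalisation, and is implemented identically in
the cohort recursion and the individual-level simulation. The event order
itself is a modelling choice (decision software leaves it implicit); it is
fixed and documented here so results are exactly reproducible.

## Accrual, discounting, costs

Utility is credited to the state occupied at the start of each cycle;
costs are charged in the cycle they occur (questionnaire + screening per
attended round; biopsy per positive screen, true or false; the one-time
stage treatment cost at diagnosis, for the treated fraction). Cycle 0 (age
40) is undiscounted; cycle *t* carries factor (1+r)^−t with r = 0.03.
A half-cycle (trapezoidal) correction is available as
`half_cycle_correction: true` but is off by default, matching the plain
cohort default of decision-tree software.

Screening attendance is 100% among living, not-yet-diagnosed women within
the eligible ages (40–69); only treatment uptake varies (baseline 1.0;
scenario 0.7). Biopsy is treated as perfectly accurate. Detected DCIS is
treated with the same uptake; a detected-but-untreated DCIS remains in
situ (there is no diagnosed-untreated DCIS state) and is only counted as
a detection once treated.

### Utility conventions

Stage utilities (0.79/0.79/0.77/0.69) attach to the *disease state from
onset*, not to awareness of it: preclinical, treated and
diagnosed-untreated stage-s women all carry utility(s); healthy, DCIS and
treated-DCIS women carry 1.0. The alternative reading — undiagnosed
disease carries utility 1.0 — is available as
`preclinical_stage_utility: false`, but it makes early detection look
harmful: screen detection would move women to the stage utility years
before symptomatic diagnosis, and the resulting QALY loss (≈0.1 per woman)
overwhelms the mortality benefit (≈0.04), so annual screening would
*reduce* QALYs. Since stage utilities were measured on prevalent patients
as health-state (not diagnosis-event) valuations, attaching them to the
state is also the semantically coherent choice, and it is the default.

The false-positive disutility (25%, range 11–34%) is a multiplicative
decrement applied for the diagnostic episode — positive screen to biopsy
resolution — whose duration is `fp_disutility_duration_years`, default
5/52 year (≈5 weeks). Applying it for a full cycle-year (set the duration
to 1.0) would cost ≈0.08 discounted QALYs per woman under annual
screening, again exceeding the entire mortality benefit and making a
false positive as bad as living several months with metastatic disease,
which is inconsistent with how such decrements are measured. The episode
reading keeps one-way results over the 11–34% range qualitatively stable.

## Calibration

With screening disabled, cancers surface only on symptomatic
presentation, so the stage distribution of presenting cases is a function
of progression rates and symptom probabilities.
`calibrate_symptom_probs` minimises the L2 distance between the model's
presentation distribution and a user-supplied target using Nelder–Mead on
logit-transformed probabilities (deterministic initial simplex; default
start at the currently configured probabilities). The map from four
symptom probabilities to a three-degree-of-freedom distribution has
one-dimensional fibres, so the recovered vector is the solution nearest
the start; the round-trip guarantee is in distribution space (residual
below `tol`). The shipped symptom probabilities are already calibrated
values, so running the calibration is optional.

## Sensitivity analyses

Only parameters with published ranges are varied (test performance,
utilities, the false-positive disutility, unit costs); transition
probabilities and incidence are fixed. One-way analysis re-evaluates both
arms with one parameter at its minimum and maximum. The probabilistic
analysis draws all ranged parameters jointly — gamma for costs,
log-normal for utilities/disutility, beta for sensitivity/specificity.
Each distribution is fitted by pinning its mean to the baseline and
fitting the single spread parameter so the (2.5th, 97.5th) percentiles
match the published (min, max) in least squares; (min, max) are thereby
interpreted as a central 95% interval. Draws use one seeded generator
with parameters sampled in sorted-path order, so a seed fully determines
the analysis. The CEAC reports, per willingness-to-pay value, the
fraction of draws with positive net monetary benefit.

## Validation: microsimulation oracle

`simulate_cohort` re-implements the identical cycle convention by
sampling individual life histories (vectorised across women) without
sharing any transition-matrix code, so agreement is evidence rather than
tautology. The acceptance suite checks both arms at n = 200 000 women for
the baseline and five random parameter sets: cohort expectations fall
within 3 standard errors of the sampled means for cost and QALY. The
disease-free limit (onset switched off) is checked against the life
table's closed-form discounted survival product to 1e-9 in the cohort
engine and to Monte-Carlo error in the microsimulation.

## Synthetic inputs

The other-cause mortality table is generated as a Gompertz hazard
h(a) = level·e^(slope·(a−40)) with defaults level = 9·10⁻⁴,
slope = 0.095, converted to annual probabilities q = 1 − e^(−h). These
values give a remaining life expectancy at 40 of ≈42–44 years and a
3%-discounted life expectancy of ≈24.4 years, the magnitude for urban
Chinese women; the generator is a synthetic stand-in for a national
female life table, which is not bundled. Real tables (CSV with columns
`age,q`) can be supplied everywhere a life table is accepted. The
synthetic table reproduces the level and curvature of adult female
mortality but none of a real table's cohort effects or old-age
deceleration; results that depend on absolute life expectancy (QALY
totals) carry that caveat, while incremental comparisons between
screening arms are insensitive to modest life-table error.

`random_parameter_set` draws valid parameter sets for property tests:
ranged parameters uniformly inside their published ranges, unranged
probabilities within ±50% of baseline clipped to [0, 1].

## Problem sizes and numerical choices

Default analysis sizes: 61 annual cycles (ages 40–100); 1000 PSA draws;
200 000 women per microsimulation arm; calibration tolerance 1e-4 with at
most 600 objective evaluations. A two-arm cohort evaluation takes ~30 ms;
the full acceptance computation (scenario grid + 1000-draw PSA) completes
in well under a minute on one CPU. Ties and degenerate inputs: an ICER is
undefined (reported as None) at zero QALY increment while the net
monetary benefit is still computed; a degenerate point range yields a
point-mass distribution in the PSA; all-zero symptom probabilities raise
a degenerate-distribution error rather than returning a NaN distribution.

## Known limitations

- Treated patients cannot relapse or progress; their only breast-cancer
  hazard is the constant post-treatment fatality.
- No tumour-growth or continuous-time modelling; stage dwell times are
  geometric with the published annual rates, giving a long mean
  preclinical stage-I sojourn (~13 years). The comparative economics of
  screening intervals are sensitive to this: with long sojourns,
  infrequent screening retains most of the benefit, which is why the
  5-yearly interval attains the lowest ICER here.
- Screening attendance is universal; harms other than false-positive
  disutility (radiation, overdiagnosis beyond the explicit DCIS pathway)
  are not modelled.
- Mammography-alone test performance is not bundled; the corresponding
  scenario rows are produced only when the user supplies a
  `test_perf.mammography_alone` block.
- The high-risk relative risk (2) applies to both arms by default
  (`comparator_high_risk: false` reverts the unscreened arm to
  general-population incidence).
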