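# Methods

## The analysis

`cogdecline` implements a practice-corrected reliable-change analysis of a
repeated cognitive test battery administered through a positional protocol:
a seated baseline, a 3-hour 17° head-down (Trendelenburg) block with the
battery repeated every 30 minutes, a supine recovery hour with one sitting
of the battery half-way through, and a final sitting immediately after the
subject sits up — nine occasions in all.  The battery comprises 1-, 2- and
3-back working-memory tasks, a Stroop colour-word task and a lexical
decision task; each sitting of each test is reduced to an accuracy (fraction
of scorable trials correct) and a mean response time (RT).

Repeated administration improves scores regardless of any intervention, so
the change criterion is normed on a seated control cohort that sat the same
battery four times.  Per test and metric, the controls' mean and sample SD
(n−1 denominator) of the change between their third and fourth attempts
define the practice ("learning") correction and the normative scale.  For an
intervention subject at occasion *k*,

    z = (Δ − μ_learn) / σ_learn,    Δ = value(k) − value(baseline)

and the subject is classified as showing cognitive decline at *k* when any
test's accuracy z falls below −1.96 or RT z rises above +1.96 (the
`any_test_metric` rule; strict inequalities).  This is the ISPOCD-style
reliable-change criterion.  A `composite_mean_z` alternative averages the
decline-oriented z across tests and metrics before thresholding, matching
the composite construction used in the original ISPOCD methodology.  The
threshold (default 1.96), combination rule and sign convention are all
configurable on `ClassificationRule`.

Two sign conventions exist because the source analyses of this design have
described the same criterion both as "baseline subtracted from follow-up"
(decline = negative accuracy z, positive RT z — our `internal` default) and
with the printed inequalities reversed (positive z = accuracy deterioration,
negative z = RT deterioration), which is consistent only with a
baseline-minus-follow-up reading.  The two cannot be reconciled
simultaneously; both are implemented, they are exact duals (applying `paper`
to negated deltas reproduces `internal`), and the default is the
self-consistent one.

Group-level analyses mirror the reporting conventions of this literature:
per-occasion mean change from baseline with a t-based 95% CI and a paired
two-sided t-test against zero (tests are first averaged within subject so
each subject contributes one value per occasion × metric), and a one-way
within-subject repeated-measures ANOVA (subject as blocking factor,
F = MS_occasion / MS_occasion×subject) with an optional Greenhouse–Geisser
correction computed from the double-centred occasion covariance.  No
multiple-testing correction is applied to the per-occasion p-values,
matching the raw-per-timepoint presentation this analysis reproduces.  The
sample-size computation is the normal-approximation two-sample-means form

    n = (z_{1−α/2} + z_{power})² (σ₁² + σ₂²) / (μ₁ − μ₂)²

with configurable rounding.  The default is `floor`: with the 1-back vs
2-back accuracy inputs (98% SD 2% vs 91% SD 8%, α = .05, power = .80) the
raw value is 10.89 and the historically projected figure for this design is
10 per group, which only floor rounding reproduces; `ceil` (11) is the
statistically conservative option and is exposed.

## The synthetic cohort generator

Subject-level data for this design are not publicly deposited, so the
package ships a generative model used for all validation:

* **Accuracy**: P(correct) = logistic(a − d + g_acc·m + v + e_occ), with
  subject ability a ~ N(μ_a, σ_subj), test difficulty d, per-attempt
  practice gain g_acc, m prior administrations, injected decline shift v
  (logits) and an occasion-level "day-form" state e_occ shared across the
  battery.
* **RT**: shifted lognormal, RT = t₀ + exp(s + o + g_rt·m + u + e'_occ + σε)
  with subject speed s, test offset o, practice g_rt, decline shift u
  (log-scale) and trial noise ε ~ N(0,1).

The logistic/shifted-lognormal pair is the standard psychometric
parameterisation: accuracy is bounded with additive effects on the logit
scale, RTs are positive and right-skewed with multiplicative effects.  The
occasion-level state term exists because real battery scores are correlated
within a sitting (arousal, fatigue); without it, ten nearly independent
flag opportunities per subject × occasion drive the any-test false-positive
rate far above anything observed in practice.  It applies identically to
both cohorts and therefore leaves the per-metric calibration of the Z
criterion untouched.

Decline is injected through a per-occasion profile of (log-RT shift,
accuracy-logit shift), zero at baseline.  A configurable fraction of
intervention subjects is "susceptible" and receives the profile multiplied
by `susceptibility_multiplier`; controls are seated throughout and receive
practice only.  Ground truth (latents, susceptibility, applied shifts per
subject × occasion) is returned for recovery testing.

Default parameters (all configurable) and the reasons for them:

| parameter | default | rationale |
|---|---|---|
| n_intervention / n_control | 15 / 5 | the emulated design |
| control attempts | 4 | the emulated design |
| trials per test | 30 | typical short-battery length; unspecified in the design |
| n-back target rate | 0.3 | common n-back construction |
| Stroop incongruent / LDT nonword fraction | 0.5 | balanced conditions |
| test difficulties | −3.2 … −1.5 logits | anchor mean accuracies at ~96% (1-back), ~91% (2-back), ~82% (3-back), ~95% (Stroop/LDT) |
| practice g_acc, g_rt | +0.03, −0.01 per attempt | residual learning after the protocol's three familiarisation runs; the steep part of the learning curve is assumed already absorbed |
| σ (trial log-RT noise) | 0.3 | ~30% trial-to-trial RT variation |
| t₀ (non-decision shift) | 0.2 s | standard non-decision time |
| subject SDs (logit / log-RT) | 0.5 / 0.12 | moderate stable individual differences |
| occasion SDs (logit / log-RT) | 0.15 / 0.06 | within-subject sitting-to-sitting form |
| susceptible fraction / multiplier | 1/3 / 3.5 | roughly a third of subjects cross the threshold at the later occasions in the demonstration scenario |
| decline profile | RT +0.04→+0.10 log, accuracy −0.05→−0.12 logit | RT-dominant decline rising with head-down time, partial supine recovery, slight worsening on sitting up |

Practice is linear per attempt on the logit/log scales; attempts are
counted from the first practice run, with intervention subjects entering
baseline after three practice sittings.  The one-step (attempt 3→4)
learning correction is therefore exactly centred only at the first
follow-up when practice is nonzero — a property of the emulated correction
itself, not of this implementation.  Randomness is a single seed split
hierarchically per (cohort, subject, occasion, test) via `SeedSequence`, so
changing one test's trial count perturbs no other cell, and the trial-level
and score-level generation paths consume identical streams (they agree to
floating-point round-off, which is tested).

What the generator does **not** emulate: stimulus-kind effects on the
response model (incongruent Stroop trials are not slower than congruent
ones; n-back load affects only the difficulty intercept), response
omissions, RT outliers from lapses, fatigue trends distinct from practice,
the mid-protocol toilet break taken by some subjects (expressible manually
as a dip in the decline profile, but not modelled), or any cerebral
physiology.  Passing validation on this generator shows the estimators are
correct under a well-specified psychometric model; it does not show the
classifier is well calibrated on real batteries, where normative samples
are small and model misspecification is certain.

## Validation studies and chosen problem sizes

* **Null calibration** (`studies.null_calibration_study`): zero decline and
  zero practice in both cohorts (the strongest form of "shared practice
  structure", under which every post-baseline occasion is an exact null),
  mid-range accuracy (difficulty 1.2 logits below mean ability) and 300
  trials per test so the binomial lattice of proportion scores cannot
  distort the 2.5% tail.  With 500 intervention subjects, 200 controls and
  20 replicates, the per-metric flag rate is required to sit within 3
  Monte-Carlo SEs (from the replicate spread) of Φ(−1.96) ≈ 0.025; with the
  study-sized 5 controls the normative SD estimate is heavy-tailed and the
  rate must be at least the large-control rate.
* **Recovery** (`studies.recovery_study`): log-RT shifts {0, .05, .1, .2}
  injected uniformly at all post-baseline occasions, 100 subjects, the same
  3 replicate seeds at every grid point: mean flagged percentage must be
  non-decreasing.
* **Oracle equivalence**: on 100 random score-table fixtures, Z scores,
  flags, classifications, paired t p-values and repeated-measures F agree
  with plain-Python brute-force recomputations (Z to 1e-12, i.e. machine
  precision given differing summation orders; t/F to 10 decimals).

## Numerical choices and degenerate inputs

* Sample SDs use the n−1 denominator throughout; `validate_learning` guards
  the Z denominator with an SD floor (default 1e-9) — a normative SD that
  small signals a broken fixture, not a precise population.
* Zero-variance deltas in the paired summary: p = 1 when the mean is also
  zero (certain null), error otherwise.
* All-constant repeated-measures grids return F = 0, p = 1 (statsmodels
  would return NaN); zero error SS with nonzero occasion SS returns F = ∞,
  p = 0.
* Printed percentages round half-up to the nearest integer (4/15 → 27);
  exact rationals are retained in all CSV outputs.
* RT scoring averages correct scorable trials only by default
  (`correct_only`, the usual psychometric convention); `all_scorable` and
  an off-by-default winsorizing fraction are available.  Stroop congruent
  and incongruent trials are pooled.
* Threshold comparisons are strict, so z exactly at the threshold does not
  flag.

## Known limitations

* With a 5-subject normative sample the criterion's false-positive rate is
  inflated well above its nominal level (the package demonstrates this
  rather than hiding it), and with ten flag opportunities per subject ×
  occasion the any-test rule's familywise rate is higher still.
* The one-step learning correction under-corrects multi-step practice
  whenever learning continues past the fourth control attempt.
* The repeated-measures ANOVA assumes a balanced grid and (without the
  Greenhouse–Geisser option) sphericity; no mixed-effects covariance
  modelling is offered.
* The power computation is the two-independent-means normal approximation;
  no paired or t-based variant is provided.
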