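# Methods and design notes

## Setting

Children identified by population screening as carrying two or more islet
autoantibodies are staged by OGTT and HbA1c into stage 1 (normoglycemia) or
stage 2 (dysglycemia) of presymptomatic type 1 diabetes; an
autoantibody-negative control group anchors what "normal" CGM looks like.
Each participant wears a blinded, factory-calibrated sensor for ~10 days at
5-minute cadence. The package asks three questions of such data: can CGM
metrics separate controls, stage 1 and stage 2; can control-anchored
thresholds and a composite score predict progression to clinical (stage 3)
diabetes within a year; and how reproducible is any of this across repeat
wears, given that factory-calibrated sensors carry substantial per-wear
additive reading offsets.

## Quality control

The first 12 h of every wear are discarded (insertion artifact; the removal
is half-open, so a sample exactly 12 h after the first timestamp is kept).
Implausibility is then flagged by three configurable detectors:

* flat-line: a run of ≥ 3 identical consecutive values lasting ≥ 3 h;
* rate-of-change: adjacent samples implying > 15 mg/dL/min; both ends of
  the step are flagged;
* rail-pinning: ≥ 30 min at the sensor reporting limits (40/400 mg/dL).

These detectors are heuristic stand-ins for the visual curation that such
studies apply; they are not a reproduction of any published criterion.
Flagged samples are dropped; a wear is included only if strictly more than
96 h of samples remain (retained samples × nominal cadence — gaps do not
count as wear time) and the flagged fraction is ≤ 20 %. A trace records the
trim it has received, so the QC pipeline is idempotent.

## The metric suite

All metrics are computed over retained samples: mean, population-SD
(denominator n; with ~2 800 samples per wear the n vs n−1 distinction is
far below reporting precision, but the convention is fixed), CV =
100·SD/mean, maximum, TA140/160/180/200 (percent of samples strictly above
the threshold), TB80/100 (strictly below), and the nocturnal mean over
clock time [03:00, 06:00), pooled across nights (a flag switches to
equal-weight nightly means; pooling is the default because wears cover the
same number of full nights almost always). Proportions are sample-count
proportions, not trapezoidal integrals — cadence is uniform after QC.
Computation is in mg/dL throughout; mmol/L (÷ 18.016, 1 decimal) is for
display only.

The additive-offset fingerprint follows from these definitions: a constant
per-wear offset c shifts mean, max and nocturnal mean by exactly c, leaves
SD untouched, moves every TA up and every TB down, and scales CV by
mean/(mean+c).

## Staging

Stage 3 criteria are evaluated before stage 2 so overlapping values (e.g. a
2-h glucose of 200) resolve upward; the label is "provisional" because a
clinical diagnosis requires confirmatory testing, which is outside the data
model. Values in the narrow gaps between the normoglycemia ceilings and the
dysglycemia bands (HbA1c in (6.4, 6.5], fasting in (125, 126), 2-h in
(199, 200) — reachable only with continuous inputs) are labeled stage 2
with an explicit `range_gap` criterion: the dysglycemia bands are read as
extending up to the stage-3 cutoffs. This choice keeps the label total,
unique, and monotone in every glycemic field (property-tested). The
symptomatic random-glucose route to stage 3 is out of scope.

## Thresholds, rule, score

The 100 %-specificity cutoff of a metric is its exact control-group maximum
(not rounded; reports show 1-decimal values alongside). Flagging is
strictly-greater, so the extreme control itself is not flagged and
specificity on the derivation controls is 1 by construction — this is a
definition, not an empirical claim, and the corresponding test is a
construction check. The any-k rule (default k = 2 of the 4 discriminating
metrics SD, TA140, TA160, TA180) is monotone in each metric.

The Progression Prediction Score is a maximum-likelihood logistic
regression of the within-1-year progression indicator on the four metrics
in natural units (no standardization; coefficients are per mg/dL or per
percentage point). Participants enter the fit if autoantibody-positive and
either followed for at least the horizon or progressed — censored-early
non-progressors are excluded rather than imputed. On complete separation or
non-convergence the fit falls back to a small L2 penalty (α = 1e-4),
recorded in the model diagnostics. Scores are banded at 0.19 and 0.4, both
cuts inclusive to the middle band. The score is in-sample and unvalidated
by design; no cross-validation machinery is provided.

## Evaluation statistics

* Confusion statistics carry exact counts; percentages are rounded half-up
  to integers for report parity; undefined ratios are reported as missing,
  never as zero.
* AUC is the midrank Mann–Whitney statistic divided by n₁n₀ (tested against
  exhaustive pair counting with ties); the CI uses the DeLong placement
  variance. The ROC curve has one operating point per distinct threshold.
* Kaplan–Meier risk at the horizon is 1 − S(h) from the product-limit
  estimator with Greenwood variance; the 95 % CI is linear-scale, clipped
  to [0, 100] %. Log-rank tests use the standard chi-square.
* Group comparisons: median (IQR) per group, Kruskal–Wallis across groups,
  pairwise two-sided Mann–Whitney U; categorical variables use chi-square,
  replaced by Fisher's exact for 2×2 tables with any expected cell < 5 (a
  documented heuristic — the choice between the two tests is otherwise
  unspecified in this field's reports). No multiple-testing correction is
  applied, matching practice in the exploratory analyses this mirrors.
* The offset-correlation analysis reports Pearson r of the nocturnal mean
  against TA140, SD and CV (Spearman available by flag). Under additive
  per-wear offsets, nocturnal mean and TA140 correlate strongly while CV is
  roughly level-independent; that asymmetry is the diagnostic signature.
* Repeatability: for participants with two QC-passed wears, second-minus-
  first deltas per metric, per-threshold flag concordance, any-k rule
  concordance, and the count of pairs with |Δ mean| > 10 mg/dL.

## Synthetic cohort generator

The generator is a first-class, tested component; it defines the conditions
under which the pipeline is exercised. Per participant, a latent state
holds a basal level and an excursion scale; per wear,

    reading(t) = clip(baseline + circadian(t) + Σ meals(t) + AR1(t)
                      + session_offset + noise(t), 40, 400)

* circadian: one sinusoid (default amplitude 3.2 mg/dL, peak 18:00), so the
  03:00–06:00 window sits near the trough, approximating fasting;
* meals: Poisson-timed (3.2/day) within 06:00–22:00, gamma-shaped pulses
  (peak at 40 min, shape u·e^(1−u)) with gamma-distributed amplitudes whose
  mean is group-dependent (25/33/52 mg/dL for control/stage 1/stage 2)
  times the personal excursion scale;
* AR(1) wander: per-5-min coefficient 0.93, stationary SD ~8 mg/dL,
  growing by 0.45 mg/dL per mg/dL of basal-level deviation (variability
  scales with level), floored at 30 % of the base;
* sensor error: one additive offset per wear, N(0, 8 mg/dL), plus white
  noise (SD 2). No multiplicative term by default (the additive form is
  what the repeatability and correlation analyses presuppose);
* between participants: basal level N(group mean, 6) with group means
  109/110.5/122.5 mg/dL; excursion scale lognormal (σ = 0.2) correlated
  0.5 with the basal level.

OGTT panels are drawn from group-dependent normals, with the 120-min value
shifted by 30 mg/dL per unit of excursion scale and HbA1c linear in the
expected mean glucose (2.0 + 0.028·mean, SD 0.15) — a configured link, not
claimed physiology. Progression times are exponential with group hazards
0/0.07/0.60 per year scaled by (excursion scale)², censored at a per-person
follow-up drawn uniformly between 1 and 1.5 years.

Defaults were calibrated once, analytically and by multi-seed Monte Carlo,
to the published group structure of this study design: control medians
(mean ~115, SD ~16, TA140 ~7 %, nocturnal ~106 mg/dL) with graded stage
increases; 33-control maxima near the published cutoffs (SD ~24, TA140
~40 %, TA160 ~12 %, TA180 ~5 %); and the control correlation pattern
r(nocturnal, TA140) ~ 0.8, r(nocturnal, SD) ~ 0.36, r(nocturnal, CV) ~ 0.
Reaching that pattern required the basal-level couplings above: with purely
independent person effects, CV inherits a spurious negative correlation
with level (CV = SD/mean), and with a heavy coupled lognormal tail the
control maxima swallow the stage-2 distribution. The calibration targets
were the published values; the split between meal-amplitude coupling and
level-coupled AR amplitude is what reconciles the near-zero CV correlation
with realistic control extremes.

What the generator does **not** emulate: sensor drift within a wear,
compression artifacts, meal-composition effects, insulin dynamics,
age/sex effects on glycemia, informative censoring, or any multiplicative
sensor error (available as an extension point but off). Passing tests
therefore demonstrate correctness of the analysis machinery and qualitative
reproduction of the offset-driven phenomenology — not clinical performance
on real cohorts, whose published cohort-specific numbers depend on
unavailable raw data.

## Reproducibility and problem sizes

A single run seed drives all randomness; cohort generation consumes one
deterministic stream, analysis stages are deterministic, and re-running a
config byte-reproduces every artifact (the manifest stores the config and
its hash; output location and verbosity are excluded as non-substantive).
The test suite and the acceptance script use study-sized or smaller
problems — cohorts of up to 200 participants with 10-day wears (~576 k
samples), 100-replicate logistic recovery at n = 2 000, 10⁴-draw
Monte-Carlo oracles — sizes chosen so the full suite runs in well under a
minute while keeping Monte-Carlo error far below the tolerances tested.
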