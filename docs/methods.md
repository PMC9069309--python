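# Methods

This note documents the models implemented in `mhq`, the constants they
ship with, and what the synthetic cohorts do and do not establish.

## The instrument and the composite score

The instrument rates 47 mental-health elements on a 9-point life-impact
scale. 27 *spectrum* elements describe functions that run from positive to
negative (9 = healthy pole); 20 *problem* elements are pure detractions
(9 = constant, severe impact on functioning). The published material names
only a handful of elements (self-image, self-worth and confidence, memory,
physical intimacy, emotional control, coordination, sleep quality, feelings
of sadness/distress/hopelessness); the remaining labels in
`data/elements.yaml` are plausible fillers. The 27/20 split, the element
ids used by the rule table, and the related-group tags are the binding
parts; labels are configuration.

The composite score on [-100, 200] is a reconstruction of the instrument's
proprietary transform from its published constraints: it must be nonlinear
in the life-impact rating, weight element classes by symptom seriousness,
attain both endpoints, and be consistent with the clinical thresholds (a
profile with five or more clinically significant symptoms must not reach
the upper half-scale). The shipped transform is:

1. **Per-element penalty curve.** With `d` the number of steps from the
   healthy pole (0..8), penalty = `w * (0.8 * min(d, 3) + 0.15 * max(d - 3, 0)^2)`
   where `w` is the class weight (mild 1, moderate 2, severe 3). The
   benign region (up to 3 steps) is linear; beyond it the penalty
   accelerates quadratically, so the step from rating 8 to 9 on a problem
   element costs far more than the step from 1 to 2.
2. **Normalization.** The raw penalty sum is mapped affinely so the best
   possible answer set (all spectrum 9, all problem 1) scores exactly +200
   and the worst exactly -100 — the only two printed anchors.
3. **Symptom-count deduction.** 18 points per clinically significant
   symptom (problem rating >= 8 or spectrum rating <= 1), then clamping to
   [-100, 200]. A purely additive per-element transform cannot couple the
   score to symptom counts strongly enough: five elements' whole ranges
   cover under a quarter of the scale, so a heavily symptomatic but
   otherwise perfect profile would still score near +180. The count term
   makes the guarantee provable: the cheapest five symptoms (five mild
   problem elements at rating 8, everything else perfect) leave a base of
   184.6, and the 90-point deduction lands at 94.6 <= 100. A linear count
   term (rather than a convex one) was chosen so the attainable score
   ladder fills the -75..-50 band rather than jumping to the floor.

Score categories are six 50-point bands, Distressed [-100, -50) up to
Thriving (150, 200]; a score of exactly 100 is Managing because the upper
two bands are defined by score > 100.

All constants live in `ScoreTransformParams` and can be overridden; the
defaults were fixed during the generator calibration described below.

## Clinical mapping

A rating marks a clinically significant symptom at >= 8 (problem) or <= 1
(spectrum) — thresholds equivalent, on average, to experiencing the symptom
about five days a week (see the probe calibration). The rule engine
evaluates, per disorder, a conjunction of required-element conditions and
k-of-set clauses over the 47 symptom flags. The shipped 10-disorder table
(`data/disorder_rules.yaml`) is a reconstruction aligned with the symptom
content of the corresponding diagnostic criteria (e.g. depression requires
the sadness element plus at least 5 of a 9-element set); the published
mapping itself is not in the public record, so the table is data, not
contract. Every shipped rule requires at least four symptomatic elements.
Duration/timing criteria are out of scope: the instrument measures current
perception. Known fidelity caveats for OCD and bipolar disorder (broad or
missing element matches) carry over to any table expressed over this bank.

## Criterion analyses

Productivity uses two 0-31 day counts: days fully unable to work (M,
absenteeism) and days with reduced productivity (R, presenteeism).
Aggregated per 25-point score bin, mean M is fitted to `a*exp(-b*s) + c`
(floor `c >= 0`, because the top bins keep a small nonzero loss;
initialized from a log-linear regression) and mean R by ordinary least
squares. Fits run on bin means, as the aggregate curves are reported; bins
with fewer than 20 respondents are excluded (config). Total productivity
loss is `M + n*R` with the fractional loss `n` on unproductive days
assumed in [0.2, 0.5]; band evaluation returns the loss at both ends.

## Reliability battery

*Sample reliability*: k (default 4) nonoverlapping samples drawn by
stratified sampling without replacement over age band x gender x country
cells, with proportional allocation rounded by the largest-remainder method
(sums exactly to the target size). Equivalence is assessed by one-way ANOVA
per element and on scores, plus pairwise Pearson correlation of the
47-element mean vectors.

*Internal consistency*: Pearson r per configured item pair, with
categorical items recoded first (sleep sufficiency: all the time = 7, most
= 5, some = 3, hardly ever = 1). The shipped specs cover the three related
pairs (sleep quality/sleep sufficiency, sadness/current mood,
self-image/self-worth) and three unrelated pairs (memory/physical
intimacy, emotional control/coordination, memory/emotional control). The
mood pair correlation is reported signed (negative: impact of sadness and
mood valence run in opposite directions).

*Test-retest*: respondents with a second attempt at least 3 days after the
first are paired (first attempt with the earliest qualifying retake;
same-day and next-day retakes are treated as experimentation and dropped).
Statistics: Pearson r between first and second scores; a pooled element
correlation over all (pair, element) rating tuples — one number for the
whole bank, matching how aggregate element reliability is quoted — plus
per-element correlations for diagnostics and a per-stratum table over gaps
{3-7, 8-30, 31-60, 61-120, 121-450} days (strata with < 3 pairs reported
absent). The pooled correlation deliberately includes between-element mean
differences; that is what makes a pooled 0.70 compatible with per-element
values near 0.4.

## Life-impact scale calibration

For one probed element (sadness/distress/hopelessness), respondents rating
its impact >= 5 also report frequency (0-7 days last week) and severity
(5 ordered levels). Per-rating means and SEMs (SD/sqrt(n)) are fitted
linearly against the rating; the line extrapolates outside 5..9 (a rating
of 1 should imply < 1 day/week). The frequency x severity composite is
fitted with a second-order polynomial: if both means are linear in the
rating their product is exactly quadratic, so the quadratic is the natural
form for the "nonlinear" composite relationship.

## The synthetic-data generator

The generator emulates the statistical structure of the study's pooled
web-survey data so every pipeline stage can be exercised without access to
the underlying database. Per respondent, a latent well-being trait theta is
drawn from a two-component normal mixture — 78% N(0.2, 0.95) and a 22%
unwell tail N(-2.2, 1.15) — standardized to zero mean and unit variance so
the mixture controls only the distribution's shape. Each element's healthy
propensity is `loading*theta + group_loading*u_g + sigma*eps` with unit
total variance; ratings discretize the propensity linearly around a
per-element baseline (spectrum elements rate high when healthy, problem
elements low), clamped to 1..9.

Frozen defaults and what they were set by:

| parameter | default | rationale |
| --- | --- | --- |
| loading | 0.60 | unrelated-pair rating correlations ~ 0.35-0.40 |
| group loadings | self-regard 0.67, sleep 0.57, mood 0.54 | related-pair anchors 0.77 / 0.63 / 0.64 |
| rating scale | 2.0 latent SD per rating unit | realistic marginal spread and tail mass |
| baselines | spectrum 5.2-8.0, problem 1.6-4.6 (sadness 3.6, sleep quality 6.2) | marginal means by format; between-element variance drives the pooled retest correlation |
| trait mixture | 0.78/0.22, means 0.2/-2.2 | unwell tail: ~4-5% Distressed, populated low score bins |
| retest stability | 0.91 (trait and shared factors) | score retest r ~ 0.84 |
| person-by-item stability | 0.15 | pooled element retest r ~ 0.70; without a persistent person-by-item component this anchor is unreachable while cross-element correlations stay near 0.38 |
| probe frequency | Binomial(7, p), mean 0.65*rating - 0.2 | anchored at 5 days/week for rating 8; < 1 day/week extrapolated at rating 1 |
| probe severity | 1 + Binomial(4, p), mean 0.4*rating + 0.4 | linear severity with enough noise that impact correlates more with frequency than severity |
| absenteeism mean | 2.43*exp(-0.0207*score) + 0.15 | low-bin mean 15.0 and top-bin 0.2 days |
| presenteeism mean | 10.7 - 0.04*score | low-bin mean 14.2 and top-bin 3.2 days |
| day-count noise | negative binomial, dispersion 2, clamped 0..31 | SD ~ 11.3 at mean 15, integer day counts with variance > mean |
| retest gaps | 15% < 3 days, rest over the five strata | exercises the same-day/next-day exclusion |
| ease-of-understanding flag | P(true) = 0.9742 | 2.58% exclusion rate |

Calibration procedure: the correlation-bearing parameters were grid-tuned
against the anchored statistics (retest correlations, consistency pairs,
probe anchor, bin-fit quality) over several seeds and then frozen; the
script performing the evaluation is the same pipeline the acceptance
script runs. The anchored day-count and probe means are fixed by published
bin values, not tuned.

Reproducibility: every operation draws from `default_rng([seed, stream])`
with a fixed stream id per product (cohort, retests, probes,
productivity), so a (config, seed) pair yields byte-identical output and
the four products are independently reproducible.

### What the generator does not emulate

- **Diagnostic co-occurrence.** A single common factor under-produces
  jointly extreme symptom profiles: in synthetic cohorts only ~15-30% of
  Distressed respondents satisfy a disorder rule, versus ~89% reported for
  the real instrument. Mean symptom counts per bin remain monotone, and the
  high-score end (<= 0.03% of scores > 100 meeting any rule) is
  reproduced, but absolute burden percentages at the low end are not
  calibrated. Passing burden tests therefore validates the engine and the
  score-symptom coupling, not population prevalence.
- **Demographic structure.** Country/gender/age/employment cells are
  independent of the trait; matched-sample equivalence is trivially
  satisfied rather than stress-tested.
- **Item nonresponse and careless responding**, recruitment-campaign bias,
  and any real time trend between attempts (state change is a stationary
  autoregression).

## Numerical choices and degenerate inputs

- Pearson correlations return NaN with a degeneracy flag when either
  series is constant or has fewer than 3 observations.
- ANOVA returns F = 0 (p = 1) for globally constant data and F = inf
  (p = 0) when groups differ with zero within-group variance.
- The exponential fit raises with its initializer diagnostics on
  non-convergence and flags `b ~ 0` (constant means) as degenerate.
- Bin edges: [low, low+25) with the top bin closed at 200; category bands
  are lower-closed except that exactly 100 belongs to Managing.
- Scores are clamped to [-100, 200] after the symptom deduction; the clamp
  binds only at the floor, where heavily symptomatic profiles accumulate.
- Largest-remainder rounding breaks ties by cell order (stable argsort).

## Problem sizes

The packaged analyses run at the study's subset scales, reduced
proportionally where the full database would be needed: probe calibration
on ~4,300 probes (study: 4,247), productivity on 8,000 respondents
(study: 7,625), test-retest on ~2,200 pairs (study: 1,907), internal
consistency on 20,000 and clinical burden on 50,000 respondents (study:
174,618). At these sizes the full acceptance recomputation takes a few
seconds on one CPU.
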