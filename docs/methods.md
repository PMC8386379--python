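# Methods

This note documents the models and procedures implemented in `phenoweek`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish.

## Latent severity and PHQ-9

Each participant carries a weekly latent depression severity in the logit
units of an item-response model:

- participant baseline `b ~ N(mu_arm, between_sd²)` with `between_sd = 0.5`;
- weekly deviations follow an AR(1) process `x_w = φ x_{w-1} + ε_w`,
  `φ = 0.8`, innovation SD 0.3, initialized at its stationary
  distribution. The persistence value is a modeling choice (within-person
  week-to-week PHQ-9 autocorrelation is not well pinned down empirically)
  and is exposed in `CohortConfig`.
- PHQ-9 item `i` is drawn `Binomial(3, logistic(severity + offset_i))`
  with offsets spread evenly over [-1.2, 1.2]. This respects the 0-3 item
  range, makes the expected sum strictly monotone in severity, and hits
  the scale floor/ceiling exactly in the infinite-severity limits.

The arm means `mu_arm` are not free parameters: they are solved by root
finding (Gauss-Hermite quadrature for the exact expectation) so that the
expected week-0 sum is 17.4 in the depressed arm and 5.4 in the control
arm, matching the baseline severity split of the emulated recruitment
design (80:20 depressed:control; depressed = PHQ-9 >= 10 at enrollment).

## Feature effects

Every one of the 34 registered features has a signed standardized effect
`e_f` of severity on its weekly mean. The weekly generating target is

    target_fw = base_f + scale_f * (e_f * z_w + 0.6 * u_fp + 0.6 * v_fw)

where `z_w` is severity standardized against the cohort mixture (so
configured effects are population-z-scale regardless of cohort
composition), `u_fp` is a per-participant intercept and `v_fw` weekly
noise. Defaults: `e_f = 2.5 × (the published univariate correlation)`,
capped at |0.6|, with the two missing-data indicator features fixed at 0
— a single a-priori rule that preserves the published ordering and signs
at moderate magnitude. Base/scale values per feature are plausible
field-scale numbers (e.g. sleep 7 ± 0.9 h, battery 58 ± 8%, speech
110 ± 15 wpm) recorded in `FEATURE_GEN`.

Direct streams (audio, light, battery, volumes, screen, Wi-Fi, apps,
sleep, calls, texts, diary) realize their targets through daily/minutely
noise so that the pipeline's daily-to-weekly aggregation recovers them on
average. Counts use Poisson realizations of the target rate; sentiment is
realized by mixing positive/negative lexicon tokens with the mixing
weight solved from the target score (so the deterministic lexicon scorer
recovers it). Location effects are mechanistic rather than additive:
severity lowers the daily outing rate (log-linear), raises work-skipping
and lowers hospital-visit probability, which jointly raise homestay and
lower unique clusters, entropy, variance and hospital time — the
published sign pattern emerges from behavior rather than from painting
values onto features.

Two fidelity levels share this target model. The full path realizes every
minutely sample and event; the weekly fast path
(`simulate_feature_matrix`) draws the 34 weekly values directly from the
targets plus small measurement noise. Replicate-heavy statistical checks
(null calibration at 200 replicates, 20-replicate sign recovery) use the
fast path; pipeline, filtering, location and the study-scale
effect-recovery checks use the full path.

## Trajectories and GPS

Days are scheduled around eight anchors per participant (home, work at
1.5-5 km, and six other tagged places at 0.5-8 km, one tagged "hospital
or doctor's office" and one "place to exercise"). Nights (11 PM-4 AM) are
at home by construction; workday attendance covers the 10 AM-3 PM window;
evening/weekend outings visit the other anchors. Stationary positions get
Gaussian jitter (default σ = 10 m). Transit between anchors is sampled
every minute with heavy position error (σ = 400 m) and a per-trip random
route bow (midpoint offset σ = 500 m, endpoints pinned): GPS error in
motion is realistically much larger than at rest, and without the route
variation, hundreds of repeated trips along one line would accumulate
enough density to chain spurious DBSCAN clusters along the commute.
A small number of low-density transit clusterlets still form occasionally;
they add noise, not bias, to the unique-cluster count.

Clustering runs once per participant over the whole study (the home
definition requires cross-week identity of place) with DBSCAN under
haversine distance, eps = 30 m, min_samples = 5 minutely points — both
exposed in `LocationConfig`. For full-study traces the pipeline bins
points to a ~3 m grid and clusters the occupied cells with occupancy
weights; each raw point inherits its cell's label. This is exact up to
the sub-grid displacement and avoids the quadratic neighbor lists that
raw DBSCAN builds when ~10⁵ points sit within one eps radius. The
unbinned mode remains the default of the public `cluster_locations` API.

Open definitional choices, flagged rather than inferred: location
entropy uses natural log over clustered minutes (noise excluded);
location variance is population `var(lat) + var(lon)` in raw degrees²;
the work heuristic's 15% share is computed over clustered (non-noise)
minutes per week; minutes from 23:00-23:59 attach to the following
night's home window; commute requires a direct home<->work transit with
no intermediate dwell in any cluster. Commute minutes feed the daily
location-budget summary but are not one of the 34 analysis features.

## Filtering and aggregation

A day is sufficient iff (max over the seven minutely sensors of distinct
sampled minutes) >= 720 AND (distinct hours containing a ping) >= 18.
Days with no samples are insufficient, not errors. A week is retained iff
>= 3 of its 7 days are sufficient; weeks are aligned to each
participant's enrollment day in 7-day blocks. Weekly values are
arithmetic means over sufficient days carrying a value, so a retained
week can still miss a specific feature. Event features (calls, texts)
are 0 — not missing — on sufficient days without events; permission-gated
streams (app usage, sleep report) are missing when absent, mirrored by
the two indicator features (weekly fraction of days with no data).
PHQ-9 availability is not required for week retention; the univariate
screen applies its own pairwise-complete rule.

## Statistics

The screen computes Spearman r (average ranks for ties) and the
large-sample t-approximation p per feature over pairwise-complete weeks;
an exact permutation option exists for n <= 9. Features with fewer than
three complete pairs (or constant values) are flagged undefined and
excluded before adjustment. Adjustment is the Benjamini-Hochberg
nonnegative step-up across the defined tests (statsmodels'
implementation, cross-checked in the tests against a brute-force step-up
oracle).

Repeated weeks per participant are pooled, as the analysis design
prescribes. This is a documented limitation, not a bug: with
participant-level heterogeneity in both features and PHQ-9, the pooled
t-approximation is anti-conservative (in a 15-participant × 8-week null
simulation, ~78% of replicates produced a spurious BH discovery). The
null-calibration check therefore uses cohorts with one week per
participant, where the test's independence premise holds and the measured
familywise null rate is ~3-5%. Correlations on pooled multi-week cohorts
should be read as descriptive effect sizes, not as calibrated inference.

The multivariate model is scikit-learn's elastic-net logistic regression
(saga solver, fixed random state, tol 1e-6), minimizing the logistic loss
plus `(1/C)[ρ‖β‖₁ + (1-ρ)/2 ‖β‖₂²]` with an unpenalized intercept;
C = 1.0 and ρ = 0.5 are the study-fidelity defaults. Cross-validation
partitions participants (not weeks) into 10 seeded near-equal folds with
no stratification. Standardization parameters are fit within each
training fold (leak-free) rather than globally; a global mode would match
a literal single-pass reading of "standardize all features" but leaks
test-fold moments, and the difference is negligible at these sizes. Test
folds holding a single class have no defined AUC and are excluded from
the mean/SD with a warning — at small cohort sizes with an 80:20 arm
split this prunes many folds, which is why the demo run reports 3 of 10
folds while the 200-participant configuration retains all 10. ROC AUC is
computed in the Mann-Whitney rank form (ties count ½), cross-checked
against scikit-learn in the tests. The reported SD is the fold-level
sample SD (ddof = 1).

Within-participant mean imputation replaces a missing feature-week with
the mean of that participant's observed weeks for that feature, never
alters observed cells, and drops weeks that remain incomplete (a feature
missing in all of a participant's weeks cannot be imputed this way).

## Accounting

Percentages are numerator/denominator ratios rounded half-up (decimal
arithmetic, not binary float rounding) to the printed precision — e.g.
4151/4980 -> 83.35%, 313/384 -> 81.5% at one decimal. The synthetic
accounting reports PHQ-9 adherence over the full roster, retained weeks,
and depressed-week fractions of the complete-case and imputed sets.

## Missingness defaults

Whole-sensor absence is sampled once per participant-device (e.g. ambient
light 15%, app usage 10%, ambient audio 4%, location 1%), day dropout at
8%, minute loss at 5%, and survey skips at 17% (PHQ-9), 20% (diary), 25%
(daily sleep report). These were chosen once to land the synthetic
adherence near the >80% regime of engaged remote cohorts and to produce
both missingness regimes seen in real device data (whole-row absence vs.
speckled loss), including participants for whom a feature is missing in
all 12 weeks and therefore unrecoverable by within-participant
imputation.

## Problem sizes

The test suite's study-scale checks use one full-fidelity cohort of 200
participants × 12 weeks (~2.5 minutes to simulate and featurize), 20
weekly-level replicate cohorts of the same size for sign recovery, 200
one-week null cohorts of 40 participants for false-positive calibration,
and 20-seed label permutations of a 100-participant cohort for the
chance-level AUC check. The acceptance script runs one 60-participant ×
12-week full-fidelity cohort. These sizes give stable pass/fail margins
for every property checked while keeping a complete run in the minutes
range.

## What the synthetic cohorts show — and what they don't

Passing tests establish that the pipeline implements its rules exactly
(filter boundaries, aggregation, clustering heuristics, screen and model
mechanics), that injected population-level effects are recovered with
their signs, and that the machinery is calibrated where its assumptions
hold. They do not establish anything about real smartphone data: the
generator's streams are conditionally Gaussian/Poisson around weekly
targets, its missingness is ignorable by construction (real missingness
plausibly correlates with severity), its GPS error model is stylized, its
diaries are token pools rather than language, and effect sizes were
injected, not discovered. Real-data correlations of this kind are an
order of magnitude smaller than the demo's, and pooled-week inference on
real cohorts inherits the anti-conservatism described above.

## Known limitations

- The pooled univariate screen is anti-conservative under within-person
  repetition (see Statistics); a mixed-effects screen is out of scope.
- DBSCAN parameters and several location definitions (entropy base,
  variance transform, work-share denominator) are package choices where
  the field has no single convention; all are exposed in config.
- Physical-activity classification from raw inertial signals is not
  implemented; the activity stream arrives pre-labeled per minute.
- The deterministic lexicon sentiment scorer is a reference
  implementation behind a pluggable interface, not a model of language.
- Single timezone per cohort; all hour-of-day heuristics are local-time
  rules.
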