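# Methods

`utitask` analyses two-alternative mouse-tracking classification data
in which participants sort food images into "tasty" vs "not tasty"
boxes at the top corners of the screen while the cursor is sampled at
100 Hz. The package turns raw cursor logs into trial-level conflict
measures, aggregates them into participant-level indices of the
unhealthy = tasty intuition (UTI) — the lay belief that healthiness and
tastiness of food trade off — and provides the inferential tools used
to validate such a task. A simulator generates complete synthetic
cohorts with known ground truth so every stage is testable without
collected data.

## Data model

Three CSV tables (UTF-8, comma separated, one header row) carry a
dataset:

* `samples.csv` — cursor samples `(participant_id, trial_id, t_ms,
  x_px, y_px)`. `t_ms` is rebased so the first retained sample of each
  trial is 0: tracking starts when the cursor leaves the start button
  and ends at the response click.
* `trials.csv` — stimulus id, food type (healthy/unhealthy), the
  classification made, response side, presentation order, and the
  observed start/click pixels.
* `participants.csv` — demographics, condition, the three explicit
  UTI items (1–7) and K food-frequency items (1–8; default K = 20).

No raw-export dialect of any particular experiment builder is parsed;
the three-table layout is this package's interchange convention.
`validate_dataset` checks all cross-table invariants (sample
monotonicity, orphan trials, side/classification consistency, scale
ranges) and reports violations rather than raising, so a single pass
yields a complete audit.

## Trajectory preprocessing

Each trial is mapped per-trial into a unit frame anchored at the
*observed* cursor positions: the start-button exit point becomes
(0, 0) and the click pixel becomes (−1, 1) for a left response or
(1, 1) for a right one. Each axis scales independently, which also
flips the downward screen y axis so that "up" is positive. Left-ending
paths can be mirrored onto the right (`mirror_to_right`, idempotent)
for averaging and plotting.

Spatial normalisation resamples a path at 101 points equally spaced
along its cumulative arc length (0–100 % of the movement distance) by
linear interpolation; endpoints are preserved exactly and inserting
collinear vertices changes nothing. Temporal normalisation
interpolates x and y at 101 equally spaced times and is the input
convention for sample entropy. Trials with zero horizontal/vertical
extent or zero path length are flagged degenerate and excluded from
metrics with their rows retained, since such trials carry no geometry.

## Trial metrics

* **Reaction time** — last minus first timestamp (ms); the first
  sample is at movement onset by construction.
* **Signed maximum absolute deviation (MAD)** — the largest
  perpendicular point-to-line distance between the 101-point
  arc-length path and the straight chord through its first and last
  points. The deviation of maximal magnitude is reported, signed
  positive when that point lies on the side of the chord facing the
  *non-chosen* response box (the conflict direction). MAD is computed
  in the pixel frame (the conventional reporting unit, px) and also in
  the unit frame. Point-to-line rather than point-to-segment distance
  is used, matching the chord definition.
* **Sample entropy** — SampEn(m, r) = −ln(A/B), where B counts pairs
  of length-m templates within Chebyshev tolerance r and A the same
  for length m + 1, self-matches excluded; r = r_frac × SD of the
  series. Defaults m = 2, r_frac = 0.2. The series analysed is the x
  coordinate of the time-normalised path — lateral motion is where
  response competition expresses itself; this choice (and both
  parameters) are package conventions and configurable. Degenerate
  cases (zero SD, no matches) return 0 with a flag.

Average trajectories (pointwise means of unit-frame, mirrored,
arc-length paths) support the usual healthy/unhealthy visual
comparison.

## Participant indices

Trial exclusion follows the preregistered 3-SD rule: the mean and SD
are computed once over all non-degenerate trials of the whole sample
(grand pooling, no iterative re-trimming). RT is excluded on both
tails ("slower and faster"), MAD on the upper tail of the signed
value; both rules and k = 3 are configurable. Excluded trials are
flagged, never dropped, so exclusion reports can audit counts and
bounds.

The UTI difference scores are ΔRT = mean RT(healthy) − mean
RT(unhealthy) and ΔMAD likewise, over retained trials; positive values
mean costlier processing of healthy foods. Deltas are undefined (NaN,
participant retained) when a food-type cell is empty. The explicit
score is the mean of the three 1–7 items; internal consistency is
available via Cronbach's α = k/(k−1)·(1 − Σ item variances / variance
of sums). A descriptive median split labels scores strictly above the
median "high" (ties low); all confirmatory statistics use the
continuous score.

The diet quality score (DQS) summarises the FFQ into five components,
each scored 1–3 from configured frequency thresholds, summed to 5–15
(higher = healthier). Because the underlying guideline tables are not
part of this package's sources, a documented default configuration
ships (five components of four items; healthy components score 3/2/1
at item-mean ≥ 5 / ≥ 3 / < 3, the two unhealthy components
reverse-scored at ≤ 2 / ≤ 4 / > 4) and any component→item map can be
supplied as YAML.

## Inferential harness

Scalar statistics are implemented directly from their standard
formulas — Pearson r with the t-based two-sided p, Welch's t with
Satterthwaite df, Cohen's d with pooled SD and the
normal-approximation CI (SE² = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))), the
nested-model F-change — and are cross-checked in the test suite
against independent library evaluations (scipy, statsmodels' ANOVA,
pingouin) to 1e-10.

Trial-level models use crossed random intercepts for participant and
stimulus. Linear mixed models are fitted by REML via statsmodels'
`MixedLM` with a variance-component encoding of the two crossed
factors; the fixed part is the full food type × classification ×
standardized-explicit-score factorial plus indicator-coded demographic
covariates (most frequent level as reference). Coefficient p-values
use the normal approximation on estimate/SE; no denominator-df method
is imposed. Non-convergence is reported in the fit object, never
silently replaced. The explicit score is z-scored over the
participants in the analysis sample so slopes read "per 1 SD".

Simple-slope contrasts (the healthy−unhealthy difference of the UTI
slope within each classification) are linear combinations of fixed
effects; with indicator coding the contrast at classification c is
β_uti:food + c·β_uti:food:cls, with the SE from the corresponding
quadratic form of the coefficient covariance and a z test.

The classification model (tasty = 1) is a logistic mixed model with
the same crossed intercepts, estimated by variational Bayes
(statsmodels `BinomialBayesMixedGLM`); a constant outcome is refused
as degenerate. Incremental validity uses nested OLS: DQS on
covariates + explicit score, with and without a behavioural index, and
the F-change ((RSS_r − RSS_f)/1)/(RSS_f/df_f); exact collinearity of
the added column is reported as a singular flag.

Power analysis for a correlation uses the Fisher-z closed form
n = ⌈((z_{1−α/tails} + z_{power}) / atanh|r|)² + 3⌉; r = .21, two-tailed
α = .05, power .90 gives n = 235.

## Synthetic cohorts

Each simulated agent carries a latent trait u ~ N(0, 1). A goal
manipulation ("hedonic" condition) adds a state activation to the
*effective* trait, u* = u + 0.5, leaving the trait itself — and hence
the explicit scale — unchanged; this encodes the view that self-report
captures the stable belief while the task is context-sensitive.

* **Choice**: P(tasty) = logistic(1.4 + 0.2·[unhealthy] −
  1.0·max(u*, 0)·[healthy]). Healthy acceptance falls with the trait;
  unhealthy items are unaffected (≈ 80 % tasty), reproducing the
  asymmetric classification pattern typical of this task.
* **Conflict**: c = softplus(0.5 + 1.0·max(u*, 0)·[healthy, tasty] +
  1.5·[not tasty]). Trait-driven conflict loads only on trials where a
  healthy item is affirmed as tasty — the diagnostic cell — while "not
  tasty" responses are uniformly harder for everyone. The rectifier
  max(u*, 0) expresses that only agents who actually hold the belief
  experience the conflict, mirroring the choice channel; it also makes
  the conflict channel convex in the trait, so a state activation
  shifts behaviour more than the same-sized cross-sectional slope
  would suggest.
* **Motor model**: movement duration = (900 ms + 350 ms·c +
  stimulus offset) × agent factor × lognormal(σ = 0.25) trial noise.
  The cursor steps toward the chosen box every 10 ms so as to arrive
  on time, while a lateral pull toward the competing box (total
  impulse 95 px·c, decaying linearly over the first half of the
  movement) bends the path and per-step Gaussian jitter (σ = 16 px)
  roughens it. The final sample is the click pixel. Small per-agent
  speed factors (lognormal σ = 0.10) and per-stimulus duration offsets
  (σ = 20 ms) give the crossed random intercepts real content.
* **Questionnaires**: explicit items are clip(round(4 + 1.2u + N(0,
  0.8)), 1, 7) (α ≈ 0.85); FFQ responses are constructed by inverting
  the default DQS config so that the score tracks clip(10 − u +
  N(0, 2.5), 5, 15) — a generator convenience, not a claim about how
  real questionnaires arise.

Defaults reproduce the validation studies' design (10 + 10 stimuli
shown twice → 40 trials, 1920×1080 screen, start button bottom-centre,
response boxes top corners, tasty on the left). Effect and noise
magnitudes were fixed once so that the end-to-end pipeline recovers an
explicit–ΔMAD validity correlation centred near .3–.45 — the magnitude
regime reported for explicit–implicit agreement — while a 0.5 state
activation in a 100-per-arm two-group experiment reproducibly yields
the positive ΔRT/ΔMAD shifts and the healthy-tasty choice drop. RT
trial noise makes Δ-score SDs land near the ~140 ms scale observed in
such tasks. With all trait coefficients zeroed the pipeline's
uti × food-type test is calibrated (≈ 5 % false-positive rate).

All randomness flows from one seed sequence with per-agent spawned
substreams, so cohorts are bit-identical under a fixed seed and stable
under parallel generation. The ground-truth table (u, u*) is emitted
separately and never feeds the public tables.

### What the generator does not emulate

Real cursor data contain pauses, re-entries, hardware quantisation,
device/DPI heterogeneity, learning and fatigue across trials, and
stimulus-specific appeal beyond a scalar trait; RTs here are
symmetric-lognormal around a planned duration rather than genuinely
skewed decision-time mixtures, and demographic covariates carry no
behavioural effects. Passing recovery tests therefore demonstrates
that the *pipeline* is correct and sensitive at realistic
signal-to-noise ratios — not that the generative model is a faithful
account of human reaching.

## Numerical choices and degenerate inputs

Resampling tolerances: equal arc spacing to 1e-6 relative; endpoint
preservation exact. MAD sign ties (extreme point exactly on the chord)
take the positive orientation. Sample-entropy degenerate cases return
0 with a flag rather than ±inf. The exclusion rule requires ≥ 2
non-degenerate trials (SD undefined otherwise). Mixed-model fits use
L-BFGS with statsmodels defaults; `converged` is part of the fit
object. Median-split ties go to "low". The simulator refuses
non-positive design counts, unknown conditions, and pathological
configs whose trajectories would exceed a hard step cap.

## Test problem sizes

The heavy test suites use the sizes that make their claims meaningful
while staying practical on one CPU: recovery and condition suites run
20 cohorts of 200 participants (the validation-study scale); the null
calibration uses 200 reduced cohorts (30 participants, one repetition)
with the index-level uti × food-type test, whose rejection rate under
the null is the same quantity the trial-level interaction targets.
Parameter-recovery tests for the mixed models simulate directly from
the linear model (60 participants × 16 stimuli), independent of the
cohort generator.

## Known limitations

Mixed-model p-values are asymptotic (no Satterthwaite/Kenward-Roger
df); the logistic mixed model is variational (posterior SDs can be
mildly optimistic); no area-under-curve, x-flips or velocity-profile
metrics; no imputation of missing questionnaire items; the DQS default
thresholds are a package convention to be replaced by the user's
guideline tables when scoring real questionnaires.
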