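# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `rehabtrack`, and what the synthetic-data validation does and
does not establish.

## Coordinate and landmark conventions

Landmark streams follow the 33-point BlazePose topology. `x` and `y` are
image-normalized (origin top-left, `y` increasing *downward*), `z` is a
relative hip-centred depth, `visibility` a confidence in [0, 1]. All angle
mathematics is convention-independent (angles are invariant to rigid
transforms and to reflection of an axis), so the y-down convention never
needs correction. By default angles are computed in the 2-D image plane
(`dims=2`) — the sagittal or frontal camera view is assumed roughly
perpendicular to the movement plane — with `dims=3` available when depth is
trustworthy.

A landmark is treated as unreliable below visibility 0.9 ("high confidence"
cut of common pose estimators). The default handling policy is `hold_last`
rather than `drop`, because angle traces must stay contiguous for the
hysteresis counter; `interpolate` is available for offline use and falls
back to `hold_last` when fewer than two confident frames exist.

## Joint angles

A joint angle is defined by a (start, vertex, end) landmark triple. All
three built-in exercises use the hip–knee–ankle triple of the exercising
side (vertex = knee): it is the only triple the source workflow states
explicitly, and per-exercise triples are fully configurable in
`ExerciseSpec` for clinicians who prefer e.g. shoulder–hip–knee for hip
flexion.

Two formulations are implemented as separate code paths — the vector
dot-product rule and the law of cosines on pairwise distances — and their
agreement to 1e-9° on random non-degenerate triples is a standing test.
Numerical choices:

* cosine arguments are clamped to [−1, 1] only within a tolerance of 1e-9;
  a larger violation (inconsistent side lengths) raises instead of
  silently clamping;
* zero-length vectors / coincident landmarks raise a degenerate-geometry
  error at the scalar API and yield flagged NaN frames in trace mode —
  never unflagged NaN;
* near-collinear triples are intrinsically ill-conditioned for the
  distance-based formulation (arccos has unbounded derivative at ±1), so
  the 1e-9° equivalence claim excludes a 1e-6 neighbourhood of cos θ = ±1;
* optional smoothing is a centered moving average of odd width (default 1,
  i.e. off); degenerate frames are excluded from the average.

## Status bands

Five ordered bands ST < LOW < OKAY < GOOD < PERFECT grade the instantaneous
angle. Band intervals are half-open `(lower, upper]` — "less than or equal"
on every upper edge — with the best band closed at its extreme, so the
bands tile [0, 180] exactly; a fine-grid test against an independently
hand-written oracle checks every boundary (15, 30, 60, 100, 130).

Hip flexion: ST > 130°, LOW (100, 130], OKAY (60, 100], GOOD (15, 60],
PERFECT ≤ 15°. Hip external rotation: identical except GOOD (30, 60],
PERFECT ≤ 30°. Knee extension improves with *increasing* angle and only its
two trajectory thresholds (95° and 160°) are given upstream; the package
default mirrors the same five-step progression across them — ST ≤ 95°,
LOW (95, 115], OKAY (115, 140], GOOD (140, 160], PERFECT > 160° — and is
explicitly a repo-defined default, overridable in `ExerciseSpec`.

Angles are graded against the rest-near-180° biofeedback convention (a
seated leg at rest reads ≈ 170°); no re-zeroing at the neutral position is
applied.

## Repetition counting

Counting uses hysteresis thresholds *separate* from the status bands,
because both sets exist upstream: hip flexion counts a repetition on
>160° → <15° → >160°, hip external rotation on >150° → <30°, knee extension
on <95° → >160°. Region entry must persist `min_rep_frames` consecutive
frames (default 3 at 30 fps) so a single-frame noise spike never counts;
NaN frames break debounce runs.

A repetition's window closes at the frame of re-entry into the start
region. Its start is anchored at the end of the previous repetition (or
the first confirmed start-region frame), so the window covers the full
excursion *including the dwell at the resting extreme*. This matters for
ROM: a window that began only when the angle left the start region would
clip the resting plateau and under-report ROM by the width of the start
region (≈ 8° for the defaults). With the anchored window, zero-noise
synthetic sessions recover the commanded ROM exactly.

ROM is defined as max θ − min θ over the repetition window; per-session
summaries report mean/median/SD (n−1) with a t-based 95% CI.

## k-NN terminal-state classification

The pose embedding is the 2-D coordinates of 12 torso + lower-limb
landmarks (shoulders, hips, knees, ankles, heels, foot tips), translated so
the mid-hip is the origin and scaled so mid-hip→mid-shoulder is unit length
— exactly translation- and scale-invariant, not rotation-invariant (camera
roll is assumed small). k = 10 by default, which makes the per-class vote
count directly a 0–10 confidence scale. Class probability is votes/k.

Determinism: neighbours are ordered by (distance, insertion index);
class-vote ties are broken by smaller mean neighbour distance, then
lexicographic class name. An exhaustive-search oracle equivalence over
random small datasets is a standing test; scikit-learn's
`KNeighborsClassifier` serves as an additional independent cross-check on
tie-free data and for precision/recall bookkeeping, never as the
implementation.

Sequence classification smooths the vote counts with an exponential moving
average (α = 0.2 by default; α = 1 is the identity). The
classification-based counter counts a rise of the target-state confidence
through an enter threshold (default 8/10) after having been at or below an
exit threshold (default 2/10); it starts armed.

## Evaluation statistics

MAE, MSE and RMSE are computed by their definitions over predicted−actual
differences; `use_reported_errors` evaluates a stored error column verbatim
instead, for tables whose published error column is the quantity of record.
The bundled nine-row worked-example table contains one row whose printed
error (4.95°) does not equal its predicted−actual difference (12.95°); the
package preserves the table as printed and computes both views rather than
repairing it. R² is the standard 1 − SS_res/SS_tot and is undefined (error,
not NaN) at zero total variance.

The ICC is the one-way random-effects ICC(1,1),
(MSB − MSW) / (MSB + (k̄ − 1) MSW) with k̄ the mean group size. The
upstream description names only "a linear mixed effects model"; for the
balanced random-intercept case the one-way ANOVA form is identical, and it
matches `pingouin`'s ICC(1,1) to machine precision in the tests.

## Synthetic data generator

The generator emulates a seated subject in a 2-D planar linkage (trunk,
thigh, shank, foot; hip anchored; thigh horizontal) whose hip–knee–ankle
angle follows a commanded profile: per repetition, an ease (smoothstep by
default, sinusoid optional) from the resting angle to the target angle and
back, with 0.5 s dwells at both extremes, 4 s per repetition, 30 fps.
Default profiles span each exercise's counting condition with margin:
hip flexion 170°→10° (ROM 160°), hip external rotation 170°→20°, knee
extension 85°→170°. Non-articulated landmarks (face, arms, resting leg) are
emitted at plausible static positions so files are schema-complete.

Noise is modelled as (i) Gaussian jitter on the commanded angle (degrees),
(ii) Gaussian jitter on every landmark coordinate (normalized units,
default assumption 0.003 when enabled), and (iii) per-frame visibility
dropout of the exercising leg. These are stated assumptions about
pose-estimator error, not measurements of it. All randomness flows from an
explicit seed; identical configuration and seed give byte-identical files.

Cohorts use a two-level ROM distribution — per-subject ROM from
N(mean, between-SD²), per-repetition jitter N(0, within-SD²) — seeded
deterministically from one master seed. The validation cohort shape is 30
subjects × 2 legs × 10 repetitions (600 repetitions), the size used in the
motivating reliability analysis. The reliability simulation uses
between-SD 16°, within-SD 1.6° around a 40.2° mean, whose analytic ICC is
16²/(16² + 1.6²) ≈ 0.990; because a 40° ROM cannot satisfy the full-range
counting condition, per-repetition ROMs for the ICC are extracted from the
computed angle trace over the generator's ground-truth repetition windows,
while counting-based extraction is validated separately at full ROM.

Ground truth (repetition windows, commanded ROM, commanded angle series) is
carried alongside every generated sequence; tests never re-derive truth
from the generated data.

### What the synthetic validation does and does not show

Passing the synthetic suite establishes that the geometry, grading,
counting and classification layers are internally correct and mutually
consistent, and that the pipeline is robust to Gaussian jitter of the
magnitudes modelled. It does not establish performance on real video:
pose-estimator errors are structured (occlusion, depth ambiguity, clothing),
real movement is not a clean ease curve, and clinical populations move with
tremor, compensation and incomplete excursions. Published classification
accuracies on clinical recordings are therefore not targets of this
package's tests.

## Problem sizes

The default test suite and the acceptance script run the full 60-session
cohort (≈ 73k frames, ≈ 2.4M landmarks) plus a second 60-session reliability
cohort; each completes in well under a minute on one CPU, chosen so the
whole validation is routinely re-runnable.

## Known limitations

* 2-D angles assume the camera is roughly perpendicular to the movement
  plane; out-of-plane rotation biases angles (hip external rotation from a
  frontal view is approximated by the same planar model).
* The embedding is not rotation-invariant; heavy camera roll degrades k-NN
  accuracy.
* Single person per stream; no multi-person tracking or re-identification.
* The knee-extension band partition between its two printed thresholds is a
  package default, not an upstream prescription.
* `hold_last` visibility handling can freeze an angle during long
  occlusions; the mask output should be consulted for reporting.
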