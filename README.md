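# rehabtrack

Camera-based tracking of seated lower-limb rehabilitation exercises from
body-pose landmark streams.

Post-stroke rehabilitation relies on repeated, measured lower-limb movements
— seated hip flexion, hip external rotation and knee extension — whose
quality is traditionally judged by a therapist with a goniometer and a
tally. `rehabtrack` takes the output of a commodity pose estimator (the
33-keypoint BlazePose topology, one frame of `x, y, z, visibility` per
landmark) and turns it into quantitative, reproducible session reports for
clinicians and for telerehabilitation pipelines:

* **Joint angles.** The hip–knee–ankle angle θ at the knee vertex is
  computed per frame from the landmark triple, via the dot-product rule
  θ = arccos(**a**·**b** / |**a**||**b**|) with **a** = hip−knee,
  **b** = ankle−knee, cross-checked by the law of cosines
  cos A = (b² + c² − a²) / 2bc on the pairwise distances. Angles live in
  [0°, 180°].
* **Fuzzy status bands.** θ is graded into five ordered bands —
  ST (starting position), LOW, OKAY, GOOD, PERFECT — by exercise-specific
  thresholds (hip flexion: ST > 130°, LOW (100, 130], OKAY (60, 100],
  GOOD (15, 60], PERFECT ≤ 15°; hip external rotation ends at 30° instead
  of 15°).
* **Repetition counting with hysteresis.** One repetition = the angle leaves
  the start region (θ > 160° for hip flexion), reaches the target region
  (θ < 15°) and returns, with a frame-count debounce against jitter. Each
  repetition's range of motion (ROM = max θ − min θ over its window) is
  reported with mean/median/SD summaries.
* **k-NN terminal-state classification.** Frames embedded as
  translation/scale-normalized landmark coordinates are classified into
  exercise terminal states ("up"/"down") by k-nearest neighbours
  (Euclidean distance, k = 10), giving a 0–10 vote-confidence trace and an
  independent, classification-based repetition count.
* **Validation statistics.** MAE / MSE / RMSE and R² for predicted-vs-measured
  angle tables, and the one-way random-effects intraclass correlation
  coefficient ICC(1,1) for ROM test–retest reliability.
* **Synthetic kinematics.** A forward-kinematic planar body model generates
  exercise sessions, cohorts and labelled pose datasets with known ground
  truth (repetition windows, commanded ROM, seeds), so the whole pipeline is
  testable without clinical video.

## Worked example

```python
import rehabtrack as rt

# a zero-noise synthetic session: 10 hip-flexion reps, 170° -> 10° -> 170°
seq, truth = rt.generate_session(rt.default_profile("hip_flexion"))
report = rt.run_session(seq, rt.default_spec("hip_flexion"))
print("frames:", len(seq))
print("repetitions:", report.rep_count)
print("ROM (deg), first 3 reps:", [round(r, 2) for r in report.rom_series[:3]])
print("best band per rep:", {r.best_band.name for r in report.repetitions})

# error statistics of the bundled predicted-vs-measured angle table
pairs = rt.load_worked_example()
m = rt.error_metrics(pairs, use_reported_errors=True)
print("MAE %.4f  MSE %.4f  RMSE %.4f" % (m["mae"], m["mse"], m["rmse"]))
```

prints

```
frames: 1215
repetitions: 10
ROM (deg), first 3 reps: [160.0, 160.0, 160.0]
best band per rep: {'PERFECT'}
MAE 2.4144  MSE 7.8135  RMSE 2.7953
```

The session recovers exactly the commanded 10 repetitions and the commanded
160° range of motion, and every repetition reaches the PERFECT band. The
error metrics are computed over the nine-row worked-example table shipped
with the package (`use_reported_errors=True` evaluates the table's error
column as reported; note that the column is not identical to
predicted − actual in every row, which is why both computations are
offered).

The same pipeline is available from the shell:

```sh
rehabtrack simulate --exercise hip_flexion --reps 10 --seed 3 --out-dir demo
rehabtrack track --input demo/landmarks.jsonl --exercise hip_flexion --out-dir demo/run
# -> "hip_flexion (left): 10 repetitions", plus report.json, frames.csv and
#    a ROM-per-repetition plot under demo/run/
```

`rehabtrack classify` produces per-frame confidence traces from a trained
pose dataset, and `rehabtrack evaluate` computes the angle-error and ICC
statistics from CSV files.

## Scope

The package assumes an upstream pose estimator (or pre-extracted landmark
files in the documented JSONL/CSV dialects); it does not train or run the
pose-estimation network itself, does not track multiple people, and does not
attempt clinical scoring beyond the band/threshold rules above. See
`docs/methods.md` for the model details, parameter defaults and known
limitations.
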