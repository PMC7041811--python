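# equispine

Spinal kinematics of trotting horses from optical motion capture: per-stride
range of motion (ROM) of back and pelvic angles, condition-wise percentile
summaries, an offset-adjusted between-measurement variability model, and
intraclass correlation coefficients (ICC) for repeatability.

## Who this is for

Clinical assessment of equine back motion is notoriously subjective.  Making
it objective requires knowing, for sound horses trotted over-ground, (a) the
normal range of motion of each spinal parameter, (b) how much a repeated
measurement of the *same* horse varies, and (c) how repeatable each
parameter is.  `equispine` implements that full measurement chain, from
labelled 3-D marker trajectories (head, withers, T12–S5 dorsal spine
markers, tuber sacrale and both tubera coxae) to the three statistical
summaries, for the four standard trot-up conditions: hard straight, soft
straight, and left/right lunge circles on soft footing.

## The measurement chain

**Kinematics.**  Marker coordinates (mm, +z up, 100 Hz typical) are
low-pass filtered (zero-phase 4th-order Butterworth, 30 Hz).  A per-frame
horse frame is built from the smoothed velocity of the tuber sacrale marker
(x̂ = direction of travel, ẑ = up, ŷ = ẑ×x̂), so straight lines and circles
are handled uniformly.  On the circle the projection planes are corrected
for the body lean angle, taken as the stride-mean pelvic roll.  Angles are
projection angles: pelvic roll/pitch/yaw in the frontal/sagittal/dorsal
planes from the pelvic marker triad; whole-back flexion-extension and
lateral bending as the angle between the withers–T15 and T15–tuber sacrale
segments (segmental angles analogously from the adjacent markers); body
tracking and head swivel in the dorsal plane; speed by smoothed
differentiation of the tuber sacrale track.

**Strides.**  At trot the sacrum bounces twice per stride while pelvic roll
completes one cycle; stride boundaries are the sacrum-height minima at
which pelvic roll is increasing.  Per stride, ROM parameters take max−min
and signed parameters (head swivel, body tracking, speed) the mean; trials
with five or fewer complete strides are discarded; strides containing
marker gaps are dropped, never interpolated.

**Statistics.**  With measurement means `v_him` (horse h, condition i,
measurement m = 1…12 over three days):

* percentiles: 5 % / median / 95 % pooled over horses and repetitions per
  condition;
* variability model: deviations `d = v − mean_m(v)` per horse×condition
  cell, outcome `y = √|d|`, linear mixed model
  `y ~ day + repetition + path + surface + (1 | horse)` by REML (optional
  linear speed term), and per-condition 95 % prediction upper limits
  back-transformed as `(x'β̂ + z₀.₉₇₅·√(σ̂²_horse + σ̂²_resid))²`;
* repeatability: one-way ICC(1) = σ²_horse / (σ²_horse + σ²_resid) per
  parameter × condition.

A synthetic module generates marker-level trot motion with prescribed angle
waveforms (flexion-extension at twice stride frequency; lateral bending,
axial rotation, pelvic roll at stride frequency) and study-level datasets
with known variance components, so every stage is tested against exact
ground truth.  See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
from equispine import (MarkerConfig, analyze_trial, simulate_trot_markers)
from equispine.synthetic_data import TrotSimConfig

cfg = TrotSimConfig(noise_sd_mm=0.0)          # noise-free straight-line trot
series = simulate_trot_markers(cfg)           # 13 labelled markers, 100 Hz
result = analyze_trial(series, MarkerConfig.identity())
rec = result.record
print(len(result.segmentation), round(rec["stride_duration"], 3),
      round(rec["speed"], 2))
print(round(rec["back_flex_ext"], 3), round(rec["pelvis_roll"], 3),
      round(rec["head_swivel"], 3))
```

prints

```
14 0.75 3.79
4.979 9.658 -1.28
```

i.e. 14 segmented strides of 0.75 s at 3.79 m/s, a whole-back
flexion-extension ROM of 4.98° (= 2× the prescribed 2.49° amplitude), a
pelvic roll ROM of 9.66° (2 × 4.83°) and the prescribed −1.28° mean
cervical bend — the generator/analyzer closure that the test suite checks
throughout.

Study-level, with a simulated 12-horse dataset:

```python
from equispine import simulate_measurement_dataset, percentile_summary
from equispine.synthetic_data import StudySimConfig
from equispine.variability_model import (offset_adjust,
                                         fit_variability_model,
                                         prediction_upper_limits)

records = simulate_measurement_dataset(StudySimConfig(seed=2))
devs = offset_adjust(records, params=["back_flex_ext"])
fit = fit_variability_model(devs, "back_flex_ext")
print(prediction_upper_limits(fit))
```

gives per-condition 95 % prediction upper limits for the
between-measurement variation of whole-back flexion-extension (about
0.8–0.9° under the default simulated variance components), plus their
arithmetic mean (`mean_variation`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole chain from scratch: it simulates trot-ups on all four
conditions and runs the marker-level pipeline (stride counts, speeds, ROMs,
lunge circle diameters), then simulates a full repeated-measures study and
prints the condition percentiles, the variability-model prediction limits
with recheck-day p-values, and the ICC table with column means.  All
randomness derives from `--seed`.
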