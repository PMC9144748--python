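# Methods

## Problem and pipeline

`gaitcount` estimates the number of steps in a walk from smartphone
tri-axial acceleration alone, while staying accurate across carrying
positions (handheld, trouser pocket, handbag).  Supervision comes from a
second, training-time-only channel: plantar force from a single
force-sensitive resistor under the toe of one shoe.  During stance the
sensor is loaded and during swing it is not, so each ground contact is a
force pulse and the step count is the number of pulses — an automatic
labeling scheme that scales to long recordings.

The processing chain is:

1. **Magnitude.** The Euclidean norm √(x²+y²+z²) of the raw acceleration
   (gravity included) removes dependence on phone orientation; no
   gyroscope or magnetometer is used (they cost power and are
   unnecessary here).
2. **Smoothing.** A 5-tap equal-weight moving average (half-width 2) on
   both channels.  Edge samples use a shrinking *symmetric* window
   (sample `i` averages `min(2, i, n-1-i)` neighbours per side): output
   length equals input length, constants are preserved everywhere, and
   no zero-padding artifacts appear — zeros at the edge of a pressure
   trace would look like spurious swing phases.
3. **Clipping (pressure only).** The sensor's usable range is 0.05–6 kg;
   readings below 0.5 N are set to 0 N and above 60 N to 60 N.  Clipping
   models the physical sensor and is therefore applied *before* the
   software filter.
4. **Step detection.** An event fires at each upward crossing of 30 N,
   with a 0.2 s refractory period.  30 N is half the sensor range and
   above almost all insole noise; walking cadence bounds true
   inter-contact intervals to roughly 0.3–1 s, so crossings faster than
   0.2 s are noise.  "Peak" is operationalised as a threshold crossing
   rather than a local-maximum search: it needs no look-ahead, and the
   refractory period already de-duplicates any jitter around the
   crossing.  Event time is the timestamp of the crossing sample — at
   30 Hz the 33 ms quantisation is far below the refractory period, so
   interpolation would add nothing.
5. **Windows.** 2 s windows (60 samples at 30 Hz — at least one full
   gait cycle over the whole 0.5–3 Hz walking band) advanced by 50 % of
   the window.  Features are the raw 60 filtered-magnitude samples; the
   label is the number of detected events in the window's half-open
   `[start, end)` time span, so an event on a shared boundary is counted
   exactly once per tiling.  Trailing partial windows are dropped, not
   padded: padding fabricates signal and biases labels downward.
   Feeding the raw sample vector (rather than hand-crafted statistics)
   to *all* learners is the largest inferential design choice in the
   package; a practitioner can append summary features externally, but
   the defaults keep a single representation for every model.
6. **Two-stage model.** A position classifier (default: random forest,
   200 trees, depth cap 200) predicts each window's carrying position;
   a per-position bank of regressors (default: random forest with 500
   trees, linear-kernel SVR, MLP) predicts each window's step count.
   The *ensemble* regressor is the weighted average of SVM, MLP and
   random forest, uniform weights by default; `fit_ensemble_weights`
   optionally sets weights proportional to each component's aggregate
   validation accuracy.  Predictions are floored at zero.  With a convex
   weight vector the ensemble prediction always lies within the range of
   its components.

### Whole-recording aggregation

Overlapping windows each predict a per-window count, so summing them
over-counts by the coverage factor.  Each sample in the interior of a
recording is covered by `window_len / stride` windows (2 at 50 %
overlap), while the first and last `window_len − stride` samples are
covered once.  The total is therefore

    total = Σ pred · stride/window_len
          + (overlap/window_len) · (pred_first + pred_last)/2,

rounded to an integer.  The edge term makes the estimator exact in the
single-window case (total = rounded prediction of that window) and
unbiased in the interior.  Position routing is per-recording by default:
the classifier votes on every window and the majority position routes
them all, matching the fact that a phone's placement is fixed within a
walk; per-window routing is available via `routing="window"`.

### Train/test protocol

`split_dataset` partitions windows 7:3.  `random` mode shuffles windows
(exact counts, seeded).  The default `chronological` mode cuts each
recording by time and drops the train-side windows that straddle the
cut, because 50 %-overlap windows otherwise leak half their samples from
train into test.  Chronological splitting is the honest protocol for
time-series data and is the one used in the acceptance runs.

## Learners

| algorithm | classifier defaults | regressor defaults |
|---|---|---|
| random_forest | 200 trees, max depth 200 | 500 trees |
| hist_gradient_boost | library defaults | library defaults |
| svm | linear kernel | linear kernel (SVR) |
| mlp | 4 hidden layers, 920 units total | same |
| knn | library defaults | library defaults |
| cnn | 2 conv + 2 pool + 1 dense | 4 conv + 4 pool + 2 dense |
| ensemble | — | weighted average of svm/mlp/rf |

The MLP's 920 units are split 460/230/150/80 (a tapering split; any
split summing to 920 is accepted via `hyperparams`).  SVM, MLP and KNN
are wrapped in a `StandardScaler` pipeline — magnitude windows sit
around 9.81 m/s² with position-dependent spread, and distance- and
gradient-based learners need centred inputs; tree models are
scale-invariant and are fed raw windows.

The CNN is a small numpy implementation (same-padded 1-D convolutions,
ReLU, width-2 max pooling, dense head) trained with Adam (lr 1e-3,
batch 64, up to 40 epochs) and early stopping on a 10 % validation
split with best-weight restoration.  Committed defaults: kernel width 5,
pool width 2; classifier channels (8, 16), regressor channels
(8, 16, 24, 32) with a 32-unit hidden dense layer.  Layer gradients are
verified against central finite differences in the test suite.
Regression targets are standardised internally and de-standardised at
prediction.

All learner seeds derive from a single `random_state`; identical data
and parameters give bit-identical predictions.

## Synthetic data generator

The simulator emulates the *signal structure* the pipeline relies on,
not gait biomechanics:

* **Step timing.** Quasi-periodic onsets at the scenario cadence with
  1.5 % step-to-step interval jitter (clipped at 3 SD).  Cadence must
  lie in the 0.5–3 Hz walking band; the defaults
  (`default_cohort_scenarios`) use 1.2/1.8/2.4 Hz, spanning slow to
  brisk self-paced walking.
* **Pressure.** One half-sine stance pulse per step, peak 50 N (below
  the 60 N ceiling), stance fraction 0.6 of the cycle, zero force in
  swing.  Optional artifacts (default 2/min) are half-sine blips of
  5–25 N placed at least 3 samples clear of any stance pulse, so they
  stay below the 30 N threshold even after smoothing — they exercise the
  detector's noise rejection without changing the true count.
* **Acceleration.** Gravity (9.81 m/s²) along a position-specific device
  axis with a small random per-recording tilt, plus a phase-locked
  oscillation with position-specific harmonic content, plus white
  Gaussian noise (default SD 0.4 m/s² per axis).  The three position
  signatures are invented, chosen only to be statistically separable,
  and documented as synthetic: handheld is low-amplitude and smooth
  (0.7 m/s² fundamental), pocket is high-amplitude with a strong second
  harmonic (2.4 + 1.7 m/s²), handbag is pendulum-like — a 1.6 m/s²
  fundamental amplitude-modulated at half the step rate.
* **Determinism.** All randomness flows through one
  `numpy.random.Generator` seeded by the scenario; identical scenarios
  give byte-identical CSV output.
* **Truth.** Ground truth records every pulse onset, so simulator labels
  and pressure peaks coincide one-to-one.  A single toe sensor sees one
  foot's contacts; whether a "step" means one foot's contact or both
  feet's steps is a labeling convention, recorded explicitly by the
  `steps_per_peak` knob (default 1: peaks are the labels; it scales the
  reported truth only, never the signals).

What passing tests on this simulator shows: the pipeline's arithmetic,
the detector's threshold/refractory logic, leak-free windowing/splitting,
and the capacity of the two-stage model to exploit position-specific
structure.  What it does not show: performance on real gait, where
position signatures are messier, cadence drifts, sensors saturate
mid-stride, and the acceleration–pressure clock skew is nonzero.
Real-data accuracy claims cannot be transferred from these tests.

## Problem sizes

The acceptance run trains on the default cohort — 3 positions × 3
cadences × 7 minutes (21 minutes per position), ≈ 3 800 windows — with a
chronological 7:3 split, and evaluates the labeler on 45 ten-minute
recordings; unit tests use 2-minute recordings and shrunken learner
settings.  These sizes are the package's study conditions, chosen to be
comfortably estimable on a single CPU.

## Known limitations

* Walking only: no running, stairs, shuffling or non-locomotor motion;
  the model never rejects a window as "not walking".
* The window representation is fixed (raw 60-sample vectors); no
  learned or hand-crafted feature alternatives are built in.
* The classifier has a closed world of three positions; a phone on a
  table will still be assigned one of them.
* Eq-style relative accuracy is unclamped and goes negative when the
  estimate exceeds twice the truth (rendered with a footnote); cells in
  reports are unweighted means over recordings, regardless of recording
  length.
* Stream alignment (nearest timestamp within 50 ms) assumes both clocks
  are already roughly synchronised; it corrects jitter, not drift.
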