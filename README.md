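# gaitcount

Carrying-position-independent step counting for smartphone accelerometry.

Smartphone pedometers are unreliable because people carry their phones in
different places — in the hand, a trouser pocket, a handbag — and each
placement produces a different acceleration pattern for the same walk.
`gaitcount` implements a two-stage, position-aware step counter:

1. a **position classifier** identifies where the phone is being carried
   from 2 s windows of the acceleration signal, and
2. a bank of **position-specific regressors** predicts the number of steps
   in each window, using the regressor trained for the identified
   position.  The headline *ensemble* regressor is the weighted average of
   the linear-kernel SVM, the multilayer perceptron and the random forest.

Training labels come from a plantar-pressure channel (a force-sensitive
resistor under the toe): every stance phase produces a force pulse, so
steps are labeled automatically by threshold peak detection — no manual
counting.  Because the matched pressure/acceleration recordings such a rig
produces are not generally available, the package ships a synthetic gait
simulator that generates paired streams with known ground-truth step
events; it is first-class, tested code and drives the whole test suite.

## Model summary

For a tri-axial sample $(X, Y, Z)$ (m/s², gravity included) the pipeline
computes the orientation-free signal-vector magnitude

$$\mathrm{SVM} = \sqrt{X^2 + Y^2 + Z^2},$$

smooths it with an equal-weight 5-tap moving average
$A_t = (a_{t-2} + a_{t-1} + a_t + a_{t+1} + a_{t+2})/5$, and cuts the
result into 2 s windows (60 samples at 30 Hz) advanced with 50 % overlap.
The pressure channel is clipped to the sensor's usable range (readings
< 0.5 N → 0, > 60 N → 60), smoothed the same way, and step events are
detected at upward crossings of a 30 N threshold with a 0.2 s refractory
period.  Each window's label is the number of detected events in its
half-open time span.  Evaluation uses the relative step-count accuracy

$$\mathrm{accuracy}(\%) = \left(1 - \frac{|N_e - N_r|}{N_r}\right) \times 100,$$

with $N_e$ the estimated and $N_r$ the real step count.

Available learners for either stage: random forest, 1-D CNN
(a small numpy implementation included in the package), histogram
gradient boosting, MLP, linear-kernel SVM, k-nearest neighbours, and the
weighted-average ensemble. See `docs/methods.md` for defaults and
numerical choices.

## Worked example

```python
import gaitcount as gc

# nine simulated walks: 3 carrying positions x 3 cadences, 2 min each
scenarios = gc.default_cohort_scenarios(duration_s=120.0, base_seed=1)
recordings = gc.generate_cohort(scenarios)

parts = []
for i, rec in enumerate(recordings):
    mag = gc.preprocess_accel(rec.accel)                            # |a| -> 5-tap MAF
    events = gc.detect_steps(gc.preprocess_pressure(rec.pressure))  # pressure labels
    parts.append(gc.make_windows(mag, events, rec.scenario.position, recording_id=i))
dataset = gc.WindowDataset.concatenate(parts)
train, test = gc.split_dataset(dataset, train_frac=0.7, mode="chronological")
print(f"{len(dataset)} windows -> {len(train)} train / {len(test)} test")

model = gc.EnsembleStepCounter(random_state=0).fit_dataset(train)
pos_acc = gc.classification_accuracy(model.classify_position(test.features),
                                     test.positions)
print(f"holdout position accuracy: {pos_acc:.1f}%")

fresh = gc.generate_walk(gc.GaitScenario(position="pocket", duration_s=300,
                                         step_freq_hz=1.8, seed=99))
total, votes = model.count_steps(fresh.accel)
print(f"counted {total} steps, truth {fresh.truth.count}, "
      f"accuracy {gc.step_accuracy(total, fresh.truth.count):.1f}%")
```

Output:

```
1071 windows -> 747 train / 315 test
holdout position accuracy: 100.0%
counted 536 steps, truth 540, accuracy 99.3%
```

The first line shows the sliding-window dataset and its chronological 7:3
split (the chronological cut drops boundary windows so train and test
share no samples).  The classifier identifies the carrying position of
every held-out window; the final line counts steps in a five-minute walk
the model has never seen, within 0.7 % of the simulator's ground truth.

`EnsembleStepCounter` follows the scikit-learn estimator protocol
(`fit(X, y, positions=...)`, `predict`, `get_params`/`set_params`), so it
composes with sklearn model-selection tooling.

A CLI mirrors the library (`gaitcount simulate | preprocess | label |
windows | train | count | evaluate`); see `gaitcount --help`.

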