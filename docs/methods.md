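# Methods

`fogbench` studies how training choices and recording conditions shape
window-level freezing-of-gait (FoG) detection from wearable inertial
sensors. This note documents the models, the synthetic cohort generator,
the numerical choices, and what the desk-scale experiments do and do not
demonstrate.

## Problem and protocol

A detector receives 2-s windows (256 samples at 128 Hz, six channels) of
inertial signal and predicts whether the window contains freezing.
Evaluation is leave-one-subject-out (LOSO): for each fold the model trains
on every subject but one and is scored on the held-out subject's windows —
the generalization setting any clinical tool faces. Reported metrics are
AUC (rank form, ties one half), F1, precision, sensitivity and accuracy,
aggregated as mean ± sample (n−1) SD across folds.

Two recording regimes are compared under identical protocols:

| | lab | daily_living |
| --- | --- | --- |
| freeze prevalence | 0.598 | 0.179 |
| native sampling rate | 64 Hz (upsampled ×2) | 128 Hz |
| noise SD (signal units) | 0.3 | 0.8 |
| label boundary jitter SD | 0 s | 0.5 s |
| subject heterogeneity | 0.10 | 0.35 |
| confounder pauses | none | 2 / min |

The *deployment gap* for a metric is `(lab − daily_living) / daily_living
× 100` on cross-fold means; the stability contrast is the SD ratio
`daily_living / lab` (undefined, rendered "—", when the lab SD is zero).
Performance tiers on the daily-living arm follow the F1 cut-points
excellent ≥ 0.70, moderate 0.50–0.69, poor < 0.50.

## Synthetic cohort generator

No public FoG corpus ships with this package; a seeded generator emulates
the *statistical contrasts* the analysis depends on. Normal gait is a
locomotion-band oscillation (fundamental ≈ 1.8 Hz plus a weak first
harmonic); freezing replaces most of it with 3–8 Hz "trembling" (≈ 5.5 Hz
fundamental), the classic freeze-index band contrast. White Gaussian noise
is added throughout. Episodes last 2–10 s and are scheduled so total
freeze time converges on the regime's prevalence target (residual error is
bounded by one minimum episode length over the recording). Subject
heterogeneity scales per-subject frequency, amplitude and channel-gain
variation; label jitter perturbs episode boundaries (not window labels),
emulating asynchronous expert review; confounder events attenuate the
signal briefly without changing labels, emulating non-freeze pauses.

What the generator does **not** emulate: biomechanically realistic gait,
physical sensor units and orientations, medication ON/OFF fluctuations,
activity diversity beyond amplitude pauses. Passing tests therefore show
that the pipeline's machinery reproduces the *directional* phenomena under
controlled contrasts — not that the effect sizes transfer to real
recordings, and not the real-data headline scores, which require the
external datasets.

## Preprocessing

Integer-factor upsampling by linear interpolation with the final sample
held; labels carried by nearest neighbour. Windows are contiguous slices
(length L = round(window_s × rate), stride L × (1 − overlap)); trailing
partial windows are discarded so the model input shape is fixed. The
window label rule is majority: 1 iff the freeze fraction strictly exceeds
0.5 (configurable threshold). Per-channel standardization statistics are
fit on training-fold windows only (SD floored at 1e−8) and carry
provenance tags listing the subjects they were fit on; the LOSO driver
refuses to apply statistics whose provenance contains the test subject.

## Network

A temporal convolutional network: four blocks with dilations 1, 2, 4, 8;
each block is two causal dilated 1-D convolutions (kernel 3) each followed
by batch normalization, ReLU and 30% dropout, wrapped in a residual skip
(1×1 projection in the first block where channel counts differ, identity
elsewhere; no post-addition activation). Global average pooling over time
feeds a linear head with two logits. Causal left-padding of
(kernel−1)×dilation per convolution makes output t depend only on inputs
≤ t; note that train-mode batch normalization couples time steps through
batch statistics, so the causality guarantee is stated for inference mode.

The receptive field of this configuration is 1 + Σ (kernel−1)×dilation
over all convolutions = 61 samples (≈ 0.48 s at 128 Hz), and the 64-channel
configuration has 89,282 trainable parameters; both values are verified in
tests against an impulse-response oracle and the built model's parameter
total, and are reported as computed.

The network is implemented directly on numpy arrays with hand-derived
backward passes and an Adam optimizer (L2 weight decay folded into the
gradient). Convolutions run as single large GEMMs over a
(channels, batch, time) layout. The test suite validates the full backward
pass against central finite differences in float64. Training is seeded and
single-threaded, hence bit-reproducible.

## Training plans

Three presets encode the imbalance-handling arms:

| plan | stopping | focal γ | class weights α | weighted sampling |
| --- | --- | --- | --- | --- |
| C | AUC | 1.5 | [0.18, 0.82] | yes |
| D | F1 | 1.0 | [0.30, 0.70] | no |
| E | F1 | 1.2 | [0.25, 0.75] | no |

Shared settings: Adam, learning rate 1e−3, weight decay 1e−4, batch 32, up
to 200 epochs, patience 30, 10% validation split. The focal loss is
−α(1−p)^γ log p with α selected by the window's true class and p clamped
at 1e−7. On majority-freeze cohorts (prevalence > 0.5) the class-weight
pair is reversed so the minority class keeps the larger weight. Weighted
sampling draws each epoch's windows with replacement, proportional to
inverse class counts, balancing expected class frequencies per batch.

The validation split is a stratified random *window* split within training
subjects (per class, round(n×frac) windows, at least one). A window-wise
split shares subjects between train and validation halves and is therefore
optimistically biased relative to a subject-wise split; it matches the
"fraction of windows" phrasing of the protocol and is the package default.
Early stopping monitors validation AUC or F1 at the 0.5 decision
threshold; improvements smaller than `min_delta` (default 0) do not reset
the patience counter, and the checkpoint restored is the earliest epoch
attaining the maximum of the monitored metric. A validation split that
degenerates to one class aborts the fold with an explicit error rather
than imputing a metric.

### Compound-amplification accounting

Each imbalance correction multiplies the effective minority-class
emphasis: the class-weight ratio (max/min of α), the sampling factor
(1−π)/π at minority prevalence π, and a focal-gain constant. The focal
gain for γ = 1.5 is a reported empirical factor (2.8), not derivable in
closed form; it is stored as configuration, used only by the accounting,
and counted as 1 for γ < 1.5. Plan C's stack compounds to
2.8 × 4.6 × 4.6 ≈ 60-fold emphasis (one significant figure); Plan D's to
≈ 2.3-fold. The 60-fold overcorrection is the mechanism behind Plan C's
failure signature: near-total recall with collapsed precision.

## Scaled-down study

The full-scale protocol (64 hidden channels, 200-epoch budget, 25–35
subjects) is far beyond a desk-scale test run. The package pre-registers
one scaled study in `fogbench.experiments` and uses it for both the test
suite and the acceptance script: 8 subjects × 5 minutes per cohort, five
cohort seeds, an 8-hidden-channel TCN (temporal geometry unchanged),
non-overlapping windows, 15 epochs with patience 5 and min_delta 0.005,
batch 64, learning rate 3e−3. The higher rate compensates for the reduced
epoch budget on the much smaller network; min_delta > 0 is what lets AUC —
which saturates early and then creeps in its third decimal — actually
terminate training at plateau, reproducing the stopping-metric mechanism
at small scale. Four arms: Plan C; Plan C with F1 stopping (stopping-metric
contrast at fixed imbalance stack); Plan D (overcorrection contrast); Plan
D on matched lab cohorts (deployment gap).

The directional findings checked on this study are: F1-monitored stopping
achieves mean held-out F1 at least that of AUC-monitored stopping; Plan C
shows sensitivity > precision and lower precision than Plan D; and the lab
regime shows higher mean F1 with a positive gap percentage and a smaller
across-fold F1 SD than daily living. Magnitudes at this scale are smaller
than the full-scale reference values and are not asserted.

## Numerical choices and degenerate inputs

- AUC uses the Mann–Whitney rank formulation; ties contribute one half.
  Tests cross-check against trapezoidal ROC integration.
- A fold with zero predicted positives reports precision 0 with a
  degenerate flag instead of NaN, so aggregation never drops folds.
- Paired t-tests use df = n−1 and Bonferroni adjustment min(1, p×m);
  Cohen's d is mean(diff)/sd(diff) for paired designs and the pooled-SD
  form for the Welch (unequal-variance) comparison. Zero-variance
  differences degenerate to t = 0, p = 1 when the mean difference is zero
  and are flagged as overflow otherwise.
- Constant channels normalize to zero via the SD floor.
- Strict config parsing: unknown YAML keys are fatal, since the studied
  effects are sensitive to plan settings and a typo must not silently
  revert a parameter to its default.

A behaviour worth knowing about at this scale: the 8-channel model can
memorize the training subjects' narrow oscillator frequencies instead of
band power, so an occasional held-out subject whose trembling frequency
falls between the memorized lines fails badly — sometimes with *inverted*
scores (AUC near 0). Such folds are the synthetic analogue of the
hardest daily-living subjects in real cohorts and are left in the
aggregates; they are one reason the scaled study asserts directions, not
magnitudes.

## Known limitations

The generator's distributional choices beyond prevalence, rates, bands and
the qualitative noise/jitter/heterogeneity contrasts are stand-ins; no
claim is made that synthetic magnitudes match real cross-dataset gaps.
Episode-level evaluation (detection latency, per-episode hits) is out of
scope; all metrics are window-level. The window-wise validation split's
optimistic bias is documented above. The DAPHNET-format loader is
exercised against a small synthetic fixture only.
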