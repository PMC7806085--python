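# Methods

## Problem and pipeline

In laparoscopic surgery the surgeon cannot palpate tissue directly; a
forceps-type tactile sensor stroked over the tissue produces a force-proxy
time series in which a stiff inclusion — here a toroidal mock-up of an
early-stage (0-IIc) gastric tumor — leaves a characteristic two-peak
signature as the probe crosses its two edges. `palpaid` implements a
detection-assistance pipeline over such traces:

1. **Windowing.** The trace (1 kHz, low-pass filtered at 10 Hz) is cut into
   windows of `t_window = 1.0 s` shifted by `t_window − t_overlap = 0.1 s`.
   Each interior sample is therefore covered by ten windows and the
   estimate refreshes at 10 Hz.
2. **Segmentation network.** A fully connected network with three hidden
   layers maps each window x ∈ ℝ^W to per-sample tumor probabilities
   y ∈ (0,1)^W: h_i = relu(W_i h_{i−1} + b_i) for i = 1..3 and
   y = logistic(W_4 h_3 + b_4). At full scale W = 1000 with hidden widths
   2000. Weights are He-initialized (SD √(2/fan_in), biases zero) and
   trained with Adam (lr 1e−3, β₁ 0.9, β₂ 0.999, ε 1e−8) on mini-batches
   of 100 windows for 200 epochs, minimising binary cross-entropy.
3. **Fusion and scoring.** Window outputs are fused by per-sample averaging
   over all covering windows. Within each scanning interval (recovered
   from the tangential contact force) the maximum fused score is taken;
   the mean of the per-scan maxima is the trial's representative score.
   A trial is declared tumor-positive when the score strictly exceeds the
   detection criterion.
4. **Criterion calibration.** Accuracy is evaluated on the grid
   c_j = 0.00 … 1.00 (step 0.01). With ACC_max the curve's peak,
   ACC_th = ACC_max − (ACC_max − 0.5)/10 defines a qualifying band; the
   criterion c_th is the midpoint of the smallest and largest qualifying
   c_j.
5. **Signal-detection evaluation.** Hit and false-alarm rates over the same
   grid (plus (0,0)/(1,1) anchors) trace the empirical ROC; the trapezoidal
   area A_g summarises criterion-free potential sensitivity (0.5 chance,
   1 perfect).
6. **Validation.** Within-participant: 4 balanced folds of a participant's
   40 trials; per fold the remaining 30 trials are split five times into
   20 training (10 per class) and 10 calibration (5 per class) trials.
   Across-participant: leave-one-participant-out, with 13 + 7 trials per
   class drawn from each remaining participant for training and
   calibration, re-drawn five times. In both designs the five calibrated
   criteria are averaged, and test trials are scored by the ensemble mean
   of the five trained networks' fused score series (option:
   final-repetition model only).

## Deliberate corrections of the source formulas

Three printed formulas in the source literature are internally inconsistent
and are implemented in their standard forms, with the literal variants kept
behind flags for comparison:

* the output nonlinearity is the standard logistic 1/(1+e^(−z))
  (`paper_sign=True` gives 1/(1+e^(z)), under which larger pre-activations
  would mean *lower* probability, contradicting the probability reading);
* the loss is the full binary cross-entropy
  −Σ[t ln y + (1−t) ln(1−y)] (`loss_mode="positive_only"` drops the second
  term; its optimum is y ≡ 1 and training with it is degenerate);
* A_g uses the standard trapezoid ½ Σ (F_{j+1}−F_j)(H_{j+1}+H_j)
  (`literal=True` evaluates the product-of-differences variant, which is 0
  on a unit-square curve and is not an area).

## Synthetic phantom scans

The generator emulates the statistical shape of the recordings, not the
mechanics of the silicone phantom. Per trial, `n_strokes` strokes (default
3) of ~1.2 s are separated by 0.2–0.5 s gaps; each stroke contributes a
half-sine contact bump (amplitude ≈ 1.0 arbitrary sensor units) to the
sensor trace and the same raised interval to the tangential force. When the
tumor is present every stroke crosses it once: two Gaussian peaks (width =
stroke_duration/10, default amplitude 0.8, separation 0.3 s) are added and
the label is 1 from just before the first to just after the second peak.
White noise (SD 0.05) is added and the sensor trace filtered with a
second-order zero-phase Butterworth low-pass at 10 Hz (zero phase keeps the
labels aligned with the peaks). Stroke speed/force jitter (relative SD 0.1)
and cohort-level perturbations of amplitude, speed and stroke count
(relative SD 0.15) emulate within- and between-participant variation. All
geometric randomness is driven through the jitter parameters, so zero
jitter yields byte-identical envelopes — a property the tests rely on.

What the generator does **not** reproduce: sensor acoustics and drift,
contact-angle artefacts, participant-specific kinematics, heteroscedastic
noise, and the real amplitude calibration (the source reports none). A pass
on synthetic data therefore demonstrates the pipeline's internal
correctness and its ability to recover a planted signature, not clinical
performance.

## Scale and numerical choices

* **Desk scale.** The full 1000/2000 architecture (~10 M parameters)
  trains on CPU but slowly; tests and validation examples run at 50 Hz
  sampling (window 50 samples, shift 5, hidden widths 100 — the 1:2 ratio
  preserved) with 30 training epochs within-participant and 20
  across-participant. At this scale the full 12-participant within- and
  across-participant protocols run in roughly one and three minutes
  respectively.
* Probabilities are clipped to [1e−12, 1−1e−12] inside the loss; the
  forward output is clamped to the largest open sub-interval of (0,1)
  representable in float64 so saturation never returns exactly 0 or 1.
* Ties at the decision rule (score == criterion) count as "no detection"
  (strict inequality) — the conservative reading.
* Edge samples covered by fewer than ten windows are averaged over however
  many windows cover them; samples past the last full window are not
  scored, and scanning segments are clipped to the scored region.
* Scanning segmentation uses a relative threshold (0.1 × the trial's peak
  force), a 0.3 s minimum duration and a 0.1 s merge gap — all
  configurable; on the synthetic strokes the detected segments overlap the
  ground-truth stroke intervals by well over 80 %.
* Non-contiguous qualifying bands in the criterion calibration use the
  global smallest/largest qualifying criterion. Below-chance accuracy
  curves trigger a warning and fall back to the curve's maximisers.
* Fold/repetition seeds are derived with `numpy.random.SeedSequence` from
  a single user seed; identical seeds reproduce identical results
  bit-for-bit.

## Adapting recorded data

Real recordings can be analysed by writing them into the trial container
(`palpaid.io`): one CSV per trial with columns `time_s`, `sensor`,
`tangential_force`, `tumor_label` (uniformly sampled at the manifest's
`sampling_rate`), plus a `manifest.json` listing per-trial
`participant_id`, `trial_index`, `tumor_present` and `sampling_rate`
(`true_segments` may be omitted; scanning intervals are then always
recovered from the tangential force). No such dataset is bundled or
required; all tests run on the synthetic generator.

## Known limitations

* A_g inherits the 0.01 resolution of the criterion grid: scores that fall
  in the same grid cell are unresolvable, so rank-level invariances hold
  only to ~0.01.
* The calibrated criterion is near-optimal on its own calibration data
  only when the accuracy-vs-criterion curve is unimodal.
* Which of the five per-repetition models should score the test set is
  ambiguous in the source design; the default ensembles the five score
  series (symmetric in the repetitions), with a switch to use the final
  model only.
* The real recorded dataset is not required nor downloaded; nothing here
  validates against it.
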