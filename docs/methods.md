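# Methods

This note documents the models and procedures implemented in
`solegrf`, the assumptions behind them, and the numerical and design
choices a maintainer would want to know.

## Estimation task and model

During the stance phase of walking the foot loads three uniaxial
plantar load cells (mid-heel, 1st metatarsal, 5th metatarsal). The task
is sequence-to-sequence regression from the four input channels (the
three sensors plus their sum) to the three ground-reaction-force axes
(vertical, anterior–posterior, medial–lateral), sample by sample at
200 Hz over one stance (~0.59 s, ~118 samples).

The network stacks three LSTM layers of widths 200, 50 and 200, each
followed by a linear fully-connected (FC) layer of matching width, with
a final 3-unit linear regression head. The FC widths are a design
choice: "each LSTM connected to an FC layer" is read minimally, with
each FC preserving its LSTM's width; the inter-layer FCs are linear
(learned projections), as in the common regression-network idiom.
Training follows the recipe the architecture was published with: Adam,
learning rate 0.01, minibatch 32, nominally 1000 epochs. Desk-scale
experiments in this package run 200 epochs, which is past the point
where held-out loss plateaus on the synthetic cohort; 1000 remains the
documented full-scale default.

Implementation notes (all in `grfnet.py`, pure numpy, float32):

* **Normalization.** Per-channel z-scoring of inputs and targets with
  statistics from the training split only. Without it the MSE loss is
  dominated by the vertical channel (~700 N) and ignores ML (~30 N).
  The scaler is stored with the model and inverted at inference.
* **Variable lengths.** Stance durations differ across subjects, so
  batches are padded to the batch maximum and the loss is masked.
  Because the LSTM is causal and padding sits at the end, predictions
  at unpadded positions are unaffected by padding (tested).
* **Optimization.** Adam with bias correction and a global
  gradient-norm clip of 5.0 — a numerical safeguard; at learning rate
  0.01 occasional early-epoch gradient spikes otherwise destabilize
  the run. No early stopping; instead the checkpoint with the best
  validation loss is returned (`selection="best_validation"`), with
  `"last_epoch"` available.
* **Reproducibility.** Initialization (uniform ±1/√H, forget-gate bias
  1) and epoch shuffling derive from the config seed; two runs with
  the same data, config and seed are bit-identical. Checkpoints are
  single `.npz` archives (parameters, scaler, config, loss history,
  schema version) that reload to bit-identical predictions.

Subject independence is enforced structurally: the trainer refuses
train/validation splits that share a subject, and the pipeline splits
by subject id before segments are formed into sets.

## Preprocessing

Both instruments record the same stance on their own clocks (load
cells nominally 100 Hz, force plate 120 Hz). Each trial pair is:

1. resampled to 200 Hz by cubic-spline interpolation (sample k at
   k/200 s; constants and aligned grid points are preserved exactly).
   Spline rather than linear interpolation keeps the worst-case error
   on sub-15 Hz content below 0.1% — linear interpolation leaves ~3%
   ripple on 10 Hz content sampled at 120 Hz;
2. lowpass filtered with a 4th-order Butterworth at 15 Hz. Default is
   zero-phase (forward–backward, reflection-padded): a causal pass
   would delay events by ~15–20 ms and bias every timing statistic.
   The forward–backward pass squares the magnitude response, so the
   gain at the cutoff is 0.50 rather than 1/√2 (asserted in tests). A
   causal mode and a bypass mode (`"none"`, for already-filtered data)
   are provided;
3. synchronized at the heel strike, detected independently per
   instrument as a debounced force onset: first sample above 10 N that
   stays above it for ≥ 25 ms, on the vertical channel (force plate)
   and the heel channel (load cells). The threshold operationalizes
   "the point at which the force occurred"; the hold rejects noise
   spikes. Swing-phase load-cell noise (~1.5 N) sits far below the
   10 N threshold, so lag before contact cannot trigger it;
4. cropped to the force-plate stance interval (half-open, 0-based;
   from onset to the end of the contiguous supra-threshold region),
   with the load-cell sum appended as the fourth input channel.

Filter edge transients decay below 1e-6 N roughly 0.4 s into a
recording; the generator therefore gives every trial at least 0.4 s of
swing lead-in, and filter-accuracy assertions exclude the outer 50 ms.

## Synthetic gait generator

The generator stands in for a human cohort (healthy young adults at
preferred walking speed) whose recordings are not available. It is a
phase-domain template model: stance phase p ∈ [0, 1], waveforms defined
on stance only, swing contributing only noise.

* **Vertical GRF**: two Gaussian bumps (weights 1.2/1.15 BW, centers
  0.24/0.76, width 0.18) times sin(πp)^0.5 — the classic M-shape, with
  maxima near 30%/70% of stance at 1.0–1.1 body weight and a
  mid-stance valley near 0.83 BW. The bump centers sit slightly
  outside 25%/75% because the sine taper pulls the realized maxima
  inward.
* **AP GRF**: piecewise sine, braking (negative) before the subject's
  crossing phase p₀ and propulsion after, amplitude 0.18 BW, same
  endpoint taper. Exactly one sign change, at p₀.
* **ML GRF**: C·sin(πp)(1 + 0.3 sin 2πp) with C = (0.03 + 0.02·g₁/g₅)
  BW — the amplitude is coupled to the metatarsal gain ratio so the ML
  axis is recoverable from the inputs.
* **Load cells**: Gaussian bumps (heel gain 0.55 BW at phase 0.22;
  5th met 0.25 BW at 0.60; 1st met 0.45 BW at 0.72; common width
  0.15), reproducing the heel → lateral → medial progression. The
  width is calibrated so that the pooled correlation between the
  load-cell sum and the vertical GRF over default cohorts is ≈0.85
  (measured 0.84–0.87 across seeds), bracketing the empirical 0.84.

Subject heterogeneity: stance duration ~ N(0.59, 0.04) s truncated to
[0.4, 0.9]; body weight ~ N(650, 90) N truncated to [400, 1000]; gains
jittered ±20%; metatarsal centers jittered ±0.02. The crossing phase is
coupled to the metatarsal timing offset, p₀ = 0.45 + 0.25·(c₁ − c₅) +
N(0, 0.01), so AP timing is learnable from input timing.

**Timing groups.** A configurable fraction of subjects (default 0.25)
load both metatarsals simultaneously ("similar" timing; |c₁ − c₅| <
0.02) instead of lateral-first ("different"). Similar-timing subjects
additionally carry a latent ML amplitude factor (N(0, 0.25), clipped at
±0.5) that the load cells do not see: with coincident forefoot timing
the plantar channels no longer resolve the lateral-to-medial transfer,
so part of the ML amplitude is irreducibly unpredictable for this
group. This reproduces, as a structural property rather than a seed
accident, the observed pattern that similar-timing subjects are harder
on the ML axis.

Acquisition model: sample k at k/rate from t = 0 (no clock jitter);
heel strike uniform in [0.40, 0.55] s; 0.35 s of padding after toe-off;
force-plate channels exactly zero outside contact; zero-mean swing
noise (sd 1.5 N) on load cells outside stance and sensor noise (sd
2 N) on both instruments during stance; load-cell values clipped at
the 980.7 N sensor capacity. All draws flow through one
`numpy.random.Generator` seeded from the config, making datasets
byte-reproducible.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: inter-step variability within a subject
beyond noise (templates are fixed per subject), double support and
multi-step trials, center-of-pressure trajectories, sensor drift or
hysteresis, foot–shoe interface mechanics, pathological or aged gait,
and any deviation of real GRF shapes from the three-template family.
Scores on the synthetic cohort demonstrate that the pipeline and
estimator recover a learnable mapping under realistic signal
structure, rates and noise — not that the same accuracy holds on human
data.

## Validation metrics

* **Pooled r / RMSE** per axis: all test samples concatenated, one
  number per axis (per-trial averaging is available as an option).
* **Mid-stance timing error**: AP zero-crossing (braking→propulsion)
  located with linear sub-sample interpolation, searching from the
  global minimum forward to skip spurious flips near contact; error =
  estimated − measured, classified earlier/later/equal with "equal"
  meaning within half a sample period (2.5 ms at 200 Hz). Expressed
  also as a percentage of stance and of the gait cycle
  (cycle = stance / 0.6, stance being ~60% of a cycle).
* **Peak agreement**: Bland–Altman on per-trial maxima (vertical, ML:
  series maximum; AP: propulsive-phase maximum). Differences are
  estimated − measured; bias, 1.96 SD limits of agreement, bias CI
  with the t(n−1) multiplier and sd/√n standard error, and LoA CIs
  with the classical sd·√(3/n) approximation. The bias CI is nested
  inside the LoA from n = 4 (at n = 3 the t multiplier is too wide).
* **Subgroup breakdown** by timing group, with the same metrics.

All statistics are checked against independent direct-formula
implementations to 1e-12 in the test suite.

## Problem sizes

The package's standard experiment is 60 subjects × 2 trials (37/12/11
subject split — the published design) with 200 training epochs, chosen
as the desk-scale configuration at which held-out performance has
plateaued on the synthetic cohort; it runs in ~3 minutes on one CPU
core. The generator-calibration checks use 50 trials (correlation
anchor) and 1000 subjects (stance-duration anchor).

## Known limitations

* The published architecture's FC widths, regularization and
  normalization were not specified; the choices here (matching widths,
  no dropout, z-scoring) are the minimal consistent reading.
* At learning rate 0.01, Adam cannot drive the loss to the memorization
  floor on very small datasets (it oscillates around the minimum);
  the overfitting sanity test uses 0.003.
* Pooled correlation rewards getting between-trial amplitude variation
  right and can mask shape errors on low-variance axes; RMSE and the
  Bland–Altman peaks are reported alongside for that reason.
* The estimator is only as general as the synthetic cohort it is
  trained on here; applying it to real recordings requires retraining
  on instrument data with the same channel conventions.
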