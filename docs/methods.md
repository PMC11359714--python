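# Methods

## Problem

A 60-electrode EEG montage records a spatially smooth potential field: the
signal at any scalp site is a mixture of underlying cortical sources that
neighbouring electrodes largely share.  `eegdense` exploits this redundancy
to reconstruct the channels a low-density cap (9–18 electrodes) did not
record, producing a "super-density" 60-channel recording.  Reconstruction
quality is judged twice: directly, as per-channel RMSE (μV) against held-out
truth, and downstream, by whether a standard four-class motor-imagery
decoder works better on the reconstructed montage than on the low-density
one.

## Montage geometry

Electrode positions are generated on the unit sphere from the defining
rules of the extended 10–20 (10–10) system: the sagittal midline and the
coronal line through the vertex are divided in 10 % steps (18° of polar
angle), the circumferential ring sits at 72° polar with its electrodes at
18° azimuth steps, and interior electrodes lie on great-circle arcs between
a row's midline electrode and its ring electrode at quarter fractions.
Right-hemisphere positions are exact mirror images of the left, so symmetry
invariants (midline lateral coordinate 0, homolog mirroring) hold to
machine precision rather than to file-rounding tolerance.

The 2-D layout used for distances, weights and topographic maps is the
azimuthal-equidistant projection about the vertex: planar radius equals arc
length from Cz (Cz at the origin, the head rim at radius π/2 ≈ 1.571),
azimuth preserved.  All inter-electrode distances quoted anywhere in the
package are Euclidean distances in this plane.

The built-in 60-channel ordering (index 1 = Nz, 21 = FCz, 31 = Cz,
60 = O2) matches the recording convention of the four-class motor-imagery
competition data this tool targets.  That cap is slightly asymmetric in the
parietal row (P7/P5/P3 on the left against P2/P4/P6 on the right); the
built-in montage reproduces this as-is, and symmetry checks apply only to
pairs that exist.

The four built-in low-density subsets (9, 12, 15, 18 electrodes) are
left–right symmetric and cover the whole scalp — frontal pole, lateral
frontal, central, parietal and occipital rows — growing from a 9-electrode
frame (Fp1/Fp2, F7/F8, C3/Cz/C4, O1/O2) by filling in the F, P and CP rows.
They are documented defaults, not a claim about any particular published
figure; arbitrary label lists are accepted everywhere a split is.

## Preprocessing

Amplitude thresholding (default 100 μV, a convention) marks artifact
samples; marked samples exclude training windows rather than being
interpolated.  Filtering is a zero-phase (forward–backward) Butterworth
band-pass, order 4 per pass, so cue-locked latencies are not shifted.  The
classification path uses 8–30 Hz (mu + beta); the interpolation path uses
broadband 1–45 Hz by default, though the density-comparison experiment
band-limits the interpolator's training to the decoding band (see below).
Epochs span 2 s before to 4 s after the cue (1500 samples at 250 Hz);
baseline correction subtracts the per-trial, per-channel mean over
[−200, 0] ms (50 samples).  The ten experimental rounds split 8/2 into
train/test: fold *k* of the 5-fold cross-validation tests on rounds
{2k−1, 2k}.  An independent-component hook is deliberately absent: only
threshold marking and band filtering are implemented.

## Synthetic data model

The generator produces the statistical structure the method relies on,
with no head-model physics:

* K = 20 sources at fixed random scalp locations, alternating broadband
  (1–45 Hz) and alpha-band (8–12 Hz) band-limited Gaussian processes,
  mixed into channels with the Gaussian kernel
  g(d) = exp(−d²/(2·s²)), s = 0.6 planar units, amplitude 10 μV per
  source; plus white sensor noise (1 μV).  Channel amplitudes land in the
  realistic tens-of-microvolts range and inter-channel correlation decays
  smoothly with distance.
* Motor-imagery trials add per-class mu-band (8–12 Hz) sources centered on
  class-specific motor-area electrodes (right hand → C3/C5/CP3, left hand
  → C4/C6/CP4, foot → Cz/CPz/FCz, tongue → FT7/FT8/T7/T8) with a tighter
  mixing kernel (0.3 planar units — cortical rhythms are focal).  During
  the imagery period of a class-*c* trial the class-*c* sources are
  attenuated by √(1−erd_depth), an event-related desynchronization of
  depth `erd_depth` (default 0.5).
* The mu amplitude (2 μV per source against the 10 μV background) was
  calibrated once so that the reference decoder scores in the mid-to-high
  60 % range on the 18-channel montage and ≳90 % on the true 60 channels
  at 50 trials/class — the difficulty regime reported for real four-class
  competition recordings.  The alpha-band background sources are the
  distractors that keep single-trial band-power decoding nontrivial.

What the generator does **not** emulate: eye/muscle artifacts, volume-
conduction physics, inter-subject variability, nonstationary drifts.
Passing tests therefore demonstrate correctness of the algorithms and the
claimed orderings under a smooth-field model, not performance on any real
recording.

The linear-mixture fixture used for parameter recovery replaces the target
channels by known convex (Dirichlet) combinations of the observed channels
plus N(0, 0.1² μV²) noise, so the best achievable reconstruction RMSE is
exactly the noise floor 0.1 μV and learning performance is measurable
against an absolute standard.

## The interpolator

Per time step, a standard LSTM cell (forget/input/output gates, candidate
cell, all acting on [h_{t−1}, x_t]) is run in both time directions; two
such bidirectional layers are stacked (default hidden sizes 120 and 128,
so layer 2 consumes 240 features and the readout 256) and a per-time-step
linear readout maps the 2×128 features to all target channels jointly.
Inputs and targets are z-scored per channel with statistics from the
training windows only.

Training: MSE loss in standardized units, Adam (lr 10⁻³ by default,
β₂ = 0.99 — the shorter second-moment memory suits recurrent curvature),
global gradient-norm clipping at 1.0, cosine learning-rate annealing to
10⁻⁴, early stopping on validation MSE with patience 10, forget-gate bias
initialized to +1.  Windows are chronological, non-overlapping by default
(sequence length 150 samples = 0.6 s at 250 Hz; batch 100), and windows
touching artifact-marked samples are dropped.  Forward, backward-through-
time and the optimizer are implemented directly on numpy arrays and are
bit-reproducible given the config seed.

Whole-recording prediction tiles consecutive windows, with a final window
aligned to the recording end (earlier predictions kept where the tail
window overlaps).

Confidence intervals use Gaussian residual calibration: on a held-out
calibration recording the per-channel residual standard deviation σ̂ is
estimated, the interval half-width is z₍(1+γ)/2₎·σ̂ (γ = 0.95 by default),
and empirical coverage is the fraction of test samples with |error| inside
the half-width.  This is a deliberate, simple choice; constant-width
intervals ignore heteroscedasticity across time.

## Classical baselines

Inverse-distance weighting predicts each target sample as the convex
combination of the observed channels with normalized weights d⁻¹ or d⁻²
(planar distances).  A zero distance short-circuits to exact passthrough of
the first coincident electrode — the limit of the weights as d→0, and the
only numerically stable convention.  Weights are normalized so the output
unit remains μV; predictions are therefore bounded by the observed value
range.

Cubic-spline interpolation works along the electrode line (row or column of
the 10–10 grid, temporal extensions included) through the target: observed
electrodes on the line become knots on a 1-D axis of cumulative planar
distance, a natural cubic spline (zero second derivative at the ends — the
parameter-free boundary choice) is fitted per time sample, and evaluated at
the target's position.  The orientation with more observed knots wins, ties
go to the horizontal; extrapolation beyond the knot range is refused rather
than attempted.

## Downstream decoding

The reference decoder is deliberately standard and fixed across montage
conditions: 8–30 Hz band-pass, feature window 0.5–3.5 s after the cue,
one-versus-rest Common Spatial Patterns with m = 3 filter pairs per class
on trace-normalized average covariances (ridge-regularized by
10⁻⁶·trace/n_ch), log-variance features normalized by total variance, and
a shrinkage linear discriminant per class; the predicted label is the
argmax of the four class scores, ties resolved to the lowest class index.
Accuracies are pooled over the five round-folds.

In the density-comparison experiment the interpolator is trained, per
fold, on the eight training rounds' full 60-channel trials and applied to
the test rounds' 18 observed channels; decoding runs identically on (a)
the 18 observed channels, (b) the reconstructed 60 channels, and (c) the
true 60 channels, plus a label-shuffled control.  For this experiment the
interpolator trains on the 8–30 Hz band-passed signal: the decoder
consumes only that band, and spending network capacity on out-of-band
content measurably hurts the reconstruction where it matters.

## Reference problem sizes

The study-scale experiments (also what `scripts/acceptance.py` reruns) use
fixed desk-scale sizes chosen to finish on a single CPU while keeping each
effect measurable: the mixture-recovery fixture is 60 s at 250 Hz
(40/10/10 s train/validation/test) with 4 target channels and a
32/32-hidden network trained 200 epochs on overlapping 120-sample windows
(stride 20); the channel-count trend uses 30 s recordings and 24/24 hidden
units; the density comparison uses 50 trials/class with 16/16 hidden units
per fold; the vertex baseline comparison reconstructs Cz from the central
row on a 20 s recording.  Wider networks (the
120/128 default) and longer recordings improve the absolute numbers but
not the orderings under test.

## Numerical choices and degenerate inputs

Zero-variance channels make standardization impossible and raise rather
than silently proceeding.  The IDW zero-distance passthrough, the natural
spline boundary, the CSP covariance ridge and the argmax tie rule are all
stated above; each is a convention, config-exposed where it could matter.
Sigmoids are evaluated with scipy's `expit` (numerically stable in both
tails).  Random numbering everywhere flows from explicit
`numpy.random.Generator` seeds; the CLI derives per-stage seeds from the
single global seed via `SeedSequence([seed, stage_tag])`.

## Known limitations

* Reconstructed channels are deterministic functions of the observed ones;
  on jointly Gaussian data no reconstruction can add information beyond
  the observed channels, and any downstream decoding gain must come from
  the decoder's constraints (fixed filter count, variance features,
  finite trials) interacting with the reconstruction's implicit
  class-conditional structure.  See the ordering experiment's discussion
  in the test suite.
* The confidence intervals are homoscedastic per channel.
* The spline baseline is undefined for targets at the end of an electrode
  line (extrapolation refused) and for lines with fewer than three
  observed knots; such targets are simply skipped in baseline summaries.
* Training the interpolator is CPU-bound numpy; it is intended for
  desk-scale experiments, not for large-scale model fitting.
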