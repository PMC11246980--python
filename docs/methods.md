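# Methods

This note documents the models implemented in `myocomp`, the parameter
choices that matter, the synthetic benchmark's assumptions, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## EMG feature extraction

The chain assumes already-digitised EMG (the analog band-pass, notch and
gain of a recording front-end are treated as properties of the input, not
reapplied). Defaults: sampling 2,000 Hz; 4th-order Butterworth high-pass at
50 Hz applied forward–backward (`sosfiltfilt`), i.e. zero-lag, which suits
offline analysis and rejects DC/motion artefact below the cutoff; Hann
window (periodic form) of 256 samples; hop 128 (50% overlap — the standard
choice for Hann analysis; the hop is configurable); magnitude-squared FFT
spectrum; 8 equal-width bands over [0, 400) Hz.

A spectral bin belongs to the band containing its centre frequency; bins at
or above 400 Hz are discarded. The per-band statistic is the **mean** of
|X_k|² (insensitive to the unequal 6-vs-7 bin counts per band at the default
geometry; `sum` is available). The DC bin sits in band 0; after the
high-pass it is effectively zero, and assigning it keeps the partition
exhaustive. With 3 channels the feature is the 24-vector of channel-major,
band-fastest concatenation. Equal-width bands are an assumption: the band
count and upper edge are fixed by the design, the equal partition is the
simplest consistent reading and is configurable.

Useful invariants (all tested): features are non-negative without log
compression; scaling the signal by c scales raw band powers by c²; the band
decomposition agrees with a brute-force direct-DFT oracle to 1e-9 relative
error; the windowed Parseval identity holds.

## Intention estimation

**Teacher data.** For each instruction segment, feature frames whose centre
times fall in `[start + skip_s, min(start + buffer_s, end)]` receive the
taught label; defaults buffer 2.0 s, skip 0.5 s. The skip drops
contraction-onset transients; both values are configurable and were chosen
once as plausible instruction timing.

**Classifier.** A single-hidden-layer network (16 ReLU units, softmax
readout, adam, ≤ 500 epochs, fixed seed) on standardised features — the
smallest standard architecture adequate for a 24-dimensional, ≤ 5-class
problem. Training uses scikit-learn's `MLPClassifier`; the fitted weights
are stored explicitly in `PatternModel` so that JSON serialisation
round-trips bit-exactly and prediction is an explicit
standardise → ReLU → argmax forward pass. Non-convergence is logged, not
fatal. Fewer than 2 classes or fewer than 10 examples per class is an
error.

**Recognition-stabilization filter.** The raw prediction stream is smoothed
by a trailing-window modal vote: over the last `window` frames (including
the current one; shorter at the stream head), if the modal label's
proportion reaches `threshold` the output switches to it, otherwise the
previous output is held (initial output: rest). Ties break toward the
earliest label in the canonical order (rest, grip, open, wrist_flex,
wrist_extend) for determinism. Defaults `window = 10`, `threshold = 0.6`
(≈ 0.64 s of context at the default frame hop) are package choices: with a
majority threshold above 0.5 the filter removes isolated misclassifications
and empirically never increases the switch count (property-tested). The
filter never invents labels: every output appears in the raw stream or is
the initial rest.

**Hand mapping.** Wrist flexion/extension are trained as *explicit classes*
that map to `hold`, alongside rest. This is the testable reading of
excluding wrist signals from hand actions; a rejection-threshold alternative
(discarding low-confidence frames) was considered and not implemented, as
the explicit-class route makes the wrist-invariance property directly
checkable end to end.

## Kinematics

**Trunk angle.** Only the two shoulder landmarks are guaranteed, so the
trunk angle is defined as the signed angle of the inter-shoulder **line**
against the horizontal, folded into (−90°, 90°] — an interpretation, since
no formula for the angle is fixed by the four-landmark setup. The line
(rather than vector) convention makes the angle sign-equivariant under
mirroring and translation-invariant; coincident shoulders are an error.

**Distortion level.** `D(Θ) = Σ |θ_k|`, a plain sum over frames. An
optional `dt` multiplier converts to angle·time units, but the default is 1:
at ≈ 0.11 s/frame a ≈ 4.2-s trial has ≈ 38 frames, so a ≈ 10° sustained tilt
gives D ≈ 380 — the scale on which distortion summaries in this kind of
experiment are printed. D is non-negative, additive under concatenation and
positively homogeneous (property-tested).

**Trajectory summaries.** All trials are linearly resampled to the longest
trial's frame count, uniformly in sample index (the simplest reading of
interpolating shorter trials to a standard; arc-length parameterisation
would weight dwell time differently). The mean path is the per-index mean;
checkpoints at fractions 0, 0.2, …, 1.0 carry per-axis SDs (n−1) across
trials. Resampling preserves endpoints exactly and is idempotent at fixed
length. Base/end heights are the task-side elbow y at the annotated grasp
and release frames (from the generator; first/last frame if absent) —
how those instants were located in a video recording is not derivable from
the data, so annotations are an explicit input.

**Coordinates.** Internal frame is y-up centimetres with the tabletop at
y = 0. The landmark reader converts pixel-space input (y down from the
screen's top-left corner) with a cm/pixel scale, a y-flip and a tabletop
row offset.

## Evaluation

Trials needing **more than** 10 s are excluded (a trial at exactly 10.0 s is
retained — the strict reading of the rule); exclusions are always reported.
Trials over 4 s are flagged for plot annotation only. Distortion histograms
use bins [0, 50), [50, 100), … (distortion is non-negative, so the origin is
fixed at 0); the normal overlay uses the sample mean and SD. Condition
differences are conventional − separate at 3 significant figures, matching
summary-table style.

The t-test variant defaults to **paired by trial index** when retained
counts match — consistent with reporting df = n−1 over n trial pairs —
and Welch otherwise; the variant, df and both n are always recorded in the
report, since the pairing assumption cannot be verified from summary data.
No multiple-testing correction is applied (single planned comparison).
Degenerate inputs are handled explicitly: identical paired samples give
t = 0, p = 1; constant nonzero differences raise a zero-variance error.

Throughput counts completions within a 30-s session window. In the
simulation a session is assembled from consecutive trial durations separated
by a fixed 2.0-s reach-back interval — a stylised choice, since inter-trial
timing is not part of the trial model.

## Synthetic benchmark

**EMG.** Each motion class has per-channel RMS gains and a spectral band
over 20–400 Hz (sites: CH1 extensor carpi radialis brevis, CH2 flexor carpi
ulnaris, CH3 flexor carpi radialis). A labelled segment adds band-limited
Gaussian noise at the class gain, ramped on/off with 100-ms half-cosine
edges, over white noise (σ = 0.05), 50-Hz line interference (amplitude 0.1)
and 5% inter-channel crosstalk. This matches the stochastic, band-limited
character of surface EMG without claiming physiological detail (no
motor-unit model); the class profiles were chosen once for separability in
band-power space and are exactly that — a separable benchmark, not a claim
about real inter-class EMG similarity.

**Task kinematics.** Per trial: duration ~ N(μ_d, σ_d); grasp/release
heights ~ N of the preset means/SDs; trunk tilt a half-sine bump (zero at
both ends, peak ~ N clipped at 0) — the simplest smooth profile with a
controllable peak; shoulders rotate rigidly about a fixed mid-point
(half-span 18 cm, height 62 cm); the task-side elbow eases from the base to
the end height between the grasp (15% of frames) and release (85%) instants;
frames every 0.11 s with optional ±1% uniform timestamp jitter (off by
default); isotropic Gaussian landmark noise, default σ = 0.3 cm, emulating
pose-estimator jitter. `side = "left"` mirrors x.

**Presets.** `table1_C` uses printed base/end heights and SDs
(conventional 45.1/27.6, separate 22.2/10.0 cm); durations 4.2 s vs 3.8 s
(SD 0.6) and tilt peaks derived by inverting the half-sine sum
Σ sin(πk/n) = cot(π/2n): conventional 192/24.2 ≈ 7.9° (SD 64/24.2 ≈ 2.6°),
separate 90.2/22.3 ≈ 4.05° (SD 51/22.3 ≈ 2.29°). `table2_D` analogously
stylises the left-handed participant's tables. These are **stylised**
presets: trial-level distributions (normality, independence, the half-sine
shape) are modelling choices, constrained only by printed means and SDs.

**What passing tests show — and don't.** The benchmark demonstrates that
the pipeline recovers known generator parameters, that the control chain
separates well-structured classes and suppresses wrist-driven hand commands,
and that the statistics behave correctly at the printed summary values. It
does not validate performance on real EMG (electrode shift, fatigue,
co-contraction, inter-day variability) or real pose data (occlusion,
identity switches between hand tool and hand, correlated tracking error).

## Numerical choices and known limitations

- Problem sizes: the acceptance script uses 200 trials per condition for
  parameter recovery, a 30-s instruction recording per control run, and
  1,000 replicates of 30 pairs for the power check — sizes at which
  Monte-Carlo error is well below the tolerances being checked while the
  full run stays in the seconds range.
- Distortion under landmark noise is biased **upward**: E|θ + ε| > |θ|
  near θ ≈ 0, so low-tilt trials inflate measured distortion by roughly
  Σ(E|θ_k + ε| − |θ_k|). At the default 0.3-cm noise (≈ 0.67° angle noise
  over the 36-cm shoulder span) the recovered condition means run ≈ 1%
  (conventional) to ≈ 4% (separate) above the configured tilt-profile sums.
  Users comparing low-tilt conditions should treat small distortion
  differences near this scale with caution.
- The preset tilt SDs ignore duration-variance contributions to the printed
  distortion SDs, so simulated distortion spread is approximate.
- Determinism: all generators take explicit integer seeds
  (`numpy.random.default_rng`); the classifier seed fixes weight
  initialisation and batching, so repeated runs are bit-identical. Run
  manifests record the config hash and seeds.
- Tie-breaks: stabilization ties resolve to the earliest label in canonical
  order; histogram edges are half-open [a, b); report rounding is 3
  significant figures and applied only at the reporting layer.
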