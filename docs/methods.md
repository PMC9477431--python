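# Methods

This note documents the models, numerical choices and limitations behind
the package, at the level a maintainer needs to modify it safely.

## Signal model of the synthetic generator

`e2sgan.synthetic` emulates the physics that makes scalp-to-depth
translation plausible: intracranial sources whose activity reaches a depth
contact almost directly and a scalp electrode only after distance
attenuation and tissue smoothing.

* **Sources** are band-limited Gaussian noise (2nd-order Butterworth
  band-pass, zero-phase) multiplied by an envelope: constant when
  `burst_rate = 0`, otherwise a 0.4 baseline plus 1-s Hann bursts at
  Poisson times. Distinct centre frequencies (default spread 3–27 Hz) give
  channels non-degenerate spectra, which spectral matching requires. By
  default one source is anchored at each depth contact.
* **Coupling** between a channel at distance d and a source is
  g(d) = 1 / (1 + (d/d₀)^p) with decay power p (`attenuation_exponent`,
  default 2) and softening scale d₀ (`reference_mm`, default 10 mm). For
  d ≫ d₀ this is the inverse power law g ∝ d^(−p).
* **Depth channels** are the coupled source mixture; **scalp channels**
  additionally pass a 2nd-order zero-phase low-pass (`eeg_lowpass_hz`,
  default 12 Hz) standing in for the attenuating tissue layers. Each
  channel's clean mixture is standardized to unit SD before Gaussian
  channel noise of SD `noise_sd` is added, so `noise_sd` is a per-channel
  noise *fraction* — recording gain is arbitrary in practice, and the
  rescaling leaves every correlation- and PSD-shape-based property intact.
* **Exception links** (scalp, depth, gain) add the depth channel's
  dominant source directly to the scalp channel (gain in units of that
  channel's clean SD), creating "far but similar" pairs that break the
  distance-similarity trend on purpose.
* **Ground truth** pairs each scalp channel with the depth channel of
  maximal effective coupling (attenuation × low-pass gain at the source's
  centre frequency, including exception gains).

What the generator does **not** emulate: realistic forward head models,
1/f background spectra, artifacts (EMG, eye movement, electrode pops),
non-stationary state changes, or epileptiform discharges. Tests passing on
this generator show the pipeline's mechanics are correct under controlled
coupling; they do not certify clinical-grade synthesis on patient data.

## Preprocessing

High-pass (4th-order Butterworth, 1 Hz for scalp / 0.5 Hz for depth) and
IIR notch (Q = 30) at the line frequency and all harmonics below the
original Nyquist are applied forward-backward (zero phase) at the original
rate, before polyphase resampling to 64 Hz. Zero-phase filtering matters
because the spectral codec models phase increments explicitly.
Segmentation uses 1016-sample windows with stride 254 (a quarter window);
paired channels share start indices. Depth contacts to exclude (e.g.
cortical-surface contacts) are a user-supplied list — no automatic
anatomical rule is attempted.

## Spectral codec

Centred STFT, Hann window 256, hop 8, at 64 Hz: a 1016-sample segment gives
1016/8 + 1 = 128 frames and 129 one-sided bins, of which the Nyquist row is
dropped to realize the square 128×128 grid (DC is kept — drift and slow
physiology live there). Channel 0 is log-magnitude, log(|Z| + 10⁻⁶),
affinely mapped into [−1, 1] (per-tensor min/max by default; dataset-level
quantile fit — 0.25% tails — for training). Channel 1 is the
frame-to-frame difference of time-unwrapped phase divided by π; the
absolute phase of frame 0 is kept as an anchor vector so inversion is
exact. Numerical choices that matter:

* **Odd-symmetric reflect padding** at the segment edges keeps the first
  derivative continuous, which keeps boundary leakage into the dropped
  Nyquist row an order of magnitude lower than even reflection.
* **Band projection at inversion**: the representation carries no content
  above the last retained bin centre (31.75 Hz), so the overlap-add output
  is projected onto that band. Together these bound the round-trip error
  at ~10⁻⁴ relative RMSE for band-limited signals (vs ~10⁻² without).
* The reduced desk-scale geometry is segment 248, window 64, hop 8 →
  2×32×32 tensors with identical structure.

A parametrization caveat: a component at frequency f has per-hop phase
advance 2πf·hop/rate, which wraps to exactly ±π for f ≡ 4 (mod 8) Hz at
the default geometry. At those rows the IF target saturates at the edge of
the [−1, 1] range and sign-flips under jitter; an L1-regressing network is
pulled toward 0 there, the most harmful value for resynthesis. This is
inherent to representing a circular quantity on a linear Tanh output.

## Channel matching

PSDs are Welch estimates (segment 256, 50% overlap, capped at the signal
length) normalized to sum 1; dissimilarity is the Hellinger distance,
clipped to [0, 1]. Regression slopes are computed per scalp channel and
per segment over the candidates in each distance bin (bins need ≥ 2
candidates); the positive-slope proportion is pooled over segments and
channels. Ties for the best interval resolve to the smallest lower edge;
"closest to a" resolves as minimal |d − a| with depth contacts consumed
greedily in scalp-name order; both documented, deterministic. The default
bin width is 5 mm and is the parameter to revisit first on real
geometries — the benchmark layout uses 40 mm so each bin holds three
contacts per scalp channel, enough for stable per-segment regressions.

The bundled distance-monotone benchmark (`surrogate.matching_benchmark`)
is a *designed* layout: scalp channels at the ends of a coplanar line of 8
depth contacts (uniform ~13 mm distance steps), stationary sources,
attenuation scale 5 mm (well below the contact spacing, so each contact is
dominated by its own source) and 28 Hz scalp smoothing (so no band is
crushed outright and effective coupling stays ordered by distance). Under
these conditions similarity decays monotonically with distance for every
scalp channel and the distance-guided pairing provably recovers the
injected pairs; a random hemispherical layout does not guarantee the
premise, because strong smoothing can reorder effective couplings across
bands.

## Networks and training

All layers use equalized learning rate (weights stored N(0, 1), scaled at
run time by gain/√fan_in; gain √2 except the Tanh head, which uses gain 1
to start unsaturated), leaky ReLU slope 0.2, and pixel-wise normalization
(ε = 10⁻⁸) in the generator. Residual blocks are pre-activation pairs of
3×3 same-convolutions. Upsampling is nearest-neighbour ×2 followed by a
3×3 convolution (checkerboard avoidance). The critic trunk is five
convolutions (4×4; strides 2,2,2,1,1) from a fixed 5-channel input — the
attention channel is fed as zeros whenever CSA is disabled, keeping one
architecture across both training phases. The attention map α is an m×m
row-stochastic matrix (the m-vector reading of the defining product does
not type-check against α·E_mag). CSA operates on network-range
(normalized) magnitudes. WPP weights initialize to the uniform average
1/(k²+1), so the untrained head reproduces plain patch-mean scoring.

Training is Wasserstein with gradient penalty: the depth tensor is mixed
with a per-sample uniform ε between real and generated, the scalp
condition is fixed (interpolating it too is available behind a flag), and
the input gradient is taken over the full 4-channel stack including the
attention path. λ_gp = λ_L1 = 10, Adam(β₁ = 0, β₂ = 0.99), learning rates
1e-5 (G) and 2e-5 (D), one critic step per generator step, batch 16 — all
configurable. Phase 1 trains without the attention channel, phase 2
jointly (default 80 + 40 epochs). The generator checkpoint returned is the
best validation-L1 state when a validation split is provided. Training
aborts on non-finite losses. Everything is deterministic given the config
seed under single-threaded execution.

The networks run on `e2sgan.autodiff`, a reverse-mode engine over numpy
arrays whose vector-Jacobian products are themselves graph operations, so
the second-order derivatives the gradient penalty needs come from the same
machinery (convolution is im2col + matmul; im2col/col2im are exact
adjoints). It is validated against finite differences to second order in
the test suite.

## Desk-scale training surrogate

`surrogate.run_coupled_surrogate` runs the whole pipeline at 32×32 on one
strongly coupled channel pair: three band-distinct sources (4, 10, 20 Hz)
within ~10 mm of the depth contact, 15% channel noise, 10 Hz scalp
smoothing, 64 s at 64 Hz (scalp/depth correlation ≈ 0.8). Segments of 248
samples (stride 62) are encoded at window 64 / hop 8; 47 train, 8
validation, 8 evaluation. Training runs 200 updates (batch 8) with
learning rates 2e-4/4e-4 — the published 2:1 ratio scaled so a 200-step
run moves at all — with the final third of the budget in the joint
attention phase, mirroring the 80/40 split. Generated tensors are inverted
using the conditioning input's anchor phase (the condition supplies the
absolute phase reference; the generator predicts increments relative to
it) and scored by the Hellinger log-ratio against the scalp baseline, with
Welch window 64 (the same ~7 half-overlapped averages per segment as the
full-scale geometry).

Known limitation: because the synthetic scalp channel shares the exact
source realizations with the depth target, the scalp baseline's PSD
co-varies with the target segment by segment, while the bottleneck
encoder-decoder (no skip connections) can only synthesize
conditional-mean-like spectra. At this step budget the reconstruction's
Hellinger floor (~0.4–0.5) sits at or above the baseline for some source
realizations, so the surrogate beats the baseline only on a subset of
seeds; longer training narrows but does not close the gap at desk scale.
The effect is a property of the synthetic conditions (a very informative
baseline), not of the adversarial objective.

## Evaluation and perturbation

DTW is the classic O(nm) dynamic program with absolute local cost and
steps {(1,0), (0,1), (1,1)}, numba-compiled, no bandwidth constraint, on
raw (not z-scored) amplitudes. PSD metrics reuse the matching module's
Welch settings. Log-ratios use the mean baseline over the evaluation set
(the single-number baseline convention), and reports aggregate
mean ± STD per metric. The temporal robustness profile splits both
signals into non-overlapping sub-segments at every width from 2 to L/2 and
records the STD of per-sub-segment RMSEs.

Perturbation adds N(0, σ²) noise to the magnitude rows of one clinical
band — δ [0, 4), θ [4, 8), α [8, 16), β [16, 32) Hz on bin centres, the
gaps between printed band edges folded into the lower band — with σ
defaulting to the SD of that band's (normalized) magnitude entries; the
IF channel is never touched. Noise lives in normalized magnitude units,
where σ is well defined against the network range. Effects are measured
as the change in PSD-RMSE of the generated output; the per-(channel, band)
Pearson correlation between effect and mean added noise is the
sensitivity table. With fewer than 2 repeats or zero variance the
correlation is flagged undefined rather than fabricated.

## Pipeline

The `e2sgan` CLI wires the stages (synth → preprocess → match → spectra →
train → eval → perturb) over a validated YAML config with a `desk` preset
(32×32 geometry) for CPU-scale runs. Each stage records completion in a
manifest keyed by a config hash; re-running skips finished stages, and a
run directory refuses a different configuration. EDF input is supported
through MNE; the package's own storage is numpy archives plus TSV
coordinates.
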