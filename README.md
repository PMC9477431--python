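# e2sgan

Translation of non-invasive scalp EEG into simultaneous intracranial
stereo-EEG (SEEG) with a conditional adversarial network, plus the
surrounding pipeline that makes the task well-posed: matching scalp
channels to depth contacts, encoding segments as magnitude +
instantaneous-frequency spectra, and scoring synthesized signals against
the raw scalp input.

Depth electrodes record high-resolution intracranial activity but require
invasive surgery; scalp EEG is safe but smeared and noisy. For patients in
presurgical epilepsy assessment, a faithful scalp-to-depth synthesis would
let clinicians preview intracranial signal character non-invasively. This
package implements that synthesis framework end to end and ships a
synthetic paired-recording generator so every stage is testable without
patient data.

## Method

**Channel matching.** For a scalp channel, all depth contacts are candidate
partners. Candidates are sorted by Euclidean distance d and binned into
intervals of width `bin_mm`; within each interval, the Hellinger distance
HD(p, q) = √(1 − Σᵢ √(pᵢqᵢ)) between sum-normalized Welch power spectral
densities is regressed on d. A positive slope means similarity decays with
distance inside that interval. The interval itv\* = [a, b] with the highest
proportion of positive slopes across segments is selected, and each scalp
channel is paired with the unused depth contact whose distance is closest
to a. A greedy nearest-neighbour variant is included for comparison.

**Spectral codec.** A 1016-sample segment at 64 Hz (15.875 s) is encoded by
a centred STFT (Hann 256, hop 8) as a 2×128×128 tensor: normalized
log-magnitude and instantaneous frequency (IF) — the frame-to-frame
difference of time-unwrapped phase, scaled by 1/π. IF of a stationary
sinusoid is constant per frequency row, which makes phase learnable by a
convolutional network. The codec is invertible (overlap-add), with
round-trip error ~10⁻⁴ for band-limited signals.

**Adversarial translation.** The generator G maps the scalp tensor e to a
depth tensor G(e) through a strided conv encoder, two residual blocks, and
upsample+conv decoding with a Tanh head (equalized learning rate,
pixel-wise norm, leaky ReLU throughout). The critic D is a PatchGAN scoring
a 14×14 grid of patches from the (e, s) channel stack, extended by:

* **CSA** (correlative spectral attention): a row-stochastic attention map
  α = softmax(A₁(E_mag)·A₂(S_mag)ᵀ/√n) between scalp and depth magnitude
  grids; α·E_mag is concatenated to the critic input as an extra channel.
* **WPP** (weighted patch prediction): ŷ = Σᵢ βᵢqᵢ, where q concatenates
  the leaky-rectified global patch mean with the flattened patch scores and
  β is learned.

Training minimizes the Wasserstein objective with gradient penalty
(λ_gp = 10) plus λ_L1 = 10 times the L1 reconstruction error, in two
phases: first without the attention channel, then jointly with it. The
networks run on a compact in-repo autodiff engine (numpy-based,
double-backprop capable for the gradient penalty).

**Evaluation.** Synthesized segments are scored by DTW (time domain) and by
PSD-RMSE and Hellinger distance (frequency domain), each normalized against
the raw scalp baseline via Eval_log = log₂(Eval(S_fake, S_real) /
Eval(E_real, S_real)) — negative values beat the baseline. A band-limited
perturbation analysis adds Gaussian noise to one clinical band (δ, θ, α, β)
of the input magnitude and correlates the induced PSD-error change with the
mean added noise, mapping which input features the generator relies on.

## Worked example

```python
import numpy as np
from e2sgan.surrogate import matching_benchmark

recording, result = matching_benchmark(seed=0)
print("itv* =", result.itv_star)
for iv in result.per_interval:
    print(f"  [{iv.low:.0f}, {iv.high:.0f}) mm: "
          f"positive slope fraction {iv.positive_fraction:.2f} "
          f"({iv.n_slopes} regressions)")
print("pairs:", result.pairs)
print("injected ground truth:", recording.truth_pairs)
```

prints

```
itv* = (np.float64(40.0), np.float64(80.0))
  [40, 80) mm: positive slope fraction 1.00 (42 regressions)
  [80, 120) mm: positive slope fraction 1.00 (42 regressions)
  [120, 160) mm: positive slope fraction 1.00 (42 regressions)
pairs: [('E01', 'S01'), ('E02', 'S08')]
injected ground truth: [('E01', 'S01'), ('E02', 'S08')]
```

Every distance interval shows similarity decaying with distance (all
regression slopes positive), the lowest qualifying interval is selected,
and the distance-guided pairing recovers exactly the channel pairs whose
coupling was injected by the synthetic source model.

The full pipeline — synthesis, filtering, matching, encoding, training,
evaluation, perturbation — runs from the command line:

```bash
e2sgan run --preset desk --out run/ --seed 7
```

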