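# Methods

## Signal model

`echotype.simulate` generates the signals the rest of the package
consumes. Each record of length *N* contains:

* a **film echo** — a monocycle bipolar pulse (sine cycle under a Gaussian
  envelope whose width is set by the fractional −6 dB bandwidth) scaled by
  `film_echo_amplitude` and centred at `film_echo_delay`. With the default
  200 MHz centre frequency and 0.9 fractional bandwidth at 10 GHz sampling
  the pulse spans ~167 samples and its magnitude-spectrum peak lies at the
  centre frequency.
* a **scatterer echo** — the same pulse, scaled by
  `acoustic_contrast · 0.1 · (d / 5 µm)^1.5` and low-pass filtered
  (2nd-order Butterworth, zero-phase) at
  `f_c = f_centre · (5 µm / d)^m`, where the exponent *m* depends on the
  material (0.35 for cells, 0.15 for polystyrene, 0.25 otherwise). The
  amplitude law makes echo energy strictly increasing in diameter; the
  cutoff law softens large objects' spectra and separates materials at
  equal size. The echo is placed `scatterer_delay_offset` samples before
  the film echo with an integer jitter of ±16 samples emulating trapping
  variability. Per-signal diameters are drawn from a truncated normal
  (population mean ± SD; RBC 6.57 ± 0.66 µm, PNT1A 10.10 ± 0.88 µm, beads
  4.98 ± 0.06 and 9.97 ± 0.07 µm) and recorded in the manifest.
* additive i.i.d. Gaussian noise with SD `noise_sd` (default 0.05 relative
  to the unit film amplitude).

This is a phenomenological forward model: no wave propagation, scattering
theory, attenuation or transducer response is simulated. Passing tests on
these signals demonstrates that the pipeline recovers size/material
signatures that are *monotonically encoded* in echo amplitude and
spectral tilt; it does not certify performance on real recordings, whose
class signatures may be weaker, non-monotone or confounded.

The amplitude scales are validated by invariants rather than physics:
echo energy monotone in diameter, scatterer peak strictly below the film
peak, noise variance within 5 % of `noise_sd²`, and a ≥90 %-accurate
energy-threshold classifier at a twofold contrast ratio (the separability
control used by the end-to-end tests).

## Denoising autoencoder

Encoder: six dilated 1D convolutions (kernel 3, dilations 1…32, filters
16,32,32,16,8,4 tapering so the flattened feature stays small), max-pool
by 2 after every second convolution, then two fully connected layers
(2·|Z| → |Z|). Decoder: the latent vector is reshaped to a length-|Z|
single-channel sequence, then seven dilated convolutions with three 2×
upsamplings restore length *N* (the final convolution maps to one channel
with linear output, since signals are bipolar). This ties |Z| to N/8
after symmetric zero-padding to a multiple of 8 — 1250 at N = 10000 —
and makes the bottleneck a genuine compression. Training corrupts each
batch input with fresh Gaussian noise of SD σₙ (relative to peak
amplitude 1; every signal is max-abs normalized before entering the
pipeline) and reconstructs the uncorrupted signal.

Full-scale defaults follow the study's best settings: 200 epochs, Adam,
learning rate 0.01, batch 12, MAE loss, σₙ = 0.1, |Z| = 1250.

## Classifiers

The 1D CNN: seven dilated convolutions (kernel 3; dilations
1,1,2,2,4,4,8; filters 16,16,32,32,64,64,128), each followed by
batch-norm, ReLU and dropout 0.2; max-pool (size 2) after convolutions
2, 4, 6 and 7; then FC 256 → 64 → 1 with sigmoid output. Binary
cross-entropy, Adam (lr 0.001, batch 15, 50 epochs), L2 10⁻⁴ on weights
and biases, Xavier-normal initialization of weights and biases. The 2D
CNN is the same stack with 3×3 kernels and (2,2) pooling. Baselines:
linear-kernel SVM, L2 logistic regression, and an MLP with five hidden
layers of 100 ReLU units (lr 0.001, batch 12, 100 epochs) — all consuming
the same flattened features as the CNNs.

Decision threshold 0.5; a score exactly at threshold goes to the positive
class. Precision/recall are reported for a declared positive class
(default: first label alphabetically).

## Evaluation protocol

Stratified k-fold (default k = 3) with seeded shuffling; per-class fold
counts differ by at most one and every signal is tested exactly once.
Within each fold the autoencoder is fitted on the training folds only,
augmentation (originals + `copies_per_signal` noisy replicas, default 10)
applies to training folds only, and any overlap between train and test
ids raises immediately. Metrics come from confusion counts with the
conventions P := 0 (R := 0) on empty denominators and F₁ := 0 when
P + R = 0; fold aggregates are the arithmetic mean and *sample* standard
deviation (n−1) of unrounded values, rounded to 2 d.p. only for display.
The ablation runner evaluates Raw (no denoising), DN (autoencoder only)
and DN+ (autoencoder + augmentation) on shared fold assignments; the
resolution sweep re-runs spectrum and spectrogram experiments with the
frequency axis subsampled to 125…2000 bins in steps of 125 (decimation by
default, bin-averaging as an option), skipping resolutions beyond the
available bin count.

## Numerical choices

* **NumPy networks.** All neural components are implemented directly in
  NumPy (explicit forward/backward passes, Adam). Convolutions are
  evaluated tap-by-tap as BLAS matmuls in channels-last layout.
  Parameters are float32 for CPU throughput; runs are bit-reproducible
  under fixed seeds because all randomness flows through seeded
  generators. Gradients are verified against central finite differences
  in the test suite.
* **Batch-norm recalibration.** With few optimizer steps the running
  moments used at inference lag the trained weights, which degrades
  inference on small training runs. After training, a single pass over
  the training set (dropout off, batch statistics active) re-estimates
  the inference moments from the final weights.
* **Bias initialization.** Biases start at zero except in the classifier
  stacks, which follow their stated Xavier-on-weights-and-biases recipe
  (harmless there: batch-norm absorbs conv biases). In the autoencoder,
  random biases combined with a high learning rate reliably produced
  dead-ReLU collapse (the encoder output becomes constant and the decoder
  reproduces the training mean, erasing per-signal information).
* **Padding.** Signals are symmetrically zero-padded to a multiple of 8
  so three pool/upsample stages are exact; the output is un-padded to N.
* **Resolution decimation** uses `round(linspace)` indices, which for
  target ≤ source bins is strictly increasing.
* **Degenerate inputs.** Empty signals, non-finite samples, mismatched
  lengths, single-class training sets, windows longer than the signal and
  resolutions beyond the bin count are rejected with explicit errors.

## Reduced problem sizes

The package's own experiments (test suite and `scripts/acceptance.py`)
run a scaled version of the study chosen once, as the package's CPU
sizing (`echotype.presets.reduced_pipeline`):

| quantity | full scale | reduced |
|---|---|---|
| record length N | 10000 | 2000 (512 for the denoising-gain check) |
| latent \|Z\| | 1250 (= N/8) | N/8 |
| AE training | MAE, lr 0.01, 200 epochs | MSE, lr 0.003, 100 epochs |
| CNN filters | 16,16,32,32,64,64,128 | 8,8,16,16,32,32,64 |
| CNN epochs | 50 | 25 |
| noisy copies per training signal | 10 | 2 |
| signals per class | 77 | 77 |

The reduced AE recipe uses the squared-error objective with a gentler
learning rate because the full-scale recipe's optimizer budget (hundreds
of thousands of sample-epochs) is unattainable in minutes of CPU; at
reduced scale the MAE/0.01 combination under-trains and can collapse as
described above. With the reduced configuration the end-to-end DN+
system separates a twofold acoustic-contrast ratio at mean 3-fold
accuracy ≥ 0.95 for all three representations, and permuted labels fall
to chance — both recomputed, not assumed, by the acceptance tests.

## Known limitations

* The simulator's class signal is deliberately strong and monotone;
  real backscatter differences (e.g. nucleated vs anucleate cells of
  similar size) are subtler.
* The autoencoder's latent size is structurally tied to N/8; other
  compression ratios would require a decoder-side projection.
* Multiple signals per physical cell are not grouped in fold splits
  (splitting is per signal, as in the evaluation protocol this package
  follows); a manifest `group` column is carried but unused.
* No significance testing or ROC analysis; metrics are the four
  confusion-based scores only.
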