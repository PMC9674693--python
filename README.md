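# echotype

Automated cell-type classification from label-free high-frequency
ultrasound backscatter.

## The problem

Acoustic tweezers operating at high pulse-repetition frequency can trap a
single micron-sized object — a red blood cell, a prostate epithelial cell
(PNT1A), a calibration microsphere — on an acoustically transparent Mylar
film and simultaneously record the ultrasound it scatters back. The
recording is dominated by a large reflection from the film; the echo from
the trapped object is tiny, arrives slightly earlier, and carries the
object's size and material signature. Classifying objects from these
recordings traditionally requires manual post-processing of integrated
backscattering coefficients. `echotype` implements an automated
alternative: denoise the raw trace with a convolutional autoencoder, then
classify it with shallow dilated-convolution networks.

## The method

Given a raw signal `X` (length *N*), a 1D convolutional denoising
autoencoder learns

    Z = f(X + n; W_e),   X̂ = g(Z; W_d),   n ~ N(0, σ_n²)

with a compressive latent vector `Z` (|Z| = N/8; 1250 for N = 10000), six
dilated 1D convolutions + three max-poolings + two fully connected layers
in the encoder, and seven dilated convolutions + three 2× upsamplings in
the decoder. The same Gaussian corruption doubles as data augmentation:
each training signal yields `copies_per_signal` noisy replicas.

The denoised signal is analyzed in three representations:

* **waveform** — the time-domain trace itself;
* **spectrum** — `|X̂(f)|` for the non-negative half of the FFT bins;
* **spectrogram** — squared-magnitude STFT over Hamming-windowed frames
  (window `l = 32`, step `d = 16`).

A dilated 1D CNN (seven convolutions, kernel 3, batch-norm, dropout 0.2,
four max-poolings, three FC layers, sigmoid output, binary cross-entropy)
classifies the 1D representations; its 2D twin (3×3 kernels, (2,2)
pooling) handles spectrograms. Linear-kernel SVM, logistic regression and
a 5×100-unit MLP serve as classical baselines on identical features.
Evaluation is stratified 3-fold cross-validation reporting accuracy,
precision, recall and F₁ (per fold, plus mean and sample SD), with a
Raw / DN / DN+ denoising ablation and a frequency-resolution sweep.

Because the original recordings are not publicly deposited, the package
includes a parametric echo simulator (film reflection + diameter- and
material-dependent scatterer echo + Gaussian noise) so the entire system
is testable end to end. The networks are implemented in NumPy (forward
and backward passes, Adam) and are bit-reproducible under fixed seeds.

## Worked example

Simulate two microsphere populations (9.97 ± 0.07 µm at twice the acoustic
contrast of 4.98 ± 0.06 µm, 20 signals each, 512-sample records) and
cross-validate a dilated 1D CNN on their frequency spectra:

```bash
echotype simulate --config quickstart.yaml --out data
echotype run --config quickstart.yaml --manifest data/manifest.csv --out exp --mode raw
```

with `quickstart.yaml`:

```yaml
seed: 7
representation: spectrum
model: cnn1d
simulate:
  acquisition: {n_samples: 512, film_echo_delay: 330, scatterer_delay_offset: 150, noise_sd: 0.05}
  classes:
    - {label: bead10, diameter: 9.97, diameter_sd: 0.07, material: polystyrene, acoustic_contrast: 2.0}
    - {label: bead5, diameter: 4.98, diameter_sd: 0.06, material: polystyrene, acoustic_contrast: 1.0}
  n_per_class: 20
noise: {copies_per_signal: 2}
autoencoder: {encoder_filters: [8, 8, 16, 16, 8, 4], decoder_filters: [8, 8, 16, 16, 8, 8]}
ae_train: {epochs: 100, learning_rate: 0.003, loss: mse}
classifier: {filters: [8, 8, 16, 16, 32, 32, 64], epochs: 25}
```

Output (about half a minute on one CPU core):

```
spectrum/cnn1d/raw: mean accuracy 0.97, mean F1 0.97
```

and `exp/report.csv`:

```
fold,accuracy,precision,recall,f1
1-Fold,1.00,1.00,1.00,1.00
2-Fold,1.00,1.00,1.00,1.00
3-Fold,0.92,1.00,0.83,0.91
Avg.,0.97,1.00,0.94,0.97
S.D.,0.04,0.00,0.10,0.05
```

Each row is one cross-validation fold: the held-out third of the signals
is scored by a CNN trained on the other two thirds; `Avg.`/`S.D.` are the
mean and sample standard deviation across folds. The twofold contrast
ratio makes the two classes' scatterer echoes differ ~4× in energy, which
the spectrum CNN separates almost perfectly. `--mode dn+` inserts the
denoising autoencoder and Gaussian-noise augmentation in front of the
classifier (slower; the full-scale study below uses it), `ablate` compares
Raw/DN/DN+ on shared folds, and `sweep` traces accuracy against frequency
resolution.

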