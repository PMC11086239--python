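# Methods

`fecgx` extracts the fetal electrocardiogram (FECG) from noninvasive maternal
abdominal recordings (AECG). The abdominal signal is a mixture of a dominant
maternal ECG, a weaker and faster fetal ECG, baseline wander, mains
interference, impulse artifacts and broadband noise. The package implements
the complete chain: a synthetic data generator with exact ground truth,
zero-phase preprocessing, an unpaired adversarial translation model
(CycleGAN) whose generators combine a CNN front end with a bidirectional
LSTM, fetal QRS detection, and a metric suite.

## Signal model and synthetic generator

Each beat is a sum of Gaussians on a phase variable,

    z(phi) = sum_i a_i exp(-(phi - theta_i)^2 / (2 b_i^2)),  i in {P,Q,R,S,T},

with the phase advancing one full cycle per RR interval. Per-beat
heart-rate jitter (Gaussian, sd `hr_jitter_sd` beats/min) is the simplest
proxy for heart-rate variability. The abdominal mixture on channel `c` is

    aecg_c = g_c * maternal + r * fetal + baseline + mains + impulses + white,

with channel gains `g_c ~ 1 +- 0.2`, fetal-to-maternal amplitude ratio `r`
(default 0.25), maternal rate 75 bpm, fetal rate 140 bpm, 500 Hz sampling.
Noise defaults (amplitudes in the same mV-scale units as the unit-amplitude
maternal R wave): baseline 0.3 below 5 Hz, mains 0.2 at 50 Hz plus a 0.3x
third harmonic, impulses 3.0 at 0.5/s (electrode-pop scale, several times
the maternal QRS), white noise sd 0.05. With these rates a fetal QRS
overlaps a maternal QRS in roughly one beat in eight, so the hard
fetal+maternal overlap case occurs regularly.

What the generator does *not* emulate: dipole/volume-conductor projection
geometry, gestational-age-specific morphologies, uterine EMG, electrode
motion with spectral overlap into the QRS band, and rhythm pathologies.
Passing the end-to-end tests therefore shows the method recovers a weak
periodic source behind a strong one under realistic stationary noise — not
clinical performance on real abdominal recordings.

## Preprocessing

All stages are zero-phase (forward-backward filtering) so R-peak timing is
never shifted:

1. **Baseline**: a first-order Butterworth low-pass at 5 Hz estimates the
   drift, which is subtracted. Note this also removes genuine sub-5 Hz ECG
   content (T waves lose energy); evaluations against a clean reference
   therefore pass the reference through the same linear stages.
2. **Mains interference**: Welch PSD (256-sample Hann segments, 50% overlap);
   if the peak density within +-1.5 Hz of 50 or 60 Hz exceeds 5x the average
   density, 1 Hz-wide zero-phase notches are applied at the fundamental and
   harmonics up to the 3rd (harmonics above Nyquist are skipped).
3. **Impulses**: deviations from a 60 ms moving median larger than
   `k * P99(|x - median(x)|)` (k = 2.5) are replaced by the local window
   mean. The high-quantile scale is used instead of a MAD because the
   median-deviation of a smooth signal is exactly zero over monotone
   stretches (MAD degenerates) while QRS flanks re-occur every beat and sit
   far above the MAD; the 99th percentile tracks the signal's own per-beat
   deviation scale, so clean ECG passes untouched and rare large spikes are
   flagged.
4. **Centering and whitening**: per-channel mean removal, then the symmetric
   whitening map `V D^(-1/2) V^T` from the eigendecomposition of the channel
   covariance. Whitening is fitted per record (stable covariance), errors on
   rank-deficient input, and reduces to unit-variance scaling for a single
   channel.

## Model

Two generators (G1: AECG->FECG, G2: FECG->AECG) and two discriminators.

**Generator** (input and output are 1024-sample segments): three parallel
1-D convolution branches with kernel widths 3/5/7 samples (multi-scale
morphology), each a stack of conv blocks whose channel count doubles per
block from the base width, ReLU + max pooling; branch features are
concatenated, passed through dropout and a per-step fully connected resize,
then a stacked bidirectional LSTM; three parallel linear output heads
(nominally P-wave / QRS / ST feature outputs) are summed and a final fully
connected layer maps each step back to samples, restoring the input length.
Defaults: 3 conv blocks, channels 64->256, BiLSTM hidden 128 x 2 layers,
dropout 0.5. Depth (1-5 conv blocks) is configurable for ablations.

**Discriminator**: 1-D PatchGAN. Kernel-2 stride-2 convolutions halve the
temporal size per layer (channels doubling from 64, LeakyReLU 0.2); the map
is average-pooled to 16 positions and a stride-1 convolution + sigmoid
scores each patch, giving a 4x4 grid of authenticity probabilities whose
mean is the discriminator output. With six stride-2 layers the 16 positions
arise without pooling. Depth 2-6 is configurable; a non-patch variant with
one global score exists for ablations.

The network stack runs on a small reverse-mode autodiff engine written on
numpy (`fecgx.autodiff`): a taped DAG of array ops with exact gradients
(verified against finite differences), strided conv via im2col + BLAS, and
Adam. Training can run in float32 to halve memory traffic.

## Losses

* **Cycle consistency**: mean absolute error of `G2(G1(x))` vs `x` plus
  `G1(G2(y))` vs `y` (per element, batch mean).
* **Adversarial**: per-patch log scores averaged over the 16 patches and the
  batch; the discriminator minimizes
  `-(E[log D(real)] + E[log(1 - D(fake))])`, the generator the
  non-saturating `-E[log D(fake)]`. Probabilities are clamped to
  `[1e-7, 1 - 1e-7]`.
* **Identity (distortion penalty)**, three summands for a batch of size N:

      (2/N) sum_i [1 - rho(P(y_i), P(G(x_i)))] * rho(P(y_i), P(x_i))
    + (4/N) sum_i [1 - rho(y_i, G(x_i))]
    + (1/N) sum_i |p(x_i) - p(G(x_i))| / p(x_i)

  with `P` a Welch PSD (Hann 256, 50% overlap, mean-detrended — implemented
  differentiably via DFT matrices and proportional to `scipy.signal.welch`),
  `rho` the population Pearson correlation and `p` the mean squared
  amplitude. The first summand's grouping is implemented as the bounded
  product shown (zero at the fixed point); a quotient variant
  `[1 - rho(P(y), P(Gx))] / rho(P(y), P(x))` is available behind
  `identity_form="quotient"` but divides by a correlation that can approach
  zero. The identity terms are *minimized*, consistent with their role as a
  penalty inside the total objective.
* **Total generator objective**: `adversarial + lambda * cycle +
  beta * (identity_1 + identity_2)`. The weights are nowhere pinned down
  numerically by the method's description, so the package defaults to the
  standard CycleGAN practice lambda = 10 (alpha is an alias of lambda) and
  beta = 5, all configurable.

## Training

Adam (lr 1e-4, beta1 0.9, beta2 0.999), 80 epochs by default, alternating
updates: both discriminators on real/detached-fake batches, then both
generators on the weighted total. Batch size defaults to 32 (never stated in
the method's description; fits CPU memory at N = 1024). AECG- and FECG-side
batches are drawn independently by default (unpaired translation); a
*paired* mode keeps batch items aligned, which is what the sample-wise
identity correlation term `rho(y_i, G1(x_i))` implicitly assumes — the
real databases this family of methods trains on provide such record-level
correspondence. NaN losses abort training and restore the last epoch's
parameters. History rows log every loss component; the reported total is
recomputed from the logged means so the bookkeeping identity is exact.

## Detection and evaluation

Fetal QRS detection is the classic Pan-Tompkins chain parameterized for
fetal rates: 10-35 Hz zero-phase bandpass, five-point derivative, squaring,
80 ms moving-window integration, adaptive dual thresholds
(`THR = NPK + 0.25 (SPK - NPK)`, running-average updates), a 200 ms
refractory period, and RR-gated search-back admitting sub-threshold
candidates after gaps longer than 1.66x the running RR mean. Detections are
refined to the local energy maximum of the bandpassed signal.

A detection is correct when within 50 ms of a reference R-peak; matching is
greedy one-to-one by smallest time difference (ties: earlier reference).
Se = TP/(TP+FN), PPV = TP/(TP+FP), ACC = TP/(TP+FN+FP),
F1 = 2TP/(2TP+FN+FP), reported in percent. Signal quality: MSE, MAE,
R^2 x 100, and SNR = 10 log10(sum(est^2) / sum((est-ref)^2)) in dB; a
perfect reconstruction reports the capped sentinel 100 dB instead of
infinity.

## Desk-scale end-to-end experiment

`fecgx.benchmark.run_synthetic_benchmark` (driven by both the test suite and
`scripts/acceptance.py`) runs the whole method at sizes chosen for a single
CPU: 9 training records x 120 s (531 segments per domain, stride 1000),
3 held-out 60 s records, 40 epochs, batch 16, float32, paired sampling.
The model keeps the full architecture at reduced width (conv base 8,
BiLSTM hidden 24, discriminator base 16, pooling 4/2/2) — about 30k
generator parameters — so the ~1300 optimizer steps available suffice;
the learning rate is raised to 1e-3 to match the small model and short
schedule. Quality metrics compare z-scored traces (the extracted signal
lives in whitened units, the truth in mV; R^2 is scale-sensitive). Residual
misses concentrate on fetal beats whose QRS coincides with a maternal QRS
within ~50 ms — the known hard overlap case; at full scale (wider model, 80
epochs, real data) this is precisely what the extra capacity addresses.

## Numerical choices and edge cases

* Pearson correlation uses the population formula; constant inputs raise an
  error rather than returning NaN. Zero-power segments make the identity
  power term undefined and raise an error naming the segment.
* Segmentation: stride = window − overlap (1000 = 1024 − 24); trailing
  partial windows are dropped; reassembly averages the shared 24 samples.
  Annotations are 0-based sample indices everywhere.
* FFT resampling uses Fourier-domain interpolation; annotation indices are
  rescaled and rounded, end-of-record indices that fall outside are dropped.
* The WFDB subset writer quantizes at 2000 ADC units/mV into 16-bit ints;
  CSV round trips are exact (repr precision).
* Matching tolerance is inclusive (a 50.0 ms offset still matches).
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  identical configs reproduce bit-identical synthetic data, splits and
  training histories on one platform/dtype.

## Known limitations

* The desk-scale GAN leaves fetal beats under maternal QRS complexes partly
  unrecovered (sensitivity ~0.85-0.9 on the synthetic corpus at that scale).
* Whitening mixes channels; multichannel extraction currently scores one
  chosen channel rather than fusing all four.
* The autodiff engine is single-threaded numpy; it is sized for the bundled
  experiment, not for full-scale (80-epoch, 27k-segment) training.
* The "improved" detector is the classic Pan-Tompkins chain with fetal
  parameterization; no ectopic-beat or annotation-reliability handling.
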