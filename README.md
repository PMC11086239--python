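# fecgx

Noninvasive fetal electrocardiography: the fetal ECG (FECG) recorded from a
pregnant abdomen is buried under the maternal ECG, baseline wander, mains
interference and artifacts, yet its morphology (P-QRS-T, PR interval, ST
segment) carries early markers of fetal distress. `fecgx` is a library and
CLI for extracting the FECG from abdominal recordings (AECG) with an
unpaired adversarial translation model, and for evaluating the result
against reference fetal R-peak annotations. It is aimed at biomedical
signal-processing researchers who want a self-contained, fully tested
implementation that runs end to end on synthetic data with exact ground
truth — no downloads required.

## Method

Two generators and two discriminators form a CycleGAN: G1 maps an AECG
segment x to an FECG estimate, G2 maps back, and PatchGAN discriminators
D_x, D_y judge 4x4 grids of local patches. The training objective combines

* cycle consistency: `L_cyc = E||G2(G1(x)) - x||_1 + E||G1(G2(y)) - y||_1`,
* adversarial terms: `L_GAN = E[log D_y(y)] + E[log(1 - D_y(G1(x)))]` (and
  the mirrored pair), maximized by the discriminators, with the generators
  minimizing the non-saturating form, and
* a spectral identity penalty per batch of size N:
  `(2/N) Σ [1 - ρ(P(y_i), P(G1(x_i)))]·ρ(P(y_i), P(x_i))
   + (4/N) Σ [1 - ρ(y_i, G1(x_i))] + (1/N) Σ |p(x_i) - p(G1(x_i))|/p(x_i)`,
  with P a Welch power spectral density, ρ the Pearson correlation and p the
  mean signal power,

summed as `L = L_GAN + λ L_cyc + β L_id` (λ = 10, β = 5 by default). Each
generator runs three parallel 1-D convolution branches (kernels 3/5/7,
channels doubling 64→256) into a bidirectional LSTM with three output heads,
then a fully connected resize back to the 1024-sample input length.
Extraction reassembles per-segment outputs by overlap-averaging the shared
24 samples. Fetal QRS detection uses a Pan-Tompkins chain parameterized for
fetal rates, and a detection counts as correct within 50 ms of the
reference, giving Se, PPV, ACC and F1; signal quality is scored with MSE,
MAE, R² and SNR.

Everything — including the CNN-BiLSTM generators, PatchGAN discriminators,
Adam and backpropagation — runs on numpy via a compact reverse-mode autodiff
core bundled in the package (`fecgx.autodiff`), so the whole pipeline works
on a single CPU with no deep-learning framework.

## Worked example

```python
import numpy as np
from fecgx import (SynthConfig, synth_aecg, preprocess_pipeline,
                   PreprocessConfig, pan_tompkins_fqrs, evaluate_detection)

# 60 s of 4-channel abdominal ECG: maternal 75 bpm, fetal 140 bpm at
# one quarter of the maternal amplitude, plus wander/mains/impulse noise
aecg, fecg_clean = synth_aecg(SynthConfig(seed=42))
clean, model = preprocess_pipeline(aecg, PreprocessConfig())
print(clean.meta["preprocess_log"])

# detect fetal beats directly on the clean fetal reference channel
peaks = pan_tompkins_fqrs(fecg_clean.samples[0], fecg_clean.fs)
result = evaluate_detection(peaks, fecg_clean.r_peaks["fetal"], fecg_clean.fs)
print(f"TP={result.tp} FN={result.fn} FP={result.fp} "
      f"Se={result.se:.2f} PPV={result.ppv:.2f} F1={result.f1:.2f}")
```

prints

```
['baseline removed (cutoff 5 Hz)', 'notched 50 Hz (strength 35.1)',
 'impulse suppression applied', 'centered and whitened']
TP=140 FN=0 FP=0 Se=100.00 PPV=100.00 F1=100.00
```

i.e. the preprocessing chain identified and notched the 50 Hz mains
component, and the detector recovered every one of the 140 annotated fetal
beats on the clean reference with no false alarms. Training the CycleGAN
and extracting from the noisy abdominal mixture is one call:

```python
from fecgx.benchmark import run_synthetic_benchmark
res = run_synthetic_benchmark(seed=1)   # ~10 min on one CPU
print(res["fqrs_f1_pct"], res["extracted_r2_pct"], res["input_r2_pct"])
```

The CLI mirrors the stages (`fecgx synth`, `preprocess`, `train`, `extract`,
`detect`, `evaluate`, `viz-phase`, and `fecgx run --config run.yaml` for a
manifest-tracked pipeline).

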