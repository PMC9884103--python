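# msiaudit

Photon-limited SNR and channel-occlusion auditing of multispectral tissue
classification.

## The problem

Surgical multispectral imaging (MSI) systems acquire one scene under several
illuminants with an RGB sensor; each illuminant–sensor pair is a *spectral
channel* (here 7 illuminants × 3 sensors = 21 channels). Convolutional
networks trained on such channels classify tissue types better than networks
trained on white-light RGB alone — but which channels actually contribute,
and can a channel's worth be predicted from first principles?

This package implements, end to end, the analysis that answers that question
with a radiometric quantity: the **photon-noise-limited channel SNR**

```
S   = Σ_λ E(λ)·λ/(hc) · QE(λ) · Δλ · A_pixel · t_exp      (photons)
SNR = 20·log10(S / √S) = 10·log10(S)                       (dB)
```

where `E(λ)` is the illuminant spectral power, `QE(λ)` the sensor quantum
efficiency, `A_pixel` the pixel area (1 µm²) and `t_exp` the exposure
(30 ms). Shot noise is Poisson, so the noise is `√S`; sensor read noise is
deliberately excluded. A channel's *contribution* to a trained classifier is
measured by **occlusion sensitivity**: replace that channel with its
training-set mean and record the drop in the correct-class probability on
test patches. The package's headline computation correlates the two rankings
(Spearman) and audits a 20 dB threshold below which channels are inert.

Because the original cadaver image data were never deposited, every
experiment runs on a first-class synthetic scene generator that emulates the
acquisition: 21-channel cubes with per-pixel Poisson photon noise, 11 tissue
classes with smooth reflectance spectra, a UV+NIR blocking filter that is
removed only for IR illumination, irregular foreground masks, and grouping
of scenes into "specimens" for leakage-free 6/2/1 train/validation/test
splits.

## What's in the box

| module | role |
| --- | --- |
| `msiaudit.radiometry` | spectral curves, photon conversion, the 3×7 channel SNR table |
| `msiaudit.synthetic` | illuminants, sensor model, reflectance library, Poisson scene renderer, dataset generator |
| `msiaudit.patchwork` | foreground-only 32×32 tiling, channel views (`rgb3`/`msi18`/`msi21`), leakage-free splits, train-only normalization |
| `msiaudit.classifier` | compact dense-connectivity CNN (pure NumPy), Adam + cross-entropy + L2, 40-epoch protocol with best-epoch selection |
| `msiaudit.occlusion_audit` | channel means, occlusion maps, Spearman rank correlation, SNR-threshold report |
| `msiaudit.evaluation` | confusion matrices, micro/macro metrics, one-vs-rest ROC (pairwise AUC), DeLong test, 2×2 chi-square, two-class restriction, label/probability maps |
| `msiaudit.experiments` | the two designed end-to-end experiments (planted NIR band; SNR-graded contrast) |
| `msiaudit.pipeline` / `msiaudit.cli` | configured, manifest-tracked runs; `msiaudit run-all --out runs/demo` |

## Worked example

```python
from msiaudit.experiments import default_system, system_snr_table

lights, sensor, spec = default_system()
print(system_snr_table(lights, sensor, spec).to_frame().round(2))
```

```
   arri_white  sony_white  uv405  blue445  green525  red638  ir808
R       49.02       38.20   7.98    21.69     27.14   33.63  34.51
G       48.66       37.79  11.30    25.01     34.14   25.38  33.17
B       46.42       34.55  13.65    32.64     27.83   22.42  32.75
```

The broadband-white channels top out near 49 dB, matched narrowband pairs
sit in the 30 dB range, and the UV channels — whose light the blocked sensor
barely detects — fall below 14 dB. Running the planted-band experiment
(11 classes that differ only inside 790–860 nm, where only the IR channels
can see):

```python
from msiaudit.experiments import planted_nir_experiment

r = planted_nir_experiment(seed=1)
print(f"msi18 {r.msi18_test_accuracy:.3f}  rgb3 {r.rgb3_test_accuracy:.3f}  "
      f"chi2 p = {r.chi2_p:.1e}")
print("top occlusion channels:", r.top_occlusion_channels)
```

prints (seed 1)

```
msi18 0.456  rgb3 0.092  chi2 p = 2.9e-181
top occlusion channels: ('ir808:R', 'ir808:G', 'ir808:B')
```

— the 18-channel classifier recovers the planted information while the RGB
classifier stays at the 1/11 chance level, and occlusion attributes the
difference to exactly the three IR channels. The companion experiment with
spectrally uniform class contrast yields a Spearman correlation of ≈ 0.7–0.9
between channel SNR and occlusion sensitivity across seeds.

A full configured run with all artifacts (SNR tables, checkpoints, occlusion
heatmap, label maps, manifest with checksums):

```bash
msiaudit run-all --out runs/demo --seed 1
```

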