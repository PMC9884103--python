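# Methods

## Radiometric model

A spectral channel is one (illuminant, sensor) pair. Its maximum signal is
the photon count a pixel collects from a perfect (reflectance 1) surface in
one exposure:

S = Σ_λ E(λ)·λ/(hc) · QE_eff(λ) · Δλ · A_pixel · t_exp,

with E the illuminant spectral power in W·m⁻²·nm⁻¹, QE_eff the quantum
efficiency after any blocking filter, A_pixel = 1 µm² and t_exp = 30 ms.
Photon arrival is Poisson, so the noise is √S and

SNR = 20·log10(S/√S) = 10·log10(S) dB.

Sensor read noise is excluded by design: modern CMOS sensors contribute
under two electrons, negligible against shot noise at the counts considered
(tens to tens of thousands of photons). Because S is the *maximum* signal,
the channel SNR doubles as its dynamic range.

Numerical choices: all spectral curves live on a uniform 380–900 nm grid at
2 nm (covering the 400–810 nm broadband lights and the 808 nm line's tail);
resampling is linear interpolation with zero outside a curve's support; the
integral is a rectangle sum with the grid step as bin width. The SNR table
is invariant to grid refinement within 0.05 dB for the smooth default
curves. Channels with S = 0 carry NaN ("NA" in exported tables), never
−infinity, and rank last in orderings; ties in rankings break by the fixed
roster order (illuminants: ARRI broadband, Sony broadband, UV 405, blue 445,
green 525, red 638, IR 808; sensors R, G, B; channel index = 3·illuminant +
sensor).

## Synthetic acquisition model

The generator emulates a sequential-illumination MSI microscope so every
downstream stage is testable without proprietary image data.

**Illuminants.** Narrowband lights are Gaussian lines at their nominal
peaks (405/445/525/638 nm at 10 nm FWHM, 808 nm at 12 nm); broadband lights
are flat-tops with raised-cosine edges (400–810 nm and 450–700 nm). Peak
powers are free parameters of the simulation; the defaults were calibrated
once so that the 21 channel SNRs span roughly 8–49 dB with the structure of
a real system — broadband white highest (~46–49 dB), matched
narrowband/sensor pairs near 30 dB, UV lowest (8–14 dB). Absolute tissue
radiometry is not recoverable from published figures, so only this span and
ordering, not exact dB values, are modeled.

**Sensor.** Each RGB channel is a visible Gaussian lobe (B 460, G 540,
R 615 nm) plus a shared NIR shoulder near 820 nm (silicon response), a small
UV shoulder at 405 nm, and a flat 5% cross-talk pedestal over 400–700 nm
(dyed color filters leak a few percent). A UV+NIR blocking filter
(passband 420–700 nm, raised-cosine edges, 1% out-of-band leak) sits in the
optical path for every illuminant *except* IR, for which it is physically
removed — mirroring the acquisition protocol of the real device. With the
filter engaged the effective QE at 405 nm is below 1% of peak: the sensor
cannot detect the UV light, which is why the UV channels anchor the low end
of the SNR table.

**Reflectance.** Each of K classes (default 11, named for head-and-neck
tissue types) has a smooth mean spectrum: a shared base curve plus a
class-specific combination of broad Gaussian bumps whose rms amplitude is
the `separability` parameter (absolute reflectance units). Offsets are
normalized by the basis's *expected* rms — a class-independent constant — so
distinct classes keep distinct offsets. With `band_nm` set, the bumps are
localized inside that wavelength band, planting all between-class
information there and nowhere else. Intra-class variation has two knobs:
a per-scene lognormal scale jitter and a per-scene smooth additive
perturbation.

**Rendering.** Foreground is an irregular smooth closed contour (Fourier-
wobbled disk) covering 30–80% of the frame; per-pixel texture is a lognormal
gain on reflectance; each channel's mean count integrates
light × effective QE × realized reflectance, and observed counts are
Poisson draws stored as 16-bit integers with a full-well clip at 65535
(logged clip rate). Composite scenes with several labelled regions use a
per-pixel class map. Background pixels use a flat 2% reflectance. Scenes are
256×256 by default (a desk-scale stand-in for the 1920×1080 originals; both
are supported). Demosaicking is not simulated — channels are generated at
full resolution directly.

**Specimens and splits.** Scenes are grouped into "specimens" (default 9,
split 6/2/1 into train/validation/test), each contributing a configurable
number of scenes per class. Specimen ids are disjoint across splits by
construction, and the patch assembler re-validates this, so no specimen can
leak between training and evaluation.

What the generator does *not* emulate: real tissue reflectance spectra and
contrast (no public measurements to anchor them), autofluorescence,
radiative transfer, specularities, demosaicking artifacts, or anatomical
texture. Passing tests therefore demonstrate that the pipeline's mechanics
and the SNR–contribution relationship behave correctly under a controlled
photon-noise model, not that any particular clinical accuracy would be
attained on real tissue.

## Patching and normalization

Scenes are tiled on a grid anchored at pixel (0,0) into contiguous
non-overlapping 32×32 tiles, row-major, partial edge tiles discarded; a tile
is kept only if all 1024 mask pixels are foreground. Channel views: `rgb3`
is the broadband-white triplet (the non-multispectral baseline), `msi18`
drops the UV triplet (whose light the blocked sensor cannot detect; the
choice is configurable), `msi21` is everything. Raw photon counts span about
four decades across channels, so inputs are normalized with statistics
computed **from training patches only**. Three modes exist, because the
choice is scientifically loaded:

- `zscore` (default): per-channel standardization. Best conditioning, but it
  amplifies photon-starved channels to unit variance — a network can then
  overfit their noise, giving dead channels a small but nonzero occlusion
  footprint.
- `global`: a single scale constant shared by all channels. Conditions the
  inputs while preserving the physical amplitude hierarchy, as when a
  network consumes raw sensor counts; photon-starved channels stay
  structurally inert.
- `none`: raw counts. Faithful to an acquisition pipeline with no image
  transformations, but the four-decade dynamic range prevents the small
  network used here from training at all.

Class imbalance is preserved, never rebalanced.

## Classifier

A compact dense-connectivity CNN in pure NumPy (no deep-learning framework
is required at run time): a 3×3 stem convolution (stride 2) with a 2×2
average pool, then dense blocks in which every 3×3 convolution receives the
concatenation of the block input and all previous layer outputs and emits
`growth` new feature maps; 1×1 compression convolutions with average pooling
join blocks; global average pooling and an affine layer produce K-way
softmax probabilities. The default is 3 blocks × 4 layers with growth 12
(~70k parameters); the end-to-end experiments use a smaller 2×3/growth-8
net (~13k parameters) sized to the synthetic task and a single-CPU budget.
Backward passes are hand-derived (im2col) and verified against central
finite differences to 1e-5 in float64.

Training follows a fixed protocol: multiclass cross-entropy, Adam at
initial learning rate 0.001, L2 regularization 0.001 (added to the gradient,
weight matrices only), 40 epochs in batches of 128, no early stopping; the
epoch with the highest validation micro-accuracy is selected post hoc (ties
→ earliest). Batch order is the only stochastic element and derives from the
config seed, so training is bit-reproducible; there is no separate
nondeterministic mode to toggle. Argmax ties in prediction resolve to the
lowest class index.

## Occlusion audit

The per-channel mean is the scalar grand mean over all pixels of all
*training* patches, computed in the model's input space (after
normalization) so the substituted value is exactly the average the network
saw; requesting means from any other split raises. Occluding channel c sets
that channel of every patch to its mean, leaving other channels
bit-identical (pure function, idempotent). For each class k the signed
sensitivity is Δ[k,c] = mean correct-class probability before minus after
occlusion on test patches of class k; the class-averaged |Δ| ranks channels
(signed values are also reported, since a negative Δ means occlusion
*helped*). Spearman's rho between the SNR ranking and the sensitivity
ranking uses average ranks on ties and is undefined (NaN) for constant
inputs. The threshold report flags channels below 20 dB (configurable) and
checks whether each flagged channel's mean |Δ| stays under a nullity bound
of 0.01.

## Statistics

ROC curves enumerate every distinct score threshold without interpolation;
AUC is the pairwise (Mann–Whitney) statistic, ties counting one half,
computed via average ranks. DeLong's test uses midrank placement values and
the structural-components covariance estimator; its AUC agrees with the
pairwise definition to 1e-12 and its variance is validated against a
2000-replicate bootstrap. The 2×2 chi-square is Pearson's statistic without
continuity correction (patch counts are large enough that the correction is
immaterial; the choice is explicit) with p from the 1-df chi-square
distribution. Two-class restriction renormalizes the two chosen class
probabilities to sum to one, excludes (and counts) patches where both are
zero, and breaks ties toward the lower class index. Significance statements
use α = 0.001.

## The two designed experiments

**Planted NIR band** (`planted_nir_experiment`). The 11 class spectra
differ only inside 790–860 nm (separability 0.08). The broadband channels
are acquired through the blocking filter and cannot see this band, so the
`rgb3` classifier has nothing to learn (accuracy ≈ 1/11), while `msi18`
recovers the information through the IR channels; the accuracy difference is
tested with the 2×2 chi-square on ≥ 2000 test patches. A 21-channel model is
audited by occlusion: the three IR channels must attain the top
sensitivities and the below-20 dB UV channels must be inert (mean |Δ| <
0.01). This experiment uses the `global` normalization mode: the inertness
claim is about a network consuming physically scaled inputs, and per-channel
z-scoring would instead hand the network amplified UV noise to overfit —
a property of the preprocessing, not of the channels.

**SNR-graded contrast** (`graded_snr_experiment`). Class offsets are spread
uniformly over the whole spectrum at 0.0015 rms — small enough that
per-channel discriminability is limited by photon noise and therefore graded
by channel SNR across most of the 8–49 dB span. Intra-class variation
(0.0005/0.0003) and texture (2%) are kept below the planted contrast for the
same reason. This experiment uses the default `zscore` mode: with channel
amplitudes equalized, the only property distinguishing channels is their
noise level, which isolates exactly the effect the audit measures (and the
faint contrast this design needs is not learnable at raw amplitude scale).
A 21-channel model is trained per seed and the Spearman correlation between
channel SNR and occlusion sensitivity is the result; across seeds it lands
around 0.7–0.9. Above roughly 35 dB the common-mode nuisance floor, not
photon noise, limits discriminability, so the very top of the two rankings
can permute — one reason a synthetic desk-scale rho sits below a perfect
monotone relationship.

Problem sizes for both experiments — 256×256 scenes, 9 specimens (6/2/1),
one train scene per class per specimen, 10 (planted) or 4 (graded) test
scenes per class, and the 2×3/growth-8 network at the full 40-epoch
protocol — were chosen as the smallest configuration at which the planted
effects are unambiguous on a single CPU.

## Pipeline

`Pipeline` validates its YAML/dict configuration against a schema (unknown
keys rejected before any compute), runs simulate → SNR → patch → train →
evaluate → occlude → report, writes every artifact under the run directory,
and records a manifest with SHA-256 checksums and per-stage wall-clock.
Identical config and seed reproduce byte-identical CSV/JSON artifacts. The
`msiaudit` console script exposes each stage as a subcommand; training is
always deterministic, so no separate determinism flag exists.

## Known limitations

- Synthetic separability is a free parameter; nothing anchors it to real
  tissue contrast, so absolute accuracies are not comparable to any
  clinical result.
- The occlusion audit measures the *trained model's* reliance; with highly
  redundant channels the division of credit among them is partly arbitrary,
  which caps the SNR–occlusion rank correlation below 1 even when the data
  are perfectly SNR-graded.
- The NumPy network is small by design; it is not a drop-in replacement for
  GPU-scale DenseNets, and wall-clock scales linearly with patch count.
- DeLong and chi-square assume independent patches; patches from one scene
  share acquisition noise, so reported p-values are optimistic in the same
  way as in the patch-based literature.
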