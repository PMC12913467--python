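# Methods

## Problem and model

Given a subject's baseline structural brain MRI `I_bl ∈ R^{X×Y×Z}` (already
skull-stripped and linearly registered to a common space), the package
forecasts the follow-up image `Î_yx = G(I_bl, S_yx)` at a chosen inter-scan
interval (one year, four years, or either one from a single model).  The
central idea is the *progress map* `S_yx`: a group-level spatiotemporal
prior summarizing how brains change over that interval, computed from the
training split only and injected into a conditional generator.

### Progress maps

Two forms are supported:

- **Residual map** — the voxel-wise arithmetic mean of
  `(follow-up − baseline)` over all training subjects with a follow-up at
  the interval.  The sign convention is follow-up minus baseline, so
  atrophy appears as negative values in tissue.  Residual maps are kept in
  their native signed units, preserving the direction of change.
- **Edge map** — the 3D Sobel gradient magnitude of a residual map.  Each
  axis response is the separable kernel (derivative stencil `[-1, 0, +1]`
  along the gradient axis, `[1, 2, 1]` smoothing along the two orthogonal
  axes, via `scipy.ndimage.sobel`); the three responses combine as a
  Euclidean magnitude.  Boundary handling is replicate-edge, avoiding
  spurious ridges where a nonzero background meets the volume edge.  Edge
  maps are min-max scaled to [0, 1] per map so the conditioning signal is
  bounded; the scaling is recorded in the map's JSON sidecar.

Residual maps are computed on the same preprocessed (signed-normalized)
representation the network consumes.  Provenance (the subject ids averaged)
is stored with every map, and `assert_no_leakage` refuses any map whose
provenance intersects validation or test subjects — the pipeline calls it
before every evaluation.

### Generator

A 3D U-Net: four stride-2 encoder stages (4³ kernels; each block
Conv → leaky-ReLU(0.2) → batch-norm) and four decoder stages (each block
Deconv → batch-norm → leaky-ReLU) with concatenation skips, closed by a
1×1×1 convolution and a tanh head so predictions live in the [-1, 1]
training range.  At full scale the encoder channel pairs are
(in, 64), (64, 128), (128, 256), (256, 512).  The decoder's *block-level*
pairs (512, 512), (512, 256), (256, 128), (128, 64) count the concatenated
skip in each block's output, i.e. the deconvolutions themselves emit
256, 128, 64, 64 channels — the only wiring under which the printed pairs
are mutually consistent with concatenation skips.  Convolution padding
follows the 'same' convention (each axis maps to `ceil(n/2)`), deconvs
exactly double each axis, and decoder outputs are cropped to the matching
encoder stage when odd sizes arise (e.g. the 90×98×90 grid descends
45 → 23 → 12 → 6).

Conditioning variants:

- `image_concat` — the map is stacked as a second input channel
  (first conv (2, 64));
- `ffm` — a learned strided convolution (1→128 channels, kernel 4³,
  stride 2³) embeds the map into a spatial (scale, shift) pair — first 64
  channels scale, last 64 shift — which modulates the stage-1 feature block
  as `F_out = scale ⊙ F_in ⊕ shift`.  The modulation applies to the block
  output (post-activation, post-norm); the insertion point is an
  interpretive choice;
- `ffm_parallel` — a second fusion at stage 2 whose parameters are computed
  from the stage-1 *fused* feature maps;
- `ffm_cascade` — a second fusion at stage 2 whose parameters come from a
  fresh two-conv stack (1→64→2·128, kernel 4, stride 2 twice, with a leaky
  ReLU between) applied to the raw map;
- `mffm` — multi-view fusion: age and sex pass through two fully connected
  layers to a per-channel (scale, shift) that is *added* to the map-derived
  pair before modulating, `F_out = (γ_a + γ_m) ⊙ F_in ⊕ (β_a + β_m)`;
- `attr_concat` (mi-GAN) — the attribute vector tiled onto the bottleneck;
- `attr_film` (FiLM-GAN) — per-channel FiLM on the first three encoder
  blocks, parameters from a two-layer attribute MLP.

Attributes are (target age min-max scaled over the training split, sex as
{0, 1}).  Weights initialize as N(0, 0.02) with zero biases from a seeded
generator.

### Discriminator

Unconditional: four stride-2 conv + leaky-ReLU stages with full-scale
channels (1, 32), (32, 64), (64, 128), (128, 256), then fully connected
layers of 1000 and 1 units and a sigmoid.  It never sees the progress map;
conditioning acts only through the generator.

### Losses and optimization

    L_adv(G, D) = E[log D(I_yx)] + E[log(1 − D(G(I_bl, S_yx)))]
    L_total     = L_adv + α · L1,   α = 60

One discriminator ascent step then one generator descent step per
minibatch (pix2pix convention), Adam with β1 = 0.5, β2 = 0.999 (framework
default; only β1 is prescribed) and learning rate 1e-4 for both networks.
The generator minimizes the literal `log(1 − D)` term by default; a
`non_saturating` switch substitutes `−log D(fake)` because the literal
form can stall when the discriminator saturates.  Early stopping monitors
the generator total loss on the validation split and stops after 10
consecutive non-improving epochs; the checkpoint holds the weights of the
best validation epoch.  Batch-norm running statistics are frozen for
validation and evaluation.  In multi-term training every example is a
(subject, interval) pair carrying its own interval's map, so one weight set
serves both horizons.

### Numerical backend

The 3D convolution layers, transposed convolutions, batch normalization,
reverse-mode autodiff and the Adam optimizer are implemented on numpy
(float32 by default).  The strided 'same' convolution and the deconvolution
are exact adjoints — verified by an inner-product identity and by
numerical differentiation in the test suite — so desk-scale training is
fully deterministic given a seed: identical seeds reproduce loss
trajectories bit-for-bit.

## Preprocessing

Central crop (window centred, ties toward the lower index) → integer-factor
downsampling by local mean (anti-aliasing choice; the literature leaves the
kernel unstated) → per-volume min-max normalization to [0, 1] → affine
rescale to [-1, 1].  Per-volume normalization is the standard reading of
"min-max normalization" applied to a single image; normalization happens
after crop and downsample.  The nominal full-scale chain takes 182×218×182
registered scans to 180×196×180 and then to 90×98×90.

## Evaluation

NRMSE, SSIM and PSNR, computed on the [0, 1] representation with MAX = 1.
PSNR is invariant to the consistent affine range choice; SSIM's stabilizers
C1 = (0.01·MAX)², C2 = (0.03·MAX)² are not, so the convention is fixed.
SSIM uses a 7³ uniform window with sample-covariance normalization and
edge cropping, matching the volumetric default of the scikit-image API the
package is tested against (agreement ≤ 1e-6 on random pairs).  The NRMSE
denominator is the ground-truth norm by default (the reference-API
convention); a `denominator="prediction"` switch implements the
prediction-normalized variant, since the two conventions coexist in the
literature.  Identical volumes give an infinite PSNR sentinel, excluded
from aggregates with a warning.  Metrics are computed on full volumes
(background included).

Model pairs are compared with two-sided paired t-tests per metric at
p < 0.05, aligned on (subject, interval); all-zero difference vectors give
p = 1, and zero-variance nonzero differences are flagged as exact
differences rather than fed to the t formula.  Signed error maps
(prediction − truth) support slice-wise qualitative rendering (blue =
over-, red = under-prediction).

## Synthetic cohort

The generator emulates the structure of a longitudinal ageing/dementia MRI
study: co-registered intensity volumes on a common grid, a group-level
change process whose magnitude grows with the inter-scan interval,
per-subject heterogeneity, and acquisition noise.  The phantom is a pair of
concentric smooth ellipsoids — a bright tissue shell (amplitude 0.8) around
a darker ventricle cavity (0.1) on zero background, with sigmoidal edges —
chosen for analytic tractability: the image is a closed-form function of
the ventricle scale and shell amplitude, so the exact group change field is
available as an oracle.

Follow-up at interval `t` years applies ventricle radial growth
`×(1 + g·t·f_s)` and shell-intensity decrease `−c·t·f_s`, where
`f_s ~ lognormal(0, σ_h)` is a per-subject multiplicative factor on both
rates (log-normal keeps the change direction consistent across subjects).
Additive Gaussian noise (σ_n) follows the deformation; intensities are then
clipped to [0, 1].  Defaults: g = 0.05/year, c = 0.02 intensity units/year,
σ_h = 0.2, σ_n = 0.02 — a visible but noisy change signal over one to four
years, in the spirit of reported ventricular enlargement rates in ageing
and dementia cohorts.  Ages draw from N(71.3, 7.2) clipped to [55, 90],
sex is balanced Bernoulli.

What the phantom does *not* model: MRI physics (bias fields, partial
volume), elastic/diffeomorphic deformation, multi-site intensity
differences, lesions, or disease-stage structure.  Change here is purely
intensity-based and spatially shared across subjects up to a scalar factor,
so passing tests demonstrate the pipeline's correctness and the value of a
group prior under these idealized conditions — not clinical performance on
real scans.

## Desk-scale profiles and the standard benchmark

Full-scale settings (90×98×90 grids, 64 base channels, batch 4) are a
configuration away but impractical on CPU.  The shipped desk profile uses
32³ grids, base width 8 (all channel counts divided by 8), batch 2.  The
standard benchmark — used by the directional acceptance test and
`scripts/acceptance.py` — is 40 synthetic subjects at 32³ with the default
rates and noise, split 32/4/4 (the study's 170:20:20 proportions), 20
epochs maximum, three seeds per variant, comparing the residual-map FFM
model against the unconditioned baseline GAN by the median over seeds of
the test-split mean NRMSE.  At these sizes neither model is near
convergence; the benchmark probes the *ordering* (the map-conditioned
model should reconstruct no worse), not the asymptotic image quality.

## Known limitations

- The numpy backend is single-threaded BLAS-bound; full-scale training is
  out of reach without a GPU framework.
- The phantom's group change field is identical across subjects up to a
  scalar, which is more favourable to a group prior than heterogeneous
  real anatomy; the benchmark ordering should be read accordingly.
- FFM insertion at the stage-1 block output, the deconv/skip channel
  accounting, and the leaky-ReLU slope 0.2 are interpretive choices where
  the architecture description is ambiguous or silent.
- Batch-norm placement follows the block descriptions literally
  (Conv → activation → norm on the way down, Deconv → norm → activation on
  the way up) even though the order is unconventional.
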