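# Methods

## Problem and model

Total-absorption photoacoustic remote sensing (TA-PARS) microscopy records
three label-free contrasts per excitation pulse: non-radiative absorption
(heat, dominated by nuclear chromophores at UV excitation), radiative
absorption (re-emitted photons, dominated by extranuclear structures such
as cytoplasm and connective tissue), and optical scattering of the
detection beam. Because hematoxylin stains nuclei and eosin stains the
extranuclear compartment, these channels carry the same information a
pathologist reads from an H&E slide, and a conditional image-to-image
translation model can colorize them into a virtual H&E render.

`parstain` implements the full computational chain: image formation from
per-pulse records, co-registration of brightfield H&E onto the TA-PARS
frame, intensity normalization, patch tiling, pix2pix-style adversarial
colorization, and Lab-space SSIM/RMSE evaluation — exercised end-to-end on
a synthetic tissue phantom so no instrument or tissue data is needed.

## Synthetic phantom

The phantom is a generative model of a thin stained section with complete
ground truth. Its defaults define the conditions under which every test
and reference experiment runs:

- **Nuclei**: random ellipses, count Poisson with mean
  `nuclei_density x area / 1e4` (default 5 per 100x100 px), semi-axes
  Gaussian (mean 6 px, sd 1.5 px at the native 250 nm pitch, i.e. ~1.5 um —
  the scale of nuclei in a thin section), orientation uniform, intensity
  0.7-1.0. The nuclear concentration map `c_n` is positive exactly on
  drawn ellipses.
- **Extranuclear tissue** `c_e`: Gaussian-filtered white noise (cytoplasm
  texture, sigma 4 px), 12 fibers drawn as bounded-curvature random walks
  smoothed to ~2 px thickness (connective tissue), and up to 3 bright
  elliptical blobs (vessels). Vessels are folded into `c_e` rather than
  added as a fourth compartment so the `c_n` support invariant holds; they
  still appear in all three channels (strongly in radiative/scattering,
  weakly in non-radiative through cross-talk).
- **Channel forward model**: non-radiative `0.9 c_n + 0.09 c_e`, radiative
  `0.9 c_e + 0.09 c_n`, both plus additive Gaussian noise (sd 0.02 per
  channel); scattering is smoothed `c_n + c_e` with multiplicative
  speckle. The 10% cross-talk encodes that each contrast *favours* one
  compartment without being exclusive to it. Channels are clipped to
  [0, 1]. Relative channel SNRs are free parameters, not calibrated to any
  instrument.
- **H&E render**: Beer-Lambert mixing, `RGB = exp(-(d_h c_n S_h +
  d_e c_e S_e))` with the standard unit-norm hematoxylin (0.65, 0.70,
  0.29) and eosin (0.07, 0.99, 0.11) absorbance directions and doses
  (1.8, 1.0) chosen to give realistic stain depth.
- **Misregistration**: a control grid in the moving frame receives random
  displacements of magnitude at most `warp_amplitude_px` (default 5 px);
  a thin-plate spline through the displaced grid resamples the H&E render.
  The true forward transform and the true landmark pairs are returned, so
  registration error can be measured against exact ground truth.
- **Scan stream**: one pulse record per pixel in raster order at pixel
  centers (optionally jittered), features equal to pixel values.

Everything is a pure function of `(spec, seed)` and reproduces
bit-identically.

What the phantom does *not* emulate: optical point-spread functions,
biophysically accurate photoacoustic signal generation, stain variability
between laboratories, section-thickness effects, tissue folds or other
real-slide artifacts, and whole-slide scale. Passing tests demonstrate
that the pipeline's machinery is correct and self-consistent, not that
the learned colorization would transfer to real tissue.

## Image formation

Per-pulse traces are compressed to a scalar with the peak-above-baseline
reducer `max(trace) - median(trace)` (alternatives: integral, max). The
field's convention for point-scanned photoacoustic data is an amplitude
projection; the median is a robust baseline. Records are assigned to the
nearest pixel center on a Cartesian grid (half-open pixel convention,
origin at top-left, positions map to centers), multiple records per pixel
are averaged, and unvisited pixels are filled from their nearest sampled
neighbor and flagged in a validity mask. Binning (not interpolation) is
the default grid fit because it is exactly invertible on jitter-free
streams, which gives the reconstruction an exact round-trip test.

## Registration

The TA-PARS stack is the reference frame; H&E is the moving image. All
matching uses the non-radiative channel only (the three TA-PARS channels
are intrinsically co-registered). The moving-side matching raster is the
optical density of the red channel, `-log(red)`: hematoxylin absorbs
strongly in red while eosin barely does, and the log linearizes the
Beer-Lambert response, so both rasters are approximately linear in the
nuclear concentration — the regime in which normalized cross-correlation
peaks are unbiased.

Stages:

1. **Pitch match**: bilinear resample of the moving image by the pitch
   ratio.
2. **Coarse landmarks**: a regular grid of candidates filtered by local
   standard deviation (flat windows carry no matchable texture; if fewer
   than 8 candidates pass, the highest-variance candidates are kept).
   Each is refined to the best integer offset within `+-search_px` by
   windowed NCC (ties toward zero shift), with separable parabolic
   subpixel interpolation of the peak; matches with peak NCC below 0.5
   are dropped (with a fallback to the unfiltered set if the survivors
   are degenerate).
3. **Iterative subpixel passes** (default 2 more): the moving image is
   warped with the current fit, and the residual displacement at each
   landmark is measured by upsampled phase cross-correlation on
   Hann-windowed 32 px patches. Phase correlation resolves ~0.05 px
   shifts once the residual warp is locally near-uniform; a single NCC
   pass cannot, because the warp varies across the matching window.
4. **Transform fit**: thin-plate spline (exact landmark interpolation,
   minimal bending energy), solved from the standard augmented kernel
   system with `U(r) = r^2 log r`; affine least squares also available.
   The TPS was chosen as the canonical landmark-interpolating non-rigid
   family: its exact-interpolation property makes the fit testable, and
   scipy's RBF interpolator provides an independent oracle in the tests.
5. **Warp**: inverse-mapping bilinear resample; out-of-bounds pixels are
   filled white (the brightfield H&E background) and flagged. Mapped
   coordinates within 1e-6 px of the border count as in-bounds so that
   numerically fitted identity transforms do not flag edge pixels.

On 256 px phantoms with 5 px warps this recovers landmarks to ~0.3-0.5 px
mean residual and ~1% interior mean absolute error.

## Normalization

Per channel: min-max normalize, contrast-stretch saturating the bottom 1%
and top 1% of all pixel values (percentiles over the whole image, linear
interpolation between order statistics — pinned so the tests can assert
exactly), then color-reverse (`x -> 1 - x`) so strong absorbers appear
dark, matching grayscale H&E. Channel order is fixed:
(non-radiative, radiative, scattering). The preparation is logged in a
provenance list; re-preparing an already-prepared stack warns. Per-channel
normalization is the default (a flag switches to global) and "histogram
matching" is implemented as reversal only, with optional matching to a
reference off by default.

## Tiling and stitching

Square tiles (256 px at full scale, 64 px at phantom scale) with ~50%
overlap; anchors at multiples of `stride = round(tile x (1 - overlap))`
with the final anchor clamped to `dim - tile` (deduplicated), and a
single reflect-padded tile for images smaller than one tile. Stitching
blends tile predictions with a separable raised-cosine window floored at
1e-3, normalized per pixel to a partition of unity — so constant tiles
stitch to the exact constant and round trips are lossless to float
precision. The floor keeps border pixels of edge tiles from being
annihilated where only one tile contributes.

## Colorizer

A pix2pix-style conditional GAN mapping the 3-channel prepared stack to
RGB:

- **Generator**: U-Net — stride-2 convolution encoder, nearest-upsample +
  convolution decoder with mirrored skip concatenations, LeakyReLU(0.2)
  activations, sigmoid output (bounded in [0, 1] for any finite input).
  Depth 3 / base width 8 at 64 px tile scale; depth 5 / width 32 would be
  the 256 px configuration. Normalization layers are omitted: at this
  scale, with an L1-dominant objective, they add nothing but make the
  hand-verified backward pass larger.
- **Discriminator**: patch-level classifier on the 6-channel
  concatenation of input stack and (real or generated) RGB; two stride-2
  4x4 convolutions plus a final 4x4 convolution produce a logit map
  spatially smaller than the input, each score depending on a bounded
  receptive field.
- **Losses**: discriminator — mean binary cross-entropy with targets 1
  (real pair) and 0 (generated pair); generator — BCE of its fake scores
  against target 1 plus `lambda_l1 = 100` times mean absolute error to
  the registered H&E. Training uses the numerically stable
  logit formulation; the public loss functions operate on probability
  maps and satisfy the closed forms asserted in the tests (uniform 0.5
  scores give `2 ln 2`; the worked generator example gives `ln 2 + 10`).
- **Optimization**: Adam (beta1 0.5), alternating
  discriminator/generator updates per batch. The full-scale convention is
  lr 2e-4; the miniature phantom-scale configuration uses lr 1e-3 and
  batch 4, which converges in ~100 epochs where 2e-4 needs several
  hundred (the mapping from prepared channels to stain colors is close to
  pixelwise, so the small network tolerates the larger step).
- **Early stopping**: maximum 500 epochs at full scale with patience 20
  and min-delta 1e-4 on the total validation generator loss (training
  loss when no validation split is given); the best-validation parameters
  are kept. Patience 0 stops at the first non-improving epoch.
- **Determinism**: all initialization and shuffling flow from one seed;
  identical data + config + seed reproduce identical histories.

The network framework itself (strided im2col convolutions, Adam, BCE/L1)
is implemented in `parstain.nn` on float32 numpy arrays, with gradient
correctness pinned by finite-difference checks in the test suite (run in
float64, with weights scaled up so gradients sit well above
finite-difference noise).

Inference tiles the stack, runs the generator per batch, stitches with
the raised-cosine window, and verifies that the input's preprocessing
provenance matches what the bundle was trained on.

## Evaluation

Predictions and ground truth are converted to CIELAB (sRGB companding,
D65) before metrics, since Euclidean structure there tracks perception.
SSIM uses the standard luminance-contrast-structure form with a uniform
7 px window, unbiased sample covariances, stabilizing constants
`(0.01 R)^2` and `(0.03 R)^2`, and the mean over fully interior windows;
dynamic range is 100 on L and 255 on a/b, and the three channel SSIMs are
averaged. RMSE is pooled over the three Lab channels and reported in
native Lab units (the unit convention is recorded in every report).
`evaluate_pair` samples patch locations uniformly with replacement
(seeded; 1000 patches of 256 px at full scale) and reports mean +- sample
standard deviation.

## Reference experiments (`parstain.protocols`)

**Overfit bracketing** (phantom analogue of the train-equals-test upper
bound protocol): on a 512 px phantom cut into 64 non-overlapping 64 px
tiles, one model is trained on all tiles and one on the 48 tiles outside
a 16-tile evaluation subset (both 100 epochs); both are scored by Lab
SSIM on the same evaluation subset. Scoring both models on identical
tiles isolates the effect of having seen them from tile-content
difficulty. Typical results: upper bound ~0.93-0.95, held out
~0.90, and the upper bound also holds on the full training set
(>= 0.9 against a 0.80 floor). These sizes keep the experiment around
seven minutes on one CPU.

**Registration recovery**: a 256 px phantom with a 5 px warp (the
pipeline is specified for amplitudes up to 8 px) is registered back;
landmark residuals are measured against the exact inverse warp and the
recovered image against the unwarped render.

## Numerical choices and degenerate inputs

- Percentile definition: linear interpolation (numpy default), computed
  over the whole channel; a constant channel stretches to all zeros and
  then reverses to all ones.
- A flat NCC window leaves its landmark unchanged with a warning; a
  degenerate landmark configuration (duplicates, collinear) raises an
  error naming the offending points.
- TPS systems are solved directly; duplicate source points would make the
  kernel singular and are rejected beforehand.
- Stitch weights are floored at 1e-3 before normalization; the partition
  of unity is asserted to 1e-9 in the tests.
- Images smaller than one tile are reflect-padded to a single tile and
  cropped after stitching; a single covering tile is returned exactly.
- The seed for every derived random stream is a fixed offset from the
  run seed, so stages are independently reproducible.

## Known limitations

- Phantom realism, as listed above; in particular the channel->stain
  mapping is nearly pixelwise, so colorization converges far faster and
  more accurately than it would on real tissue, and the reported SSIM
  values say nothing about real-tissue performance.
- The colorizer runs on a CPU-only numpy framework: full-scale (256 px
  tiles, tens of thousands of patches, depth-5 networks) training is out
  of reach; the package targets the miniature configurations above.
- Landmark refinement assumes enough local texture; fields that are
  mostly empty background will register poorly (the variance filter then
  falls back to the least-flat candidates rather than failing).
- `match_fov` assumes correct pitch metadata; there is no automatic scale
  estimation.
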