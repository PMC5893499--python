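# Methods

This note documents the models and procedures glioscan implements, the
parameters that matter, the numerical choices, and what the synthetic
phantoms do and do not establish about real MR images.

## Pipeline model

An 8-bit 2D grayscale image flows through:

1. **Preprocessing** — 3×3 median filtering (edge replication at the
   borders). The median is chosen because MR acquisitions are commonly
   corrupted by impulse-like noise and the median removes it without
   blurring the tumor boundary; `method=none` bypasses it. MSE and PSNR
   between original and denoised image quantify how much the filter
   changed.
2. **Seeded region growing** — from a seed (by default the pixel of the
   brightest-1% set nearest that set's centroid; hyperintense lesions
   make "brightest region" a reasonable automatic proxy), the region
   absorbs any 4-connected neighbor with `|intensity − region mean| ≤ δ`.
   δ = 10 gray levels by default on the 8-bit scale — roughly 2–3
   noise standard deviations after median filtering, small against the
   ≥50-level tumor/tissue contrast the method assumes.
3. **Morphological cleanup** — opening with a 3×3 square structuring
   element, removal of 8-connected components under 25 px, and selection
   of the largest survivor. The reported tumor area is the count of true
   mask pixels.
4. **Wavelet decomposition** — separable 2D DWT, orthonormal Haar,
   symmetric half-point boundary extension, 4 levels (5 available).
   Level k decomposes level k−1's LL. LH carries horizontal-edge detail
   and HL vertical-edge detail (equivalently, pywt's cH and cV).
5. **GLCM features** — each selected LL/HL subband is min–max quantized
   to G = 8 levels, a symmetric co-occurrence matrix is accumulated at
   distance S = 1 for 0°/45°/90°/135°, and contrast, correlation,
   energy, homogeneity and entropy are averaged over the four angles.
   G = 8 keeps the 8×8 matrix well populated even for the 16×16 level-4
   subbands of a 256×256 image; the quantization is per-subband min–max,
   so features are invariant to adding a constant to the input.
6. **PNN classification** — Gaussian Parzen kernels (σ = 0.5 on
   z-scored features) centered on each stored training pattern, averaged
   per class, argmax decision.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| median window | 3 | px | smallest window that kills single-pixel impulses |
| δ (region growing) | 10 | gray levels | ≈2–3 post-filter noise SDs, ≪ assumed ≥50 contrast |
| connectivity | 4 (grow), 8 (labeling) | – | conservative growth, permissive component merging |
| mean mode | running | – | "the region's mean" naturally tracks the region; `fixed` freezes the seed mean and makes growth order-independent |
| structuring element | 3×3 square | px | smallest isotropic-ish opening element |
| min component | 25 | px | well below any plausible tumor, above speckle |
| wavelet / depth | Haar / 4 | – | orthonormal, exact small worked examples; 5 available |
| subbands | LL + HL per level | – | approximation plus vertical detail drive the texture contrast |
| G, S, angles | 8, 1, four | – | standard Haralick configuration at subband resolution |
| σ (PNN) | 0.5 | z-score units | mid-range kernel width; a leave-one-out grid search helper (`loo_sigma_search`, σ ∈ logspace(−2, 1, 20)) is provided |

## Numerical choices

- **PSNR** is implemented in two forms behind a flag: `as_printed`
  divides the peak `2^m − 1` by MSE (the form often printed in the
  applied literature, which yields small or negative dB values), and
  `standard` divides by √MSE. `as_printed` is the default; identical
  images return `+inf`.
- **Sources deeper than 8 bits** are min–max rescaled to [0, 255] on
  load (constant images map to 0), so GLCM quantization and the PSNR
  peak use m = 8 uniformly. Color inputs are collapsed with 0.299/0.587/
  0.114 luminance weights and rounded before range handling. Multi-frame
  DICOM is rejected rather than silently taking a frame.
- **Region growing determinism**: the frontier is FIFO; neighbors are
  pushed up, left, right, down, then up-left, up-right, down-left,
  down-right; each pixel is examined at most once. Running-mean results
  are therefore reproducible despite being order-dependent in principle.
- **GLCM correlation** is undefined when a marginal SD is zero (e.g. a
  constant subband); it is NaN at the statistic level and mapped to 0
  with a logged warning inside feature vectors, so degenerate inputs
  cannot poison classifier distances. The energy statistic includes the
  square root.
- **Morphology conventions**: dilation uses the reflected structuring
  element; pixels outside the image are false for both operators, so an
  all-true mask erodes to its interior. Largest-component ties break by
  scan order (lowest label).
- **PNN numerics**: kernel activations are computed after subtracting
  the minimum squared distance (a positive rescaling that preserves the
  argmax), so the σ → 0 nearest-neighbor limit survives floating-point
  underflow; reported scores stay on the absolute scale. Scores within
  1e−9 relative of the maximum are treated as exact ties and resolved by
  the declared class order, which also fixes the σ → ∞ limit. Per-class
  *averaging* (rather than summing) makes scores invariant to class
  imbalance. Zero-variance feature dimensions get SD 1 with a warning.
- **Wavelet feasibility**: a depth is feasible when every level's input
  keeps both dimensions ≥ 2 (a 2×2 input may legally produce 1×1
  subbands); infeasible requests fail naming the deepest feasible level.
  Perfect reconstruction holds to < 1e−8 for any orthonormal filter; the
  `periodization` boundary mode gives exact 1-level energy conservation.

## The phantom generator

Phantoms emulate the gross appearance the pipeline relies on: an
elliptical region of textured "tissue" (Gaussian white noise blurred to
a 4 px correlation length, amplitude 10 gray levels, around intensity
120) on a black background, with an optional brighter elliptical tumor,
plus additive Gaussian noise (SD 5) and 1% salt-and-pepper impulses.
The tumor renders as a homogeneous enhancing mass at
`brain_intensity + offset` (offset drawn from 60–100 across a cohort):
its interior variability is set by the acquisition noise alone, which is
what makes a single intensity-homogeneity criterion (the δ threshold) an
appropriate segmentation model. Labels and masks are ground truth by
construction, independent of segmentation success. Dataset generation
jitters tumor position (±12 px), semi-axes (12–26 px) and offset per
item from a seeded RNG, so cohorts are exactly reproducible.

What the phantoms deliberately lack: skull, CSF, gray/white matter
classes, bias fields, partial-volume gradients at the tumor rim, 3D
structure, and any MRI physics. Passing the end-to-end tests therefore
shows the pipeline is implemented correctly and behaves as designed when
its assumptions (bright, roughly homogeneous lesion; ≥50-level contrast;
moderate noise) hold — it does not show the method reaches any
particular accuracy on clinical images, where those assumptions are
routinely violated.

## Experiment protocol and problem sizes

The packaged phantom study uses 30 + 30 training and 10 + 10 test
images of 256×256 px — large enough for four decomposition levels and
stable GLCMs while keeping a full run in the order of seconds.
Resubstitution ("trained") accuracy is reported alongside held-out
("tested") accuracy because the two are the natural pair to compare, but
resubstitution is optimistic by construction and should not be quoted as
performance. Every experiment writes a provenance record (full parameter
dump, SHA-256 config hash, seeds, cohort sizes).

## Known limitations

- Single 2D images only; no volumes, no registration, no bias-field
  correction or skull stripping.
- One region per image: the pipeline returns the largest cleaned
  component and cannot represent multifocal disease.
- Automatic seeding assumes the lesion is the brightest structure; on
  images where it is not (e.g. T1 hypointense lesions), seeds must be
  supplied explicitly.
- The feature set is fixed (five Haralick statistics over LL/HL); no
  variance/run-length/LBP textures and no alternative classifiers.
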