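# Methods

This note documents the models and procedures implemented in `msilazy`, the
parameter choices that matter, what the synthetic phantoms do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Lazy imzML access

imzML splits a dataset into an XML header and an external binary container
(`.ibd`) whose first 16 bytes repeat the dataset UUID. The parser is a
streaming event parse (`lxml.etree.iterparse`): each `<spectrum>` element is
reduced to a fixed-size record (pixel position, byte offsets, element
counts, optional in-file normalization factor) and the element is freed, so
parser memory is proportional to the number of spectra, never to the binary
size. The UUID is always verified against the `.ibd` header; offsets are
checked against the file size; `continuous` datasets must share one m/z
array offset. Optional imzML checksums (SHA-1/MD5) are *not* verified — a
checksum pass over a multi-gigabyte container would defeat lazy loading.

Binary encoding is little-endian with dtypes taken from the CV params
(32/64-bit float or integer); writes default to 64-bit m/z and 32-bit
intensities, the common vendor convention. Pixel positions are 1-based in
the file (imzML convention) and 0-based row-major internally; conversion
happens only at the I/O boundary. Three dialects are read and written:
continuous-profile, continuous-centroid (shared m/z axis stored once) and
processed-centroid (per-spectrum axes). The per-spectrum normalization
factor is carried as a spectrum-level `userParam`, as imzML has no
standard accession for it.

### Deterministic chunked iteration

Whole-image passes assign contiguous, near-equal index ranges to worker
threads. Reductions are folded inside fixed blocks of 64 spectra and then
across blocks in index order, regardless of the worker count. Floating-point
addition is not associative, so a naive per-worker fold would change results
in the last ulp when the worker count changes; the fixed block tree makes
chunked results bit-identical for any number of workers. The block partials
(one reduced value per 64 spectra) are the only intermediate state.

### Memory model

Retained core memory after initialization is
`E = |I|(2δ_d + δ_i + δ_s) + (3 + T)|S| δ_d`: the ion-image placeholder and
normalization-factor rasters (float64), the spectrum-index raster (int32),
the validity mask (int16), three overview spectra of depth |S| (float64),
plus one working spectrum per worker thread. `estimate_memory` evaluates
this exactly; the test suite asserts that the bytes actually retained by
`initialize_artefacts` equal the T=0 evaluation.

## Signal processing

Processing order is fixed: **normalize → smooth → baseline-correct**.
Pixel-to-pixel multiplicative variation must be removed before anything
else; smoothing before baseline estimation keeps the morphological opening
from locking onto noise minima.

* **Normalization** divides intensities by a per-spectrum scalar f: the
  total ion count, the median intensity, an in-file factor, or 1. A TIC or
  median of an all-zero spectrum raises a degenerate-spectrum error; a
  missing in-file factor raises an explicit error rather than silently
  substituting 1.
* **Savitzky–Golay smoothing** (scipy, `mode='interp'`): each point is the
  centre of a least-squares polynomial over the window; edges evaluate the
  polynomial fitted to the first/last full window. Smoothing is off unless a
  window is given — there is no standardized default. The peak-recall
  analyses here use window 5, order 2, because the phantom's peaks span only
  ~6 samples (FWHM 0.59 Da at 0.2 Da spacing) and a 9-point window
  attenuates such apices by ~30%.
* **Baselines**: top-hat = morphological opening (erosion then dilation,
  flat structuring element of width 2·halfwidth+1, reflect boundaries) —
  anti-extensive and idempotent, so the baseline never exceeds the signal;
  running median = windowed median of the same width with shrinking windows
  at the edges (even-length windows take the midpoint mean). The halfwidth
  is specified in samples, not Da: resolution-agnostic and standard
  morphological practice. Corrected intensities are clipped at zero because
  downstream peak picking assumes non-negative signal.

## Peak analysis

Noise is `1.4826 · median(|x − median(x)|)` — the MAD scaled for consistency
with a Gaussian σ, robust to isolated peaks. A peak is an index whose
intensity equals the maximum of its clipped sliding window, exceeds
`snr_threshold ×` noise, and is the leftmost member of any plateau of equal
maxima (determinism). A plateau only counts when the window also contains a
strictly smaller value; without this strictness rule a constant spectrum
would consist entirely of "peaks".

**Picking threshold on mean spectra.** Averaging N spectra suppresses white
noise by √N, but the per-pixel zero-clipping after baseline subtraction
leaves a small positive bias whose ripple does *not* shrink relative to the
MAD of the mean. On the phantoms this ripple tops out near SNR 17 while
true analyte apices sit above SNR 34, so mean-spectrum picking here uses
`snr_threshold = 25`; single-spectrum picking keeps the conventional
default of 4.

**Binning** pools sorted peaks and starts a new bin whenever the gap to the
previous peak exceeds the tolerance (Da or ppm; greedy single-linkage).
Bin m/z is the intensity-weighted mean of members — more robust to
low-intensity stragglers than the plain mean — and bin intensity the member
maximum. Member sets partition the input by construction.

**Poisson monoisotopic harvesting.** For each unassigned peak (ascending
m/z) and each charge z, a chain of peaks spaced 1.00235/z Da (the average
isotopologue mass difference) within ±0.01 Da is assembled greedily. Chain
intensities are compared to Poisson weights p_k = e^(−λ)λ^k/k! with
λ = 0.000594 · (monoisotopic m/z) — an averagine-style rate — via the
cosine score; the best-scoring charge hypothesis wins (evaluating all
charges per start peak prevents a low-charge "skip chain" through every
second member of a higher-charge envelope from claiming its peaks). Chains
scoring ≥ 0.95 keep the first member as monoisotopic and flag the rest as
isotopologues; everything else passes through as singletons. The rate
constant, spacing tolerance and score threshold are configurable.

**Continuous-centroid export** samples each processed spectrum at a common
peak list (window maximum within ± tolerance, 0 for empty windows), giving
every spectrum the same centroid axis.

## Ion images, feature matrices, PCA / t-SNE

An ion image loads each masked pixel's spectrum lazily, applies the signal
chain, and reduces the intensities inside the closed interval
[centre − tol, centre + tol] with mean, max, sum or median; pixels without
spectra, masked-out pixels and empty windows yield 0. Boundary samples are
included, matching the ± window notation used throughout MSI work.

Feature matrices stack ion images at a peak list over the valid pixels
(max reducer). PCA operates on mean-centred columns via full SVD (no
variance scaling by default — peak intensities share units); score images
scatter the components back onto the raster. t-SNE is delegated to
scikit-learn with PCA initialization (deterministic for a fixed seed;
seeded random initialization when there are fewer features than embedding
dimensions) and perplexity clipped to (n−1)/3 for small inputs; embedding
channels are min–max normalized for display.

## Registration and 3D reconstruction

All registration is delegated to SimpleITK behind the module surface; a
`backend` hook on the deformable step accepts a custom engine (e.g. a
parameter-file driven external toolbox).

* **Rigid**: 2D Euler transform (rotation + translation about the image
  centre), Mattes mutual information with 32 histogram bins, *dense*
  metric sampling — randomness-free, so results are deterministic for fixed
  inputs — under a 3-level Gaussian pyramid (shrink 4, 2, 1; smoothing
  σ 2, 1, 0 px), regular-step gradient descent (250 iterations/level,
  physical-shift scales). Transform units are physical (µm) via the pixel
  size; the transform is the resampling map from the reference frame to the
  moving slice.
* **Deformable**: one B-spline control grid at the final spacing (default
  0.8 mm on the original resolution, i.e. 40 px at 20 µm) optimized with
  LBFGSB under the same pyramid, initialized by the rigid result held as
  the moving-image initial transform. A per-level control-grid refinement
  schedule was deliberately not used: the LBFGSB bound machinery does not
  survive ITK's grid-size adaptors, and a single grid under the image
  pyramid recovers the test warps to interpolation accuracy. Note that
  mutual information's Parzen-window estimate is nearly flat around a
  perfect alignment, so on *identical* images MI lets control points wander
  a fraction of a pixel; mean-squares pins them exactly and is the right
  metric for mono-modal deformable refinement.
* **Stack reconstruction**: the reference slice keeps an identity chain;
  walking outward in both directions, each slice is registered onto the
  aligned rendering of its neighbour, so every chain maps the reference
  frame directly onto its slice and cumulative drift composes implicitly.
  Chains apply to ion images only; spectra are never resampled — resampled
  spectra would invite misinterpretation, whereas transform chains can be
  stored alongside the unmodified data.
* **Landmark error**: moving-slice points are mapped into the reference
  frame (rigid chains invert analytically; chains containing B-spline steps
  are inverted per point by fixed-point iteration on the residual, which
  converges for the small smooth displacements these fields encode);
  reported as mean and population standard deviation of the Euclidean
  distances, in µm.
* Masks are resampled with nearest-neighbour interpolation, preserving
  {0, 1} exactly.

## Synthetic phantoms

`make_phantom` writes a continuous-profile imzML whose pixel spectra are
the sum over containing regions of Gaussian peak shapes (σ 0.25 Da) with
Poisson isotope envelopes (rate 0.000594/Da, spacing 1.00235/z), an
exponentially decaying baseline (amplitude 0.2, 0.008/Da), additive
Gaussian noise (σ 0.02 of unit analyte abundance), all scaled by a per-pixel
factor drawn uniformly from 0.5–2.0 — the multiplicative variation TIC
normalization removes. Defaults: 128×128 px at 20 µm, m/z 600–1000 at depth
2000 (0.2 Da spacing), three elliptical regions × five analytes. The
generator is fully seeded, down to the dataset UUID, so identical seeds
yield byte-identical files.

`make_slice_stack` renders the region geometry as a smooth structure image,
applies a radial morphology drift of ≤ 2% varying smoothly across the stack
(consecutive-section realism that does not defeat rigid recovery), and
resamples each slice through the inverse of its ground-truth rigid
transform; landmark sets are the same physical points expressed in each
slice's frame through the true transform. The default protocol (10 slices ×
7 landmarks) gives 70 reference points per set.

What the phantoms do **not** model: MALDI matrix clusters, detector
saturation, mass-dependent peak width, chemical (structured) noise,
m/z-axis miscalibration between pixels, and tissue tearing or folding.
Passing tests therefore demonstrate algorithmic correctness on idealized
data, not robustness to instrument artefacts.

## Problem sizes used in the checks

Test and acceptance runs scale the phantom's *spatial* grid down (64×64 or
smaller) while keeping the spectral conditions (depth, peak shape, noise,
intensity variation) at their defaults; the lazy-access check instead
inflates a phantom to a ≥ 1 GiB binary container (8192 spectra × depth
32768) to exercise the O(|I|+|S|) contract. Rigid-recovery statistics use
40 seeded trials with |θ| ≤ 15° and |t| ≤ 10 px on a 96×96 structure image;
Poisson-harvesting statistics use 100 seeded noisy envelopes across
z ∈ {1, 2} and m/z 800–2500.

## Known limitations

* Processed-centroid data need a user-supplied common axis (bin edges) for
  overview spectra; no resampling rule is guessed.
* In-file normalization requires the factor to be present in the file;
  there is no silent fallback.
* The Poisson chain model does not deconvolve overlapping envelopes or
  reduce charge states; it only flags chain members.
* Worker parallelism uses threads: I/O and numpy release the GIL, but pure
  Python per-spectrum callables gain little beyond overlapping I/O.
* Registration assumes 2D slices; there is no volumetric (3D×3D)
  registration, and microscopy co-registration (whole-slide formats) is out
  of scope.
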