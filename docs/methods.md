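# Methods

## Scope and data model

The package evaluates serial-section reconstruction pipelines that estimate
one 2D transform per section. Everything operates on three parallel stacks
sharing one geometry: RGB tissue sections, binary tissue masks, and RGB
landmark images carrying one colored disk per fiducial. Landmarks ride
along as images because most third-party reconstruction tools can re-apply
their transforms to a second image stack but cannot export coordinate
mappings; disk color survives interpolation, so the disks can be re-detected
after any warp and their centroids compared. Coordinates are (x = column,
y = row), 0-based, pixel centers at integers, shared by every module.
Physical units enter through two numbers: the in-plane pixel size (µm/px)
and the section spacing (µm, the slice thickness).

Two annotation designs are supported, mirroring the two ways fiducials
occur in practice. *Pairwise* landmarks (e.g. nuclei bisected by the
microtome, visible on exactly two consecutive sections) link one section
pair each; because a section then carries points shared with both
neighbors but the palette has four colors, pairwise annotations are encoded
as two disk stacks — section *i*'s disks for the pair below and for the
pair above — and pair linkage is restored on decoding. *Column* landmarks
(e.g. laser-drilled holes) run through the whole stack and use a single
stack.

## Metric panel

- **Pairwise TRE**: Euclidean distance between corresponding landmark
  centroids on adjacent sections, converted to µm. Reported per
  (pair, point) with mean/max/sample-σ summaries.
- **Cumulative ATRE** (pairwise designs): per pair, the displacement
  vectors of the matched landmarks are averaged; the ATRE at section *k*
  is the norm of the running sum of these mean vectors. Independent errors
  cancel in the sum; consistent drift — the gradual straightening of
  curved anatomy by sequential registration — accumulates linearly.
- **Line-fit ATRE** (column designs): x and y of each column are regressed
  on section index by ordinary least squares, which for equally spaced
  sections is the 3D line minimizing in-plane mean squared error; the ATRE
  is the in-plane distance to the fitted line. Columns observed on fewer
  than 3 sections are excluded.
- **Jaccard** of adjacent masks and **ΔA-%** per section, with areas in
  physical units so the values are resolution-independent. ΔA of an empty
  original mask is reported missing, and a pair with empty mask union
  scores 0 with a warning.
- **Pixel-wise similarity** over the overlap A∩B only (low-overlap pairs
  make these metrics misleading, which is what the Jaccard column guards):
  RMSE, Pearson NCC, and MI/NMI from a 64-bin equal-width joint histogram
  over the shared intensity range; MI in bits, NMI = (H(a)+H(b))/H(a,b) ∈
  [1, 2]. An empty overlap leaves all four NaN.
- **GLCM smoothness**: co-occurrences of 32-level quantized intensities at
  the *same pixel on adjacent sections*, summed into a single matrix for
  the volume (the across-section offset probes stack smoothness; in-plane
  offsets are deliberately not used). Contrast f₂ = Σ(i−j)²p(i,j) and
  correlation f₃ (Haralick) summarize it; quantization is fixed to the
  [0, 255] range so pairs accumulate on one grid.

Grayscale conversion is ITU-R 601 luma throughout. Standard deviations use
the n−1 denominator; a single observation reports σ = 0.

TRE, ATRE, Jaccard and ΔA-% are invariant to image resolution (they are
physical lengths, area ratios, or area changes); RMSE, NCC, MI, NMI, f₂
and f₃ depend on resolution and image content and are only comparable
within one dataset and scale. The resolution-invariance test computes the
panel on one registered reconstruction and on its 2× downsampled copy —
re-registering at each resolution would confound metric invariance with
aligner resolution sensitivity. ΔA-% is itself a percentage and typically
near zero for area-preserving registrations, so its cross-resolution
agreement is judged in percentage points rather than as a ratio.

## Aligners

**LS** fits the transform mapping each section's landmarks onto its
neighbor's: affine by linear least squares (≥ 3 non-collinear points),
rigid by orthogonal Procrustes with the determinant forced to +1 (≥ 2
distinct points). Degenerate configurations raise a named error.

**OPT** minimizes mean squared grayscale error over the overlap of the
fixed image and the warped moving image. The search runs coarse-to-fine
over a power-of-two image pyramid (default 3 levels) with Nelder-Mead and
an explicit initial simplex (3 px translation steps, 2° rotation, 0.05
log-scale/shear) so the first moves escape the flat center of the MSE
basin; pixel-unit parameters are rescaled between levels. Initialization
is the identity and the procedure is fully deterministic. Models:
translation (2 parameters), rigid (3), affine (6, with log-scales so scale
and shear steps are comparable to rotations). Overlap below 5% of the
frame scores a large constant so the search cannot drift apart.

**Feature-based** registration detects SIFT keypoints (scikit-image), maps
descriptors by cross-checked nearest neighbor with a 0.8 ratio test, and
fits an affine model by RANSAC (3 px residual threshold, seeded, minimum 6
inliers). Too few keypoints, matches or inliers raise a match-failure
error; stack registration then falls back to the identity for that pair by
default (policy configurable) so one bad pair does not abort a benchmark.

**Stack propagation**: pairwise transforms are estimated between adjacent
sections moving outward from a chosen reference section, and each
section's global transform is the composition along the chain; the
reference maps by identity. Re-application resamples every stack onto one
shared canvas — the tight bounding box of all transformed section extents —
with zero fill; masks are re-thresholded at 0.5 after linear warping, and
landmark images use linear interpolation (the decoder rejects
border-blurred pixels by color distance). A canvas exceeding five times
the input extent in either dimension (strictly over fivefold) marks the
reconstruction as failed. Transforms serialize to CSV/JSON (section index
plus six row-major affine coefficients), which is also the import path for
scoring external tools.

## Synthetic phantom

The generator produces ground-truthed datasets that exercise every code
path without downloads. The body is an elliptic cylinder whose axis
drifts along a half-sine in x and a cosine ramp in y (amplitude default
8 px — a gentle "banana" whose curvature a sequential registration will
straighten), with semi-axes (default 95 × 75 px on a 256² canvas) varying
a few percent along the stack. Section content is rendered analytically:
every output pixel is mapped through the inverse of that section's
perturbation into the block frame and the phantom evaluated there, so
stored images carry no interpolation artifacts and the recorded transforms
are exact by construction. Content combines band-limited 3D cosine texture
(wavelengths ≳ 30 px, correlated across sections so intensity registration
has signal), darker gland-like tubes, and ~500 nucleus-like Gaussian blobs
(2–4 px radius, ~3 sections deep) that give the SIFT detector keypoints.
Colors approximate an HE section on a white (245) background.

Per-section perturbations are sampled uniformly: translation ±10 px,
rotation ±5°, and for the affine model log-scales ±0.03 and shear ±0.02 —
chosen as plausible slide-placement variability at the default scale; the
source studies report no quantitative deformation magnitudes, so these
defaults are this package's choice. Landmarks are placed inside the
tissue with a separation that keeps encoded disks disjoint. Two observers
are emulated: both annotate with independent Gaussian jitter (σ = 1 px,
truncated at 3σ to protect disk separation), and in the pairwise design
observer 2 additionally picks its own point locations, mimicking observers
free to choose different landmarks. Observer 0 is the exact ground truth.
`emulate_study_design` reproduces the two study geometries at desk scale:
260 sections × 4 pairwise points × 2 observers and 47 sections × 4 columns
× 2 observers, i.e. 2072 + 376 = 2448 annotation records.

What the phantom does *not* model: elastic (locally varying) deformation,
folds and tears, stain variability, and photorealistic tissue appearance.
Passing tests therefore demonstrate correctness of the framework's
geometry, metrics and tuning loop — not that any aligner will reach the
same accuracy on real, locally deformed tissue.

## Tuning

The objective is the benchmark's own accuracy measure: register the tissue
stack with candidate parameters, re-apply the alignment to the landmark
stacks, decode, and return mean pairwise TRE in µm. Failures (fivefold
canvas, aligner exception with no usable result) return a penalty of twice
the unregistered stack's mean TRE, so any non-degenerate solution
dominates a failure; how failed runs should enter the surrogate is not
specified by precedent, and this penalty is a documented choice.
Optimization starts from 2·d Latin-hypercube seed points and continues
with a Gaussian-process surrogate (Matérn 5/2 kernel, per-dimension ARD
length scales, normalized targets) maximizing expected improvement with a
small exploration jitter — an approximation of the escape-prone
"EI-plus" variant, without claiming parity with it — over 512 random
candidates per iteration. A pure random-search backend (bit-deterministic
per seed) exists for testing, and an exhaustive grid sweep covers tools
that must be driven manually. Exactly `budget` objective evaluations
occur; the result is the argmin over all of them. `transfer_params`
moves tuned values between resolutions by scaling pixel-unit parameters
with the resolution ratio.

## Problem sizes and numerical choices

Test and acceptance workloads use reduced sizes chosen as desk-scale
conditions: the null experiment uses 40 sections at 256², parameter
recovery single 192² pairs, resolution invariance a 12-section
feature-registered affine-perturbed phantom (disk radius 8 so centroids
stay accurate after 2× downsampling), the cross-observer experiment 20
landmark-only phantoms of 15 sections, and tuning 6-section 160² phantoms
with budget 15 (4 seed points + 11 surrogate iterations). Color decoding
accepts pixels within 40% of the minimum inter-color distance and requires
5 accepted pixels per landmark; encoded disks of radius ≥ 3 decode to
≤ 0.5 px, and ≈ 0.1–0.2 px in practice. Mask downsampling uses block
area-majority voting, intensity downsampling block averaging. The
tightest known limitation is landmark decoding after aggressive
downsampling: below ~3 px decoded disk radius centroid noise grows
quickly, so landmark disks should be drawn with radius ≥ 2× the largest
intended downsample factor.
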