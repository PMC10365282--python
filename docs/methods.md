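# Methods

This note records the models, conventions and numerical choices behind
`imquant`, in the order a user meets them.

## Image model and conventions

Volumes are regular 3D grids with voxel spacing in mm, an origin at the
centre of voxel (0,0,0), and an orthonormal direction matrix, all in the
DICOM/ITK LPS world frame. Arrays are indexed `[z, y, x]` (slice-major);
metadata components are ordered `(x, y, z)`. Masks are non-negative integer
grids with 0 as background; "the ROI" always means nonzero voxels. Grids
are considered aligned when shape matches and spacing/origin/direction
agree within 1e-4 relative tolerance.

Intensity normalization offers `mean_std` ((x−μ)/σ), `max_min` (affine map
onto [0,1]) and `center_width` (clip to the window [c−w/2, c+w/2], then map
the window onto [0,1]). `center_width` has no default window — a CT window
is acquisition- and organ-specific, so it must be user-supplied. Gray-level
discretization uses a fixed bin number (default 64) with the maximum value
assigned the top bin; a constant ROI collapses to bin 1 rather than raising,
so downstream texture matrices remain defined on degenerate ROIs.

Resampling preserves world extent: output size per axis is
`round(n·s_in/s_out)` (minimum 1) anchored at the input origin. Masks must
use nearest-neighbour interpolation — any other scheme can invent labels.

## Delineation

The interactive tool is region-based. Canny runs inside the user rectangle;
when thresholds are unset they default to the 70th/90th percentile of the
in-rectangle gradient magnitude, which makes the defaults scale-free across
phantoms and HU images. The boundary proposal is the hole-filled edge set;
its centroid becomes the single positive seed, the rectangle vertices the
four negative seeds. The update rule is a marker-controlled watershed on
the Gaussian-smoothed gradient magnitude with positive seeds as foreground
markers and negative seeds plus the rectangle border as background markers.
This realizes both seed polarities as hard constraints (marker pixels keep
their labels) and is deterministic.

Propagation carries a slice annotation to its neighbours: dilate the
previous mask by one voxel, keep pixels whose intensity lies within
μ ± k·σ (default k = 3) of the previous mask's intensities (statistics
refreshed per slice), then filter connected components (`all`, `largest`,
or the component containing the previous centroid, falling back to largest
when the centroid lands outside). Propagation halts on an empty candidate
or after `max_slices` steps. The intensity gate is a deliberate stand-in
for an unspecified appearance model; both k and the component rule are
exposed on `PropagationSpec`.

Morphological dilation/erosion by per-axis millimetre distances is
implemented by thresholding the exact Euclidean distance transform in the
ellipsoid-scaled metric (sampling = spacing/distance per axis). This is the
same operation as dilating with an ellipsoidal structuring element but
without integer rounding of the semi-axes; on a 10 mm sphere dilated by
2 mm at 0.5 mm spacing the volume error is ~3.6%, versus ~6.4% for a
rounded voxel footprint. Digital morphology measures between voxel
centres, so boundaries land within about a quarter voxel of the continuum
result; tests therefore run geometric-accuracy checks at 0.5 mm spacing.

## Radiomics

The registry enumerates (family, source, feature) triples: 104 features on
the original image and 90 (18 first-order + 72 texture) on each of 24
derived images, 2,264 in total. Shape is geometry-only and is not repeated
per derived image. Feature keys are `source_family_feature`.

First-order moments are population moments; `entropy`/`uniformity` use the
fixed-bin histogram with base-2 logs; `total_energy` multiplies energy by
the voxel volume; robust MAD is the MAD of values inside the 10th–90th
percentile window. Skewness and kurtosis of a constant ROI (0/0) return 0.

Shape features mesh the binary mask with marching cubes after smoothing
the occupancy field with a 0.8-voxel Gaussian: meshing raw 0/1 data
produces a staircase surface that overestimates area by up to ~10%, while
the 0.5-level of the smoothed field tracks a curved boundary to sub-voxel
accuracy (digitized 20-voxel sphere: sphericity 0.992). Tiny ROIs whose
smoothed peak falls below the level fall back to the raw mesh. The cost is
rounded corners on blocky ROIs — volume there is better read from
`voxel_volume`, which is exact. Axis lengths use the 4·√λ convention on
the physical-coordinate covariance eigenvalues; maximum 2D/3D diameters
are largest pairwise surface-voxel distances (convex hull first).

Texture families follow the standard IBSI formulations, base-2 logs,
levels = bin indices. GLCM accumulates symmetric co-occurrences at
Chebyshev distance 1 per direction; features are computed per direction
over the 13 unique offsets and averaged, as are GLRLM features. GLSZM uses
26-connected zones (single matrix); NGTDM sums |i − mean valid-neighbour
bin|; GLDM counts same-bin 26-neighbours (α = 0) with dependence j =
count + 1. Degenerate 0/0 forms (correlation, IMC1, busyness, strength…)
return 0; NGTDM coarseness of a flat region returns the conventional 1e6
cap. Each family is equality-tested (rtol 1e-8) against a loop-based
enumeration oracle that shares no code with the implementation.

Filter parameters the inventory does not pin are fixed defaults: 3³
kernels for box/mean filters, 1 binomial repetition, curvature flow 5
iterations at step 0.05, 1 mm Gaussian σ, unit Laplacian sharpening, noise
amplitude 10% of the image SD (seeded; `extract_all` derives per-filter
seeds from its single seed). Wavelet bands come from a single-level
stationary coiflet-1 transform so derived images keep the input grid; axes
are padded to even length symmetrically and cropped back.

`extract_all` preprocesses (optional normalization, optional resampling),
computes shape once on the preprocessed mask, and first-order + texture per
source. Non-finite values (none observed on phantoms) would be replaced by
0 with a logged warning to honour the finite-vector contract.

## Registration

`similarity` computes MSD, Pearson NC, and MI from a 32²-bin joint
histogram in nats. `register_linear` wraps a multi-resolution (default 3
octaves) gradient-descent optimization with moments initialization; MSD
maps to mean-squares, NC to negated correlation, MI to Mattes MI, with
dense sampling so results are deterministic. The recovered transform maps
fixed-image coordinates into the moving image — i.e. the inverse of a warp
that was applied to create the moving image; tests verify recovery by
composing the two and measuring point residuals (<0.15 voxel, <0.2° on
SNR-10 phantoms). The hybrid loss evaluates a supplied dense displacement
field: image dissimilarity of the warped moving image (NC/MI negated so
all terms are dissimilarities), a diffusion regularizer (mean squared
spatial gradient of the displacement, averaged over components), and
1 − Dice of the warped segmentation. Weights have no claimed defaults; all
three are exposed.

## Modeling

Grouping is stratified and seeded; custom grouping echoes a provided
column. Scalers are fitted on training rows only; zero-variance columns
under zscore map to 0 with a warning; boxcox demands positive values.
LASSO selection uses cross-validated penalty choice when no penalty is
given. The 13 classifier names map onto scikit-learn/xgboost estimators;
PLS-DA is a small wrapper that maps the PLS regression score through a
logistic link calibrated at 0.5 on the regression scale. AUC is the
trapezoidal empirical ROC area; its 95% CI uses DeLong's structural
components. Calibration uses 10 equal-count bins. Decision curves
classify positive at score ≥ t; the clinical impact curve reports
high-risk and true-event counts per 1000 subjects. The nomogram anchors
the variable with the largest |β|·range at 100 points and picks per-
variable references so points are non-negative over the observed range;
the predicted probability is read from the logistic model itself, so the
point and probability maps cannot disagree.

The end-to-end recovery study (planted dataset: n = 300, p = 100, 3
informative features at 1.5 SD) runs the zscore → LASSO → logistic
pipeline under 5-fold cross-validation grouping and pools out-of-fold
scores for the held-out AUC. Pooling uses all 300 subjects in the
estimate; a single 70/30 split would score the same pipeline on 90
subjects, where AUC sampling noise (SE ≈ 0.025) dominates the comparison
against a fixed bar. Across 50 seeds the pooled AUC exceeds 0.90 in ≈98%
of seeds and the three informative features are selected in every fold of
every seed.

## Organ quantification

Brain: volumes are voxel counts × voxel volume; ratios divide by the
intracranial volume (all labels including CSF). The asymmetry index is
2(L−R)/(L+R) ∈ [−2, 2]. Normative flags compare a measurement to the
matched sex/age band: below p5 → atrophic, above p95 → enlarged.

Lung: the 96-feature block is fixed as 26 volumetric (infection volume and
percentage for whole/left/right lung and 5 lobes; region volumes for the
same 8 regions; total and mean lesion volume), 31 numeric (binary infected
flags for 5 lobes and 18 segments; infected-lobe/segment counts and
fractions; lesion component counts total/left/right; largest-lesion voxel
count), 32 histogram (normalized lesion-HU histogram over [−1024, 1024]),
and 7 surface features (lesion and lung mesh areas, lesion–pleura face
contact area and fraction, per-side lesion areas, surface-to-volume). A
region counts as infected above 0.1% lesion occupancy, which suppresses
single-voxel false positives. The schema carries a version string;
longitudinal change is the elementwise t1 − t0 difference of two reports
with equal versions.

Knee: mJSW is the minimum Euclidean distance between femoral and tibial
surface-voxel centres per compartment (sagittal split through the tibial
centroid; for a right knee the medial compartment lies at larger x in
LPS). Centre-to-centre distance across a gap equals the surface gap plus
one voxel spacing — 4.5 mm for a 4.0 mm gap at 0.5 mm — which sits inside
the half-voxel-diagonal tolerance used in tests. Cartilage thickness is
the mean doubled distance transform sampled on the 3D skeleton (inscribed-
sphere approximation; deterministic and mesh-free). Meniscus coverage
compares axial-projection footprints.

## Phantoms

Generators rasterize analytic shapes at voxel centres and return ground-
truth records sufficient to verify every downstream check: spheres/slabs/
plates with known volume, surface, gap; a two-lung phantom partitioned
into 5 lobes and 18 nested segments with spherical lesions (HU
−100 ± 50 on −800 parenchyma, soft tissue 40, bone 700 — plausible
anchors, not measurements); a knee plate assembly with exact gap,
thickness and coverage; a 109-region brain-like lattice (54 mirrored box
pairs + 1 midline region) with log-normal per-region volumes (CV 10%) and
a normative table computed from 1,000 simulated normals of the same
generative law; and a tabular cohort with planted informative features.
The normative table is built from the continuous generative volumes, not
from rasterized voxel counts: rounding box edges to integers makes small-
region volume distributions discrete and destroys percentile calibration.

What the phantoms do not emulate: anatomy (lobes are z-slabs, not
fissures), partial-volume and scanner point-spread effects, intensity
inhomogeneity, or inter-feature correlation structure in the tabular
cohort. Passing tests therefore demonstrate the correctness of the
computations and their calibration under the stated generative models —
not clinical performance on real images.

## Problem sizes and determinism

Test and acceptance runs use deliberately small grids: texture oracles on
≤6³ volumes (20 seeds), radiomics extraction on a ~280-voxel sphere ROI,
registration on 48³ phantoms (10 transforms), the recovery study at
n = 300 × 50 seeds. Every stochastic step takes an explicit seed;
`extract_all` and the pipeline derive sub-seeds deterministically from a
single seed, and identical configuration + seed reproduces outputs
byte-for-byte.

## Known limitations

DICOM is read-only; 4D series are out of scope. The interactive tool is
region-based (no editable contours). The propagation intensity gate is a
heuristic. Mesh-based surface measures trade blocky-ROI fidelity for
curved-boundary accuracy (see above). The hybrid loss evaluates but does
not optimize deformations. PLS-DA probabilities are a calibrated link, not
posterior probabilities. The pneumonia 26/31/7 block compositions are a
documented schema choice constrained only by the block totals.
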