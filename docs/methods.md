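# Methods

## Containers and conventions

All image computation runs on `CTVolume` (3-D float HU grid) and
`BinaryMask`, with the fixed axis convention (axial, row, column) and
spacing `(dz, dy, dx)` in mm. NIfTI-1 is the on-disk format (masks as
uint8); MetaImage is accepted on read. "Axial diameter" always means the
in-plane (row, column) Feret diameter of one axial slice, measured between
voxel centers, so a single voxel has diameter 0 and the convention differs
from caliper measurements by at most one voxel. All measurements assume the
portal-venous phase; the package does not attempt phase detection.

The cohort table is a CSV keyed by case with the four percent-change
statistics, the RECIST category and PFS in months. Missing PFS is kept as
missing and excluded from any statistic that needs it — never imputed. The
packaged 25-patient GEP-NET table has 21 complete cases; the additivity
invariant |Δ(V+D) − (ΔV + ΔD)| ≤ 0.01 holds on every row and is checked on
load.

## Liver segmentation

The intensity distribution of an abdominal CT slice is modeled as a
two-component 1-D Gaussian mixture (liver parenchyma vs everything else)
fitted by EM on **all** voxels of a manually chosen mid-liver slice — a
two-component model must see both classes, so the fit is deliberately not
restricted to the manual mask; the mask's mean HU is used only to identify
which component is liver (nearest mean; ties resolve to component 0 with a
warning). EM is initialized deterministically by splitting the samples at
their median and taking each half's moments, with `tol = 1e-6` relative
log-likelihood, `max_iter = 500` and a variance floor of 1e-3 HU² against
component collapse. The log-likelihood trace is recorded and is
non-decreasing.

The liver interval is `mu_L ± k*sigma_L` with `k = 2.5` by default
(≈ 98.8 % coverage of a Gaussian parenchyma class). The whole volume is
thresholded to that interval, the largest 26-connected component kept,
holes closed with a ball of radius 2 voxels, and — beyond the plain closing
— fully enclosed interior cavities are filled (`fill_holes=True`):
hypodense lesions fall outside the parenchyma interval by construction, and
the liver region must contain them to serve as the tumor-classification
ROI. Closings are computed on a padded grid so they are extensive even at
the array border.

## Texture features

Each ROI voxel is described by 10 features of its 11×11×11 neighborhood
(clipped, not padded, at the volume border):

- statistical, on raw HU: mean, population std, skewness (m₃/m₂^1.5),
  excess kurtosis (m₄/m₂² − 3; both 0 for a constant patch), median;
- GLCM, on HU quantized to 32 uniform levels over the window
  (−100, 300) HU: contrast Σp(i−j)², correlation (0 when a marginal
  variance vanishes), entropy in bits (0·log0 = 0), energy Σp², and
  homogeneity Σp/(1+|i−j|).

The co-occurrence matrix pools the 13 unique unit-displacement directions
of the 3-D lattice and is symmetrized, making the features insensitive to
direction reversal and offset order. The HU window covers the liver/tumor
parenchyma range with tractable 32×32 matrices. Two implementations exist
on purpose: a plain-numpy per-patch path (`feature_vector`, composed of
`glcm_3d` + `haralick_features`) and a numba kernel (`feature_map`) for
whole-liver extraction; the test suite holds them to agreement at 1e-9 and
checks the numpy path against brute-force pair enumeration at 1e-12.

## Tumor classification

A four-layer fully connected network (10 inputs, hidden layers 16 and 8,
one output; logistic activations throughout) is trained full-batch on
cross-entropy with classical momentum (learning rate 0.5, momentum 0.9,
500 epochs, Xavier-style init from a fixed seed). Plain momentum-free
descent at small learning rates stalls in the saturating logistic layers
long before the decision boundary forms, so momentum is the default; the
trainer remains deterministic for a fixed seed. Features are standardized
with training-set statistics stored in the model, and the JSON
serialization round-trips bit-identically.

A voxel is tumor iff its forward probability ≥ 0.5. Morphological closing
then opening (radius 1 each) removes pinholes and isolated noise; radius-1
structuring elements are the 3³ box (the Chebyshev unit ball — the
7-voxel Euclidean cross would shave the corners of rectangular regions on
opening), larger radii are Euclidean balls. A batch edit list
(`z,y,x,action` CSV) stands in for interactive radiologist refinement; it
validates indices, rejects conflicting add/remove pairs and is idempotent.

At desk scale the training labels come from phantom ground truth. Training
samples are drawn from **both** time points of a training phantom disjoint
from the pair under analysis: the post-treatment scan has rescaled, fainter
or darker lesions, and a classifier shown only baseline appearance
systematically over-segments the follow-up, which directly biases ΔV. The
training API itself is data-agnostic: any feature table with binary labels
works.

## Response metrics

Lesions are the connected components of the tumor mask (26-connectivity by
default). V is voxel count × voxel volume summed over lesions; D is the
mean HU over the union of tumor voxels (voxel-weighted — *not* the mean of
per-lesion means), undefined (absent) for an empty mask. RECIST targets are
the up-to-two largest-diameter lesions measuring ≥ 10 mm at baseline;
follow-up re-measures the same identities via nearest-centroid matching.
The volumetric metrics deliberately include every lesion, including those
under 1 cm that RECIST ignores — the two families are meant to disagree
when sub-centimeter disease dominates. Percent changes are
baseline-referenced, 100·(post − pre)/pre with pre > 0 required, and
Δ(V+D) is their signed sum. Δ metrics require tumor at both time points.

## Cohort statistics

Pearson product-moment correlation with the exact two-sided t-transform
p-value (n−2 df), complete-case over rows with recorded PFS, no
multiple-testing correction, significance at P < 0.05. Reported r values
are rounded to 3 decimals; internal precision is full. Group summaries are
arithmetic means of ΔV, ΔD, ΔS within the PD group and the PR∪SD group.
No censoring-aware survival model is fitted — the analysis is a plain
correlation by design.

## Phantom generator

A phantom pair is an ellipsoidal liver (default semi-axes 55/70/80 mm,
100 ± 12 HU) on a −70 ± 15 HU background, containing non-overlapping
spheres placed by rejection sampling (sequential, with up to 25 full
restarts so one unlucky large sphere cannot wedge the configuration).
Per-tumor mean HU is drawn around `tumor_hu_mean` (spread
`tumor_hu_sigma`); the post-treatment twin re-renders each tumor with
radius scaled by (volume scale)^(1/3) and shifted HU, and optional
Gaussian acquisition noise is added to both scans independently. Spheres
keep the analytic truth exact: V, D, ΔV, ΔD are known in closed form
before discretization. The generator emulates the burden regime of a
diffuse GEP-NET liver-metastasis cohort — lesion counts up to the
hundreds, per-lesion densities spanning roughly 50–145 HU, burdens from
under 1 cm³ to liters — at a desk-scale default grid of 96×128×128 voxels
at 1.5 mm isotropic.

What it does **not** emulate: lobulated lesion shapes, partial-volume
blur beyond lattice discretization, beam hardening, respiratory motion,
heterogeneous (rim-enhancing, necrotic) lesions, or inter-reader seed
variability. Passing phantom validation therefore demonstrates the
correctness of the numerical chain under the stated model, not clinical
segmentation accuracy.

## Validation problem sizes

Pipeline-level checks run on a 48×64×64 grid at 1.5 mm with four lesions
of radius 8–12 mm and 60 vs 100 HU contrast (noise σ = 8). The lesion
radii are chosen to exceed the 11-voxel window half-width: on clinical
~1 mm grids a measurable lesion spans many window widths, and this is the
equivalent desk-scale regime — with lesions smaller than the window no
voxel ever sees a pure-tumor neighborhood and per-voxel classification is
ill-posed. Under these conditions (10 seeds, medians): EM recovers the
generative mixture means within 2 HU, liver Dice ≥ 0.95, measuring from
ground-truth masks recovers the configured ΔV within 2 % absolute
(discretization only), and the full pipeline recovers it within 15 %
absolute with per-voxel F1 ≈ 0.9 before morphology.

## Numerical conventions and edge cases

- GLCM of a constant patch is a single diagonal point mass; entropy 0,
  energy 1, correlation 0 by convention.
- Quantization clips to the HU window; HU = lo maps to level 0, HU ≥ hi to
  the top level; the mapping is monotone.
- `percent_change` is baseline-referenced and deliberately not
  antisymmetric under exchanging the time points.
- An empty tumor mask yields V = 0 and an absent D; empty-group summaries
  are absent with a warning, never zero-filled.
- EM on fewer than two distinct values, Pearson on zero-variance input and
  thresholds selecting no voxels raise typed errors rather than returning
  degenerate numbers.
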