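# Methods

This note documents the models and procedures implemented in `quanthisto`,
the parameter choices that matter, what the synthetic benchmark does and
does not establish, and the numerical conventions a user reproducing our
outputs needs to know.

## Segmentation

Bright-field sections stained with toluidine blue show dark cell walls on
bright lumina, so binarization targets the wall network: a pixel is wall
iff its intensity falls below the Gaussian-weighted local mean minus an
offset (`window_px` = 51 px, `offset` = 10 intensity units by default; the
window must comfortably exceed the largest lumen diameter fraction that
would otherwise pull the local mean down). Preprocessing applies gamma,
then contrast, then brightness on intensities normalized by the dtype
maximum. Binary cleanup runs two erosions followed by one dilation with a
radius-1 disc — the literal order reproduces standard practice for
discarding noise pixels while regularizing boundaries; it thins walls by
about one pixel per side, so walls thinner than ~5 px risk breaking.

The watershed is automatically seeded: markers are *extended maxima* of
the Euclidean distance transform of the non-wall region — regional maxima
of the h-reconstruction, with the depth h chosen per connected lumen
component as `max(h_min, h_rel · max distance)` (`h_rel` = 0.6,
`h_min` = 1 px). Two details matter here. First, raw h-maxima (the
residue ≥ h rule) marks tied discrete EDT maxima of a single cell as
separate seeds and over-segments elongated cells badly; extended maxima
merge equal-height peaks separated by shallow dips into one plateau
marker. Second, the relative depth makes the rule scale-free across the
10× cell-size range between cambium and phloem: a secondary basin
survives only if it rises more than h above its saddle, which is exactly
the signature of two lumina merged across a locally broken wall. Basins
below 20 px² are discarded as slivers.

A ground-truth cell counts as mis-segmented when no predicted label
overlaps it with IoU strictly above 0.5 — a criterion that automatically
covers merges (IoU of an equal-size merge is exactly 0.5, counted as
mis-segmented), splits and misses, replacing visual inspection.

## Descriptors

Ellipses come from the eigendecomposition of the 2×2 covariance matrix of
pixel coordinates (central second moments); full axis lengths are
4·√eigenvalue and the orientation is the leading eigenvector's angle in
(x, y) image coordinates (y down), wrapped to [−π/2, π/2). Perimeter uses
the standard chain-code approximation (`skimage.measure.perimeter`);
boundary radii are centroid-to-boundary-pixel distances with a 4-neighbor
boundary definition. Positional features use a manually defined (or, for
synthetic sections, constructed) center; the normalized polar radius
divides by the mean centroid distance of the outermost 5% of cells, so
0.0 is the center and 1.0 the average outer rim, with values up to ~1.2
possible for individual protruding cells. Single-pixel cells are flagged
degenerate (minor axis 0, eccentricity 1) and carry no incline.

The exact identity of the 16 descriptors is fixed in
`descriptors.FEATURE_NAMES`; the set mirrors the moment- and
shape-feature families standard in cell morphometry and contains every
quantity the downstream analyses consume. It is an explicit convention of
this package, not a claim of byte-level equivalence with any particular
historical feature list.

## Classification

One classifier per genotype × timepoint: an RBF-SVM (C-classification)
inside a pipeline whose standardization is fitted on each training
portion only, so no information leaks across folds. Model selection uses
stratified 5-fold cross-validation with seeded shuffles. Greedy forward
selection over the 16 descriptors adds, at each step, the feature that
maximizes CV mean accuracy (ties broken by the fixed feature order); the
recommended subset is the smallest one within τ = 0.005 of the best mean
accuracy, with the fold-to-fold standard deviation as the final
tie-break. Hyperparameters come from a small log-grid
(C ∈ {1, 10, 100}, γ ∈ scale·{0.1, 1, 10}). Classifiers persist as a
directory of params JSON plus a joblib model blob and round-trip exactly.

## Quality control

Membership is tested on the cell centroid (rounded to the nearest pixel)
for speed; with ~10³–10⁴ cells per section and masks that are smooth
discs, centroid-in-mask and pixel-majority agree except for cells
straddling the mask boundary. The xylem correction is bidirectional by
default — xylem classes outside the xylem mask become phloem parenchyma
(the class they are typically confused with), phloem parenchyma inside it
becomes xylem vessel/parenchyma — and can be restricted to the first rule
(`bidirectional=False`). The operation is idempotent and conserves rows.

## Phenoprints and PCA

The 8 phenoprint variables are: total cell count, total transverse area
(µm²), the five class proportions, and the median incline — medians
across a condition's sections, with the proportion block renormalized to
sum to 1. Scaling divides each variable by its maximum over samples
(unit range), then PCA eigendecomposes the correlation matrix.
Conventions asserted in tests: eigenvalues sum to the number of
variables; scores are the standardized data (sd with n−1) projected on
the eigenvectors, so score variance along component k equals eigenvalue
k; each loading vector is flipped so its largest-magnitude entry is
positive, making biplots reproducible.

## Dip test

Hartigans' dip — the sup-norm distance from the empirical CDF to the
closest unimodal CDF — is implemented with the classic iterative
algorithm over the greatest convex minorant and least concave majorant of
the ECDF on a shrinking modal interval (count-unit arithmetic, final
division by 2n; minimum dip 1/(2n) for distinct values, 0 for constant
samples). The kernel is JIT-compiled with numba when available and
validated in the test suite against an independent oracle that minimizes
the sup-norm over piecewise-linear unimodal CDFs by linear programming,
one LP per candidate modal knot. P-values are bootstrap quantiles under
the uniform null (the least favourable unimodal case; the dip is
invariant to monotone rescaling), default 2000 replicates, seeded, with
the add-one estimator. The pooled per-timepoint sample is the default
unit of testing; per-section testing is a matter of slicing the input
table.

## Incline analyses

Lowess uses locally weighted linear regression with 3 robustifying
iterations, default `frac` = 0.3 (recorded in outputs), evaluated on a
200-point grid over the normalized radius [0, 1]. Quartiles follow the
linear (type-7) interpolation rule; outliers use the 1.5·IQR whisker
convention. Violin densities are Gaussian KDEs with boundary reflection
at 0 and π/2, normalized to integrate to 1 on the support.

## Phloem-pole periodicity

The ring profile samples a Gaussian-blurred image at ⌈2πr⌉ arc positions,
averaging across the ring width, and is inverted so dark staining foci
appear as maxima. Two complementary estimates follow:

- **Arc period** (`bayesian_period`): single-sinusoid Bayesian spectral
  estimation — for each candidate period the amplitude, phase and offset
  are marginalized analytically under flat priors and a Jeffreys noise
  scale, giving a Student-t marginal likelihood
  ∝ (residual SS)^−(N−3)/2 / √det(GᵀG); a flat prior over the period grid
  yields the posterior, MAP and central 95% interval. This recovers the
  generating period to within 5% across 40–200 px spacings at SNR ≥ 3
  and resolution-limited accuracy on noiseless sinusoids. Near-flat
  posteriors (constant signal) are flagged.
- **Spacing constancy** (`spacing_pdf`): the PDF *of the inter-spike
  distance itself*. Spikes are detected with a prominence filter
  (≥ 3·MAD); circular gaps between consecutive spikes are modeled as
  Normal(µ, σ²) with the Jeffreys prior, making the posterior predictive
  of a new gap a Student-t centred on the mean gap. A sharp dominant peak
  (≥ 0.8 of the mass within ±10% of the mode) indicates patterned,
  constant spacing; 30% gap jitter spreads the PDF below 0.5. The
  spectral posterior cannot play this role: its likelihood exponent grows
  with the profile length, so it concentrates sharply even under strong
  spacing jitter — the two-estimator split is deliberate.

## Synthetic sections

The generator emulates the radial anatomy the pipeline targets: a xylem
disc (inner 62% vessels/parenchyma, outer annulus fibers, both radially
oriented and elongated), a thin cambial ring of small orthoradial cells,
orthoradial phloem parenchyma, and compact bundle clusters placed on a
ring just outside the cambium at a constant 140 µm arc interval (the
spacing scale of real phloem poles; ~11 poles at the default radii).
Cells are anisotropically weighted Voronoi regions of jittered polar
lattices — the metric of each seed is scaled by its zone's target cell
size and aspect, which guarantees wall-separated, watershed-recoverable
cells with the intended size contrast between zones. Default geometry:
zone radii 220/245/490 µm, 0.35 µm/px (image ~2900–3072 px across,
~1080 cells), 5 px walls drawn by thresholding the Euclidean distance to
the label interface (isotropic thickness, so diagonal walls survive
binary morphology like axis-aligned ones), lumen/wall/background
intensities 200/60/225 with Gaussian noise sd 6 clipped to 8 bits.
Reduced-scale sections (radii 60/75/140 µm at 0.7 µm/px, ~250 cells) are
used throughout the test suite and for classifier training in the
acceptance script; the full-scale default is used for the segmentation
benchmark.

What the synthetic benchmark shows — and what it does not: it
demonstrates that the implementation is correct and self-consistent
(walls recovered, cells split and counted, classes separable from the
descriptors, periods recovered), under an intensity model with clean
walls, convex cells and stationary noise. Real sections add wall-staining
gradients, torn or collapsed cells, dirt, uneven illumination and
out-of-plane tissue; the published ~99% segmentation and 88% / 95%
classification accuracies on real material are therefore *analogues* of,
not guarantees from, the synthetic numbers reported here. The synthetic
class geometry also makes position (polar radius) a strong feature, which
matches the biology (cell types live in concentric zones) but means
classifier accuracy on synthetic data should be read as an upper bound.

## Problem sizes and determinism

The test suite and acceptance script run on one CPU: the acceptance
script uses one full-scale section (~1080 cells, 3072² px) for
segmentation, three reduced sections for classifier training/evaluation,
1000-replicate dip bootstraps, and 20 synthetic rings for period
recovery. Every stochastic step takes an explicit seed; rerunning any
generator or the pipeline with the same configuration and seed reproduces
images and feature tables bit-identically.
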