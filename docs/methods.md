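# Methods

This note documents the models, conventions and numerical choices behind
`habrad`, and what the synthetic phantoms do and do not establish.

## Phantom generator

Each phantom subject is a pair of co-registered 3-D volumes (T1W-like and
T2W-like contrast) on a 48 × 48 × 24 grid at 1 mm isotropic spacing, with
four ellipsoidal VOI blobs: a smaller, medial bilateral pair (caudate-like,
mask label 1) and a larger, lateral pair (putamen-like, label 2), together
about 3,800 voxels. The geometry is a deliberately simplified stand-in for
deep-gray anatomy — no cortex, no partial-volume mixtures with white
matter, no inter-subject anatomical variability (all subjects share the
mask; only textures and habitat geometry vary).

**Habitats.** Each connected blob is partitioned into `k_true` habitats as
the Voronoi cells of `k_true` uniformly drawn seed voxels (distances in
mm), so habitats are contiguous and each habitat label is present in every
structure. Habitat `h` is filled, per contrast, with a Gaussian random
field of mean `m_h`, standard deviation `s_h` and correlation length
`c_h` mm (white noise smoothed with a Gaussian of width `c_h`, renormalised
to unit variance). Defaults place the habitats on a mean ladder of 8
intensity units (ascending in T1W, descending in T2W — the direction
iron-rich versus iron-poor tissue would take), equal std 3, and a geometric
correlation-length ladder from 0.5 to 2.5 mm, so habitats differ jointly in
level and in granularity and both intensity-driven and structure-driven
voxel features carry habitat identity.

**Class effect.** Disease-class subjects receive, per habitat, an additive
mean shift, a multiplicative fluctuation scaling (raising intensity range
and RMS), and a sparse exponential "speckle" tail (5% of voxels) that
raises kurtosis and skewness — the direction of group differences expected
from neurodegeneration with focal iron deposition. Default effect strength
grows linearly across habitat index so that later habitats are the most
disease-affected.

**Noise and bias.** Magnitude-MRI noise is Rician
(`sqrt((v+n1)^2 + n2^2)`, `n ~ N(0, sigma)`, default sigma 1.0 against
tissue intensities near 100, i.e. SNR ≈ 100). The bias field is a random
quadratic with prescribed peak-to-trough amplitude (default 0.15) and unit
mean, applied multiplicatively before the noise. Everything derives from
`PhantomSpec.seed` via `numpy` seed sequences; cohorts are bit-reproducible.

## Voxel feature maps

Per contrast, 19 features per VOI voxel, computed on the cubic
neighbourhood of radius 2 (5×5×5) clipped at the VOI boundary —
neighbourhoods never sample non-VOI tissue, at the cost of smaller supports
near the surface. Matrix features discretize each neighbourhood onto 16
equal-width bins over its own min–max (constant neighbourhood ⇒ level 1).
Radius and bin count are configuration; the literature rarely states them,
and both defaults are conventional.

Conventions (shared with the catalog level): symmetric GLCM accumulated
over the 13 unique distance-1 directions and normalised once (features on
the direction-pooled matrix); run and zone matrices pooled the same way;
entropies in bits; NGTDM restricted to voxels with at least one in-region
26-neighbour. Degenerate single-cell co-occurrence matrices take the
constant-image limits: JointEnergy 1, all other GLCM features 0 (Imc1/Imc2
defined 0, InverseVariance excludes the diagonal). The kernels are
numba-compiled; the test suite checks every map against nested-loop Python
references on random fixtures at 1e-10.

## Habitat model

K-means (k-means++, `n_init=10`, fixed seed) on voxel vectors pooled across
the training cohort, after z-scoring with pooled training statistics
(zero-variance columns dropped). One pooled model, rather than per-subject
clustering with post-hoc matching, is the central interpretive choice: it
forces habitat labels to denote the same tissue signature in every subject,
which the per-habitat feature table requires. Cluster indices are relabelled
by ascending centroid value in the standardized T2W-median column, making
H1..Hk reproducible across runs. Validation subjects never contribute to
standardization or centroids. Silhouette scores use a seeded subsample of
at most 10,000 voxels.

### What phantom clustering can and cannot recover

Voxel features are neighbourhood statistics, so voxels within the
neighbourhood radius of a planted habitat interface have mixed
neighbourhoods whose feature vectors interpolate between the habitat
signatures. Two consequences, measured systematically on phantoms:

* **Recovery is high but not voxel-perfect.** At `k_true = 2`, low noise
  and the default texture design, adjusted Rand index against the planted
  labels is ≈ 0.82–0.88; the residual errors are interface voxels. Pushing
  the mean separation far above the texture std makes things *worse*, not
  better: mixed neighbourhoods then become strongly bimodal, their local
  histograms collapse, and the entropy-family features turn the interface
  voxels into a cluster of their own that k-means prefers to the planted
  partition.
* **The silhouette-optimal k can exceed the planted k.** The interface
  population, and internal macro-patches of coarse-grained (long
  correlation length) habitats, are genuine feature-space clusters;
  silhouette profiles therefore often peak at k one or two above
  `k_true`. Designs that suppress these extra clusters (equal correlation
  lengths, spread-only contrast) restore the silhouette argmax to `k_true`
  but weaken voxelwise recovery. The tests exercise both regimes
  explicitly.

Passing phantom tests therefore demonstrate that the pipeline recovers
strong planted structure and ranks clusterings sensibly — not that the
method resolves arbitrarily fine subregion structure, on phantoms or on
real MRI.

## Radiomic catalog

1,197 features per category: 13 filters (original; Laplacian-of-Gaussian at
σ = 2, 3, 4, 5 mm, σ in millimetres converted through the voxel spacing;
8 undecimated single-level coif1 wavelet subbands LLL..HHH) × 91
first-order/texture features (18 + 22 + 16 + 16 + 14 + 5), plus 14 shape
descriptors from the original-image region. Shape is computed for every
category including habitats; that per-category total of 1,197 is the only
decomposition consistent with the printed class counts
(234/286/182/208/208/65/14). With k habitats the table has 2k + 2
categories (T1W, T2W, T1_H1..Hk, T2_H1..Hk) and 1,197 × (2k + 2) columns.

Catalog discretization uses a fixed **bin count** (32 equal-width bins over
the region min–max) rather than a fixed bin width: the 13 filter responses
differ in scale by orders of magnitude (raw intensities ~100, LoG and
wavelet-detail responses ~0.1–10), so no single width keeps the effective
bin count in a sensible 16–64 band across filters, while a fixed count
guarantees it. Other conventions: Fisher (excess) kurtosis with
constant-region value 0; GLDM dependence size j = 1 + number of
26-neighbours within α = 0 of the centre level; LoG kernels truncated at
8σ so flat regions map to zero response; marching-cubes mesh for surface
area and volume; principal-axis lengths as 4·sqrt(eigenvalue) of the
physical-coordinate covariance. Regions below 10 voxels get shape features
only, the texture entries flagged missing (never silently zeroed); missing
values are imputed with training-cohort medians just before selection and
modelling.

## Selection cascade

1. **Pearson filter** — feature pairs with |r| > 0.9 are visited in column
   order; the member with the lower |point-biserial correlation to the
   label| is dropped (tie: the later column). Deterministic and documented,
   since "remove one of each pair" underdetermines the survivor.
2. **mRMR** — greedy forward selection (default 100 features kept)
   maximizing MI(feature; label) − mean MI(feature; selected); MI estimated
   on 8 equal-frequency bins. The difference variant is the default; the
   quotient variant is available.
3. **LASSO-logistic** — features z-scored, L1-penalized logistic regression
   with the penalty chosen by stratified 5-fold CV over a log-spaced grid;
   retained features need standardized |coefficient| strictly greater than
   0.0004. The threshold applies to standardized coefficients — the
   natural scale once features are z-scored.

Survivor sets are nested by construction and the cascade is deterministic
given seed and column order. On tables with 5 informative + 500 noise
features (n = 200), the cascade recovers ≥ 4 of the 5 planted features in
well over 80% of seeded replicates (19–20 of 20 across the seeds run).

## Classifier and evaluation

The SVM grid is 4 linear + 16 RBF configurations scored by mean AUC over
seeded stratified 10-fold CV; ties break toward linear, then smaller C,
then smaller γ (preferring the simpler model). The winner is refit on all
training data; probabilities come from a Platt sigmoid fit on out-of-fold
decision values (fitting on in-sample decisions would bias the
calibration). Headline feature selection runs once on the full training
cohort before CV; for stability reporting, `fold_selection_frequency`
re-runs the entire cascade inside each fold and counts survivals — both
views are exposed because they answer different questions (model building
vs. selection stability).

AUC is the Mann–Whitney concordance with ties at 1/2; its variance and the
paired test use DeLong structural components, two-sided normal p-values;
the CI is AUC ± 1.96·SE clipped to [0, 1] (a logit-scale CI is available by
flag). Under a simulated null the paired test's type-I error at α = 0.05
stays within the 0.03–0.07 calibration band over 2,000 replicates. Decision curves use the standard net
benefit TP/n − (FP/n)·pt/(1−pt) on a 0.01..0.99 grid; the treat-all and
treat-none references are included. ICC is the two-way random-effects,
absolute-agreement, single-measure form ICC(2,1). The chi-square helper
applies the Yates continuity correction by default (|O−E| reduced by 0.5,
floored at 0).

## Shapley attributions

Monte-Carlo permutation sampling: per explained subject, features switch
from a background row to the subject's values in random order, each
feature credited with the output change it causes, averaged over
permutations. The background (default: 100-row seeded subsample of the
training table) is cycled deterministically, which removes the
background-sampling term from the estimator variance; the local-accuracy
residual is spread proportionally to |φ|, leaving genuinely inert features
at exactly zero. Against exact coalition enumeration on small models the
estimator is within 2% at 2,500 permutations.

## Problem sizes

Defaults were chosen so a full run is interactive on one CPU: phantom
grids 48 × 48 × 24 (≈ 3,800 VOI voxels), cohorts of tens of subjects per
class, silhouette subsampling at 10,000 voxels, and an end-to-end
benchmark of 120 training + 40 validation subjects. All sizes scale up
through `PhantomSpec` and the stage configurations.

## Known limitations

* Phantom anatomy and acquisition are idealized (shared mask, isotropic
  voxels, stationary Gaussian textures); results on phantoms bound what the
  code computes, not clinical performance.
* The default polynomial bias-field correction handles smooth, low-order
  fields; pathological high-frequency inhomogeneity requires the N4
  backend (`method="n4"`).
* Headline model training applies selection before cross-validation (the
  common practice this pipeline mirrors); the fold-wise cascade is provided
  for stability analysis, not as a nested-CV unbiased performance estimate.
* Habitat counts beyond the texture contrast the data supports are not
  identifiable from voxel features (see the clustering section); silhouette
  and validation AUC are reported side by side rather than combined into a
  single k choice.
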