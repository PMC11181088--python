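# Methods

## Pose parameterization and model RDMs

A pose is a list of K = 19 labeled joints (ankles, knees, hips, wrists,
elbows, shoulders on both sides, plus neck, head, nose, eyes and ears; no
fingers, toes or jaw) given as 3D coordinates in a shared body-mesh
reference frame, together with a global body rotation R (a proper 3×3
rotation) and optionally a unit quaternion per joint.  No centering or
scale normalization is applied to the joint coordinates: the coordinates
are assumed to arrive in one common frame, and the only alignment operation
offered is undoing the global rotation, `J_vi = R⁻¹J`.  The 2D projection
is orthographic coordinate-dropping; no camera intrinsics are modeled.

Pose dissimilarity is the mean per-joint position error (MPJPE), the mean
over joints of Euclidean distances.  Because it is a mean of Euclidean
metrics it is itself a metric (nonnegative, symmetric, triangle
inequality), which the tests verify on random triples.

Rotation dissimilarity uses the quaternion geodesic `arccos(q_i · q_j)`.
Because q and −q encode the same rotation (double cover), the raw dot
product is sign-ambiguous; we take `arccos(|q_i · q_j|)` clamped to
[−1, 1], making the metric well defined, sign-flip invariant and bounded
by π/2.  Quaternions are stored (w, x, y, z) and canonicalized to w ≥ 0
(first nonzero component positive at w = 0) so serialization is
deterministic.  Matrix→quaternion conversion uses Shepperd's
largest-component branch selection for numerical stability, validated by
round-trip tests to 1e-8.

Model RDMs are min–max normalized to [0, 1] over the off-diagonal only
(the structural zero diagonal is not informative about the dissimilarity
range).  A constant off-diagonal makes the mapping undefined and raises an
error rather than returning NaN, because silent NaNs would poison every
downstream correlation.

## Stimulus filter and control models

The stimulus filter keeps images with exactly one annotated person whose
12 limb keypoints all carry a nonzero visibility flag; occluded-but-
annotated keypoints count as present (flag 0 means "not annotated" in the
COCO convention, which is the condition that signals truncation).  Face
keypoints are ignored as unreliable for small figures.

Body-position controls place the person bounding-box center in polar
coordinates about the image center.  Polar-angle dissimilarity wraps
circularly to [0, π] since angle is periodic; at the exact image center
the angle is undefined and set to 0 by convention (recorded in the RDM
metadata).  Polar distance is reported in pixels by default.  Body size is
segmentation area over image area.  Embedding controls accept externally
computed feature vectors and offer Euclidean distance on unit-L2-scaled
vectors ("normalized embeddings") or 1 − Pearson correlation on raw
vectors; feature extraction itself is out of scope.

## RSA core

Patterns are prepared by averaging the trials of each image and z-scoring
each voxel across images (sample SD, n − 1), so every voxel contributes
equally to the distance computation; voxels constant across images are
excluded and recorded.  The neural RDM is 1 − Pearson correlation between
item patterns.  RDM comparison is Pearson correlation between
strictly-lower-triangle vectors — a single fixed vectorization keeps
results bit-stable.  Pearson is used throughout, also for partial
correlations, which are computed by least-squares residualization of both
triangle vectors on the control triangles (with intercept) followed by
correlation of residuals; this is algebraically the inverse-correlation-
matrix formula but numerically stabler with several controls, and it
matches the three-variable closed form to 1e-10 in the tests.  When a
subject saw only a subset of images, model RDMs are subset and
re-normalized on that subset before correlation.  Fisher z uses atanh with
|r| clipped to 1 − 1e-12 to avoid infinities from degenerate searchlights.

## Searchlight

Neighborhoods contain a fixed count (default 100) of in-mask voxels
nearest to each center by center-to-center distance, with exact ties
broken lexicographically by grid index so maps are deterministic across
platforms; at mask edges the neighborhood reaches farther inward rather
than shrinking.  The fixed count corresponds, at 1.8 mm voxels, to an
equivalent-volume sphere of radius (3·100·1.8³/4π)^(1/3) ≈ 5.2 mm,
exposed as `equivalent_radius`.  Pattern preparation commutes with voxel
restriction (averaging and z-scoring are per-voxel operations), so
patterns are prepared once and each searchlight restricts columns.
Centers whose searchlight degenerates (an item pattern with zero variance
over the neighborhood's voxels) get NaN and are excluded from group
statistics, consistent with masking semantics.

## Group inference

Subject maps on a shared grid are tested with a voxel-wise one-sample t
statistic (sd with n − 1; NaN subjects excluded voxel-wise with adjusted
n; zero-variance voxels NaN rather than ±∞).  Cluster correction: voxels
with one-tailed p < 0.001 (right tail of t with n − 1 df; positive model
correlation is the hypothesis) form connected components (26-connectivity
by default, configurable to 6 or 18), each scored by its sum of t values.
The null distribution of the maximum cluster sum is built from random sign
flips of whole subject maps — the exchangeable null for symmetric-about-
zero subject effects in a one-sample design.  Cluster p-values use the
(1 + k)/(1 + N) estimator, which is never exactly zero.  Defaults are
10,000 permutations and initial p 0.001; the permutation loop only
recomputes voxel means per flip (squares are flip-invariant), so nulls are
cheap.  Cluster inference is restricted to voxels finite in every subject;
the observed t map itself is NaN-aware.  Type-I calibration is verified by
simulation: over 200 null replicates (8 subjects, 20³ grid, 500
permutations) the family-wise error at α = 0.05 falls within [0.03, 0.07].

## ROI analysis and the noise ceiling

ROI RSA runs the same pipeline over all (optionally localizer-thresholded,
strict t > threshold) voxels of a region.  The noise ceiling for
two-repeat designs models each observed pattern as signal-plus-noise with
multivariate Gaussian signal (per image) and noise (per trial):

1. noise covariance = Cov((t₁ − t₂)/√2) across images — repeat differences
   cancel the signal, and the √2 scaling makes the estimator consistent
   for the per-trial noise covariance;
2. signal covariance = Cov((t₁ + t₂)/2) − Σ_noise/2, eigenvalue-floored at
   zero (repairs are recorded);
3. a scalar on the signal covariance is calibrated by bisection (tolerance
   1e-3, common random numbers for monotonicity) so that simulated
   split-half reliability of similarity matrices matches the empirical
   split-half reliability of the two repeats;
4. each of n_sim (default 1,000) simulations draws item signals and two
   noisy repeats, builds the noiseless similarity matrix from the signals
   and the noisy one from averaged simulated measurements through the same
   averaging/z-scoring pipeline as real data, and records their triangle
   correlation; the ceiling is the mean.

Similarity (correlation) matrices are used in this module; they are
1 − RDM, and triangle correlations are identical either way.  The
calibration target is the split-half correlation of whole similarity
matrices (not of individual entries) — a design choice, recorded here.
The estimator is validated against an oracle that runs the same Monte
Carlo with the true generating distributions (agreement within 0.05 at
100 items) and against the noiseless limit (ceiling 1).  Known
limitation: when the empirical split-half reliability is close to zero
(weak representational signal or very high noise), its sampling error
dominates the calibration and the ceiling estimate becomes unstable —
estimates in that regime should be read alongside the reported empirical
reliability.

## Synthetic data

The generator defines the package's study conditions: 60 images, 100
voxels, 2 repeats per image, trial noise 0.5 in units of the planted
pattern SD for recovery experiments; 8 subjects on a 20³ grid for group
simulations.  Poses are a fixed template skeleton (arbitrary but fixed
human proportions, ~1.7 m tall) jittered per joint with Gaussian SD 0.1 m
— enough to produce a broad range of articulated poses while keeping them
body-like — and placed under uniform random rotations drawn as normalized
4D Gaussians (exactly uniform on the rotation group).  Keypoint records
are constructed so that exactly round(n · fraction_valid) images pass the
stimulus filter, with the invalid remainder violating it through an extra
person, missing limb flags, or no annotation.

Planted voxel responses are constructed so that the measurement pipeline
itself recovers the target geometry exactly at zero noise.  Classical MDS
embedding of the target RDM does not achieve this: the pipeline's item-mean
removal and voxel z-scoring double-center and rescale the pattern Gram, and
the 1 − correlation metric differs from Euclidean distance, which in
practice caps the recovered triangle correlation near 0.7.  Instead the
generator solves the inverse problem.  Any item-correlation matrix that
the pipeline can output is singular with a positive null vector (the
norm-weighted patterns sum to zero after mean removal), so the target
correlation structure is taken as C = I − D/ρ(D), with ρ(D) the largest
eigenvalue of the target dissimilarity D: C is positive semidefinite,
exactly singular, and its null vector — the Perron eigenvector of D — is
entrywise positive.  The planted Gram K = C ∘ ssᵀ (s that eigenvector) is
then exactly doubly centered, so item-mean removal is a no-op.  Patterns
are expanded on a Fourier cos/sin voxel basis orthogonal to the constant
vector (row means exactly zero, so the correlation's row-centering is a
no-op) and rotated within the basis so all voxel variances are identical
(alternating projections between the fixed-spectrum set and the
constant-diagonal constraint, converging to machine precision in tens of
iterations), which reduces voxel z-scoring to a uniform rescaling.  The
measured RDM is then an affine image of D to ~1e-15, and Pearson RDM
correlation is affine-invariant.  One consequence is a bounded contrast:
the planted correlation structure scales as range(D)/ρ(D) ≈ O(1/n_items),
so absolute RSA correlations on noisy synthetic data are modest even when
model ranking is unambiguous — mirroring the small-but-reliable
correlations typical of real RSA.  Generation fails loudly if the realized
geometry correlates below 0.95 with the target (it is 1.0 in practice).

What the generator does not emulate: spatial autocorrelation of fMRI noise
(noise is isotropic i.i.d.), hemodynamic or session structure,
inter-subject anatomical variability (maps are generated directly on a
shared grid), non-Gaussian signal distributions, and image-level
covariates correlated with pose (synthetic body geometry controls are
independent of pose).  Passing tests therefore demonstrate correctness of
the estimators and inference machinery under their stated assumptions, not
robustness to structured physiological noise.

## Problem sizes

Simulation-based tests and the acceptance script use: 200 null replicates
× 500 permutations for permutation calibration; 100 replicates at 60
items × 100 voxels for model recovery; 500 simulations at 100 items for
noise-ceiling validation; brute-force oracles on masks up to 15³–20³.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full run to a few minutes on one CPU.
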