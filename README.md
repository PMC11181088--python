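# poselight

Representational similarity analysis (RSA) of human body pose for fMRI.

When people view other people, visual cortex must solve a geometry problem:
the 2D image of a body confounds the body's articulated 3D pose with the
viewpoint it is seen from.  `poselight` implements the analysis machinery
for asking which of these representations a brain region carries.  It
parameterizes each stimulus body as

- **view-dependent 3D pose** `p3d_v = [J_1 … J_K]`, the raw K = 19 joint
  locations (`J_k ∈ R^3`);
- **view-dependent 2D pose** `p2d`, the same joints with depth discarded;
- **view-independent 3D pose** `p3d_vi` with `J_k^(vi) = R^{-1} J_k`, the
  joints after undoing the global body rotation `R`, so two poses that
  differ only in viewpoint coincide;
- **viewpoint**, the global rotation itself as a unit quaternion `q`;

and builds representational dissimilarity matrices (RDMs) from pairwise
distances: mean per-joint position error `d(p_i, p_j) = (1/K) Σ_k ‖J_ik −
J_jk‖₂` for the pose models, the quaternion geodesic `d_v(q_i, q_j) =
arccos(|q_i · q_j|)` for viewpoint, and a per-joint rotation variant
`(1/K) Σ_k arccos(|q_ik · q_jk|)` as a rotation-based pose control.  Control
RDMs for body position (polar angle/eccentricity of the person bounding
box), body size (segmentation area) and arbitrary precomputed feature
embeddings isolate pose information from image covariates.  Model RDMs are
min–max normalized to [0, 1].

Neural RDMs are built the standard way: per-trial response amplitudes
(GLM betas) are averaged over repeated presentations of each image,
z-scored per voxel across images, and compared between items by
1 − Pearson correlation.  Model and neural RDMs are related by Pearson (or
partial Pearson) correlation of their lower-triangle vectors, either within
an ROI or in a 100-voxel spherical searchlight (equivalent radius ≈ 5.2 mm
at 1.8 mm voxels) whose correlation is written at the center voxel.
Group inference Fisher-z transforms subject maps, tests them against zero
with a one-tailed t test per voxel, and corrects family-wise error with a
max-sum cluster-based Monte Carlo sign-flip permutation test (initial
threshold P < 0.001, 10,000 permutations by default).  ROI analyses come
with a Monte-Carlo noise ceiling for two-repeat designs, estimated from
multivariate Gaussian signal and noise distributions calibrated to the
empirical split-half reliability of the similarity matrices.

A first-class synthetic-data module generates every input the pipeline
needs — articulated poses under random viewpoints, COCO-style keypoint
annotations, and voxel responses whose measured representational geometry
*exactly* equals a chosen mixture of model RDMs — so every stage is
testable end to end without any neuroimaging downloads.

## Worked example

Sixty synthetic poses, a view-independent pose geometry planted into a
100-voxel "ROI" at trial noise 0.1 (in units of pattern SD), two repeats:

```python
import poselight as pl
from poselight.rdm import normalize_rdm

poses, _ = pl.generate_poses(60, jitter_sd=0.1, seed=0)
rdms = {m: normalize_rdm(pl.build_model_rdm(poses, m)) for m in pl.POSE_MODELS}

cfg = pl.SyntheticConfig(n_images=60, n_voxels=100, n_repeats=2, noise_sd=0.1, seed=0)
data, planted = pl.generate_responses([rdms["view_indep_3d"]], [1.0], cfg)

ds = pl.RoiDataset(roi="synthetic-EBA", betas=data.betas,
                   trial_image_ids=data.trial_image_ids)
print(pl.RoiRSA(ds, list(rdms.values())).fit().summary())
print(pl.NoiseCeiling(ds, n_sim=200).fit(seed=0).summary())
```

prints

```
ROI RSA
          roi          model         r  fisher_z controls
synthetic-EBA    view_dep_3d  0.031728  0.031738
synthetic-EBA    view_dep_2d  0.028788  0.028796
synthetic-EBA  view_indep_3d  0.474055  0.515287
synthetic-EBA      viewpoint -0.003909 -0.003909
synthetic-EBA joint_rotation  0.055130  0.055186
Noise ceiling: 0.5002 (MC se 0.0015, 200 simulations)
  signal scale       : 0.0044
  split-half rel.    : empirical 0.0862, simulated 0.0975
  seed               : 0
```

The planted view-independent model wins the comparison by an order of
magnitude (r = 0.47 against ≤ 0.06 for the others) and sits just below the
estimated noise ceiling of 0.50 — the expected behavior when the measured
geometry is the planted model plus trial noise.  At `noise_sd=0` the
recovered correlation is 1.0 exactly.

The same pipeline is scriptable from a shell (`poselight build-rdms`,
`filter-stimuli`, `build-control-rdm`, `searchlight`, `group-stats`,
`roi-rsa`, `noise-ceiling`, `simulate`); see `poselight --help`.

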