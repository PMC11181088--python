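"""Synthetic inputs for every pipeline stage.

Three generators emulate the study's data so the full analysis is testable
without any downloads:

- articulated 19-joint poses: a fixed template skeleton perturbed by
  Gaussian joint jitter (the canonical pose) and placed under a uniformly
  random global rotation, with optional near-identity per-joint rotations;
- COCO-style keypoint records with a controlled number of images that pass
  the single-full-person filter;
- voxel responses whose measured representational geometry matches a
  weighted mixture of model RDMs (planted geometry), with per-trial
  Gaussian noise and repeat presentations, as a flat voxel set or placed
  inside a sub-region of a 3D mask.

Planted geometry is constructed so the *measurement pipeline itself*
(average repeats, z-score each voxel across images, 1 - correlation)
recovers the target RDM exactly at zero noise.  The target item-correlation
structure is ``C = I - D/rho`` with rho the largest eigenvalue of the
target dissimilarity D: C is positive semidefinite and singular, and its
null vector s (the Perron eigenvector of D) is entrywise positive, as a
valid correlation structure of mean-removed patterns must be.  The planted
Gram ``K = C * s s^T`` is then exactly doubly centered, so removing the
mean pattern across items is a no-op.  Patterns are expanded on a Fourier
cos/sin voxel basis orthogonal to the constant vector (item means over
voxels are exactly zero, so the correlation's row centering is a no-op),
rotated within the basis so that every voxel has identical variance
(alternating projections between the fixed-spectrum set and the
constant-diagonal constraint), which makes voxel z-scoring a uniform
rescaling.  The measured RDM is then an affine image of D to machine
precision, and its triangle correlation with D is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .group import MapStack
from .keypoints import (
    COCO_KEYPOINT_NAMES,
    KeypointRecord,
    Person,
)
from .pose import JOINT_NAMES, N_JOINTS, PoseRecord
from .quaternions import UnitQuaternion, random_rotation_matrix
from .rdm import RDM, lower_triangle, normalize_rdm
from .rsa import NeuralDataset

__all__ = [
    "SyntheticConfig",
    "PlantedGeometry",
    "TEMPLATE_SKELETON",
    "generate_poses",
    "generate_keypoint_records",
    "generate_responses",
    "generate_subject_maps",
]

#: Template skeleton (units: meters, upright person ~1.7 m, x rightward,
#: y upward, z toward the viewer).  Proportions are fixed and arbitrary;
#: only relative geometry matters to every pose metric.
TEMPLATE_SKELETON: Dict[str, Tuple[float, float, float]] = {
    "left_ankle": (0.12, 0.08, 0.00),
    "right_ankle": (-0.12, 0.08, 0.00),
    "left_knee": (0.11, 0.50, 0.02),
    "right_knee": (-0.11, 0.50, 0.02),
    "left_hip": (0.10, 0.95, 0.00),
    "right_hip": (-0.10, 0.95, 0.00),
    "left_wrist": (0.55, 1.05, 0.05),
    "right_wrist": (-0.55, 1.05, 0.05),
    "left_elbow": (0.35, 1.22, 0.03),
    "right_elbow": (-0.35, 1.22, 0.03),
    "left_shoulder": (0.18, 1.45, 0.00),
    "right_shoulder": (-0.18, 1.45, 0.00),
    "neck": (0.00, 1.50, 0.00),
    "head": (0.00, 1.66, 0.02),
    "nose": (0.00, 1.60, 0.09),
    "left_eye": (0.035, 1.63, 0.08),
    "right_eye": (-0.035, 1.63, 0.08),
    "left_ear": (0.07, 1.62, 0.02),
    "right_ear": (-0.07, 1.62, 0.02),
}


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic response dataset.

    noise_sd is expressed in units of the mean planted-pattern voxel SD
    (relative trial noise); n_repeats is the number of presentations per
    image.  Either give n_voxels (flat voxel set) or mask + signal_mask
    (volumetric: planted patterns inside signal_mask, pure noise elsewhere
    in mask).
    """

    n_images: int = 60
    n_voxels: int = 100
    n_repeats: int = 2
    noise_sd: float = 0.5
    seed: int = 0
    mask: Optional[np.ndarray] = None
    signal_mask: Optional[np.ndarray] = None
    voxel_size_mm: float = 1.8


@dataclass
class PlantedGeometry:
    """Record of what was planted, and how faithfully it was realized."""

    model_names: List[str]
    weights: List[float]
    target: RDM
    realized: RDM
    fidelity: float  # triangle Pearson(realized, target)
    patterns: np.ndarray  # item x signal-voxel noiseless patterns
    seed: int


# ------------------------------------------------------------------- poses

def generate_poses(
    n: int,
    jitter_sd: float = 0.1,
    seed: int = 0,
    joint_rotation_sd: float = 0.25,
    with_joint_rotations: bool = True,
) -> Tuple[List[PoseRecord], List[np.ndarray]]:
    """Poses as randomly rotated, jittered copies of the template skeleton.

    Per image: canonical pose P = template + N(0, jitter_sd) per joint
    coordinate; global rotation R uniform on SO(3); stored joints are R P.
    Returns the records and the canonical (unrotated) poses P.
    """
    if n < 2:
        raise InvalidInputError("need n >= 2 poses")
    rng = np.random.default_rng(seed)
    template = np.array([TEMPLATE_SKELETON[name] for name in JOINT_NAMES])
    records = []
    canonical = []
    for i in range(n):
        P = template + rng.normal(scale=jitter_sd, size=template.shape)
        R = random_rotation_matrix(rng)
        joint_rotations = None
        if with_joint_rotations:
            joint_rotations = []
            for _ in range(N_JOINTS):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = rng.normal(scale=joint_rotation_sd)
                q = np.concatenate([[np.cos(angle / 2.0)], np.sin(angle / 2.0) * axis])
                joint_rotations.append(UnitQuaternion.from_array(q))
        records.append(
            PoseRecord(
                image_id=f"img{i:05d}",
                joints3d=P @ R.T,  # row k is R P_k
                global_rotation=R,
                joint_rotations=joint_rotations,
            )
        )
        canonical.append(P)
    return records, canonical


# --------------------------------------------------------------- keypoints

def _random_person(rng: np.random.Generator, width: int, height: int, full: bool) -> Person:
    """A person annotation; `full` means all 12 limb keypoints annotated."""
    cx = rng.uniform(0.25 * width, 0.75 * width)
    cy = rng.uniform(0.25 * height, 0.75 * height)
    span = rng.uniform(0.1, 0.35) * min(width, height)
    kp = np.column_stack(
        [
            np.clip(cx + rng.normal(scale=span, size=17), 0, width - 1),
            np.clip(cy + rng.normal(scale=span, size=17), 0, height - 1),
        ]
    )
    vis = rng.choice([1, 2], size=17)
    # face keypoints may or may not be annotated; the filter must ignore them
    vis[:5] = rng.choice([0, 1, 2], size=5)
    if not full:
        # knock out one or more limb keypoints (occlusion or truncation)
        k = rng.integers(1, 4)
        drop = rng.choice(np.arange(5, 17), size=k, replace=False)
        vis[drop] = 0
        kp[drop] = 0.0
    x0, y0 = kp[vis > 0].min(axis=0) if (vis > 0).any() else (0.0, 0.0)
    x1, y1 = kp[vis > 0].max(axis=0) if (vis > 0).any() else (1.0, 1.0)
    bbox = (float(x0), float(y0), float(max(x1 - x0, 1.0)), float(max(y1 - y0, 1.0)))
    area = 0.45 * bbox[2] * bbox[3]
    return Person(keypoints=kp, visibility=vis, bbox=bbox, segmentation_area=area)


def generate_keypoint_records(
    n: int,
    fraction_valid: float,
    seed: int = 0,
    image_size: Tuple[int, int] = (512, 512),
) -> Tuple[List[KeypointRecord], List[str]]:
    """Keypoint records of which exactly round(n * fraction_valid) pass the filter.

    Invalid records violate the single-full-person rule by one of three
    randomized mechanisms: an extra annotated person, missing limb keypoint
    flags, or no person annotation at all.  Returns the records and the ids
    of the qualifying images.
    """
    if not 0.0 <= fraction_valid <= 1.0:
        raise InvalidInputError("fraction_valid must be in [0, 1]")
    rng = np.random.default_rng(seed)
    width, height = image_size
    n_valid = int(round(n * fraction_valid))
    valid_flags = np.zeros(n, dtype=bool)
    valid_flags[rng.choice(n, size=n_valid, replace=False)] = True
    records = []
    valid_ids = []
    for i in range(n):
        image_id = f"coco{i:06d}"
        if valid_flags[i]:
            persons = [_random_person(rng, width, height, full=True)]
            valid_ids.append(image_id)
        else:
            mechanism = rng.integers(0, 3)
            if mechanism == 0:  # two persons, both full
                persons = [
                    _random_person(rng, width, height, full=True),
                    _random_person(rng, width, height, full=True),
                ]
            elif mechanism == 1:  # one person, incomplete limbs
                persons = [_random_person(rng, width, height, full=False)]
            else:  # no person annotation
                persons = []
        records.append(
            KeypointRecord(
                image_id=image_id, persons=persons, image_width=width, image_height=height
            )
        )
    return records, valid_ids


# ------------------------------------------------------- planted responses

def _fourier_pair_basis(V: int, r: int) -> np.ndarray:
    """V x r orthonormal cos/sin pairs at distinct frequencies, orthogonal to 1."""
    if r % 2 or r // 2 > (V - 1) // 2:
        raise ConfigurationError(f"cannot build {r} Fourier columns for {V} voxels")
    v = np.arange(V)
    cols = []
    for f in range(1, r // 2 + 1):
        cols.append(np.cos(2 * np.pi * f * v / V))
        cols.append(np.sin(2 * np.pi * f * v / V))
    return np.array(cols).T * np.sqrt(2.0 / V)


def _plant_patterns(
    D: np.ndarray, n_voxels: int, n_iter: int = 500, rtol: float = 1e-13
) -> np.ndarray:
    """Item x voxel patterns whose pipeline RDM is an affine image of D.

    See the module docstring for the construction.  Returns patterns scaled
    so the voxel SD is 1 (the unit for relative trial noise).
    """
    n = D.shape[0]
    if n_voxels < n + 2:
        raise ConfigurationError(
            f"exact geometry planting needs n_voxels >= n_items + 2 ({n_voxels} < {n + 2})"
        )
    wD, UD = np.linalg.eigh((D + D.T) / 2.0)
    rho = float(wD[-1])
    if rho <= 0:
        raise ConfigurationError("target RDM has no positive structure to plant")
    s = UD[:, -1]
    s = s * np.sign(s.sum())
    if s.min() <= 0:
        # Perron positivity can fail only for a disconnected dissimilarity
        # structure; a vanishing off-diagonal ridge restores irreducibility
        ridge = 1e-9 * D.max()
        Dr = D + ridge * (np.ones((n, n)) - np.eye(n))
        wD, UD = np.linalg.eigh((Dr + Dr.T) / 2.0)
        rho = float(wD[-1])
        s = UD[:, -1] * np.sign(UD[:, -1].sum())
        if s.min() <= 0:
            raise ConfigurationError("planting failed: non-positive Perron vector")
    C = np.eye(n) - D / rho  # PSD, singular, C s = 0 with s > 0
    K = C * np.outer(s, s)  # doubly centered planted Gram
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    neg = -w.clip(max=0.0).sum()
    pos = w.clip(min=0.0).sum()
    if pos > 0 and neg / pos > 0.10:
        warnings.warn(
            f"target dissimilarity is poorly embeddable: clipped {neg / pos:.1%} of spectrum mass"
        )
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    nz = max(2, int((w > w[0] * 1e-12).sum()))
    r = min(nz + (nz % 2), 2 * ((n_voxels - 1) // 2))
    lam = w[:r]
    B = U[:, :r] * np.sqrt(lam)
    Q = _fourier_pair_basis(n_voxels, r)

    # rotate the factor within the basis so every voxel gets identical
    # variance: alternate between the constant-diagonal linear constraint
    # and the fixed-spectrum set for the voxel-space covariance coefficient
    # matrix S (voxel covariance = Q S Q^T, spectrum(S) = lam)
    A_rows = np.einsum("vi,vj->vij", Q, Q).reshape(n_voxels, r * r)
    AAt_inv = np.linalg.pinv(A_rows @ A_rows.T)
    S = np.diag(lam)
    for _ in range(n_iter):
        d = A_rows @ S.ravel()
        d -= d.mean()
        if np.abs(d).max() < rtol * lam.mean():
            break
        corr = (A_rows.T @ (AAt_inv @ d)).reshape(r, r)
        S = S - (corr + corr.T) / 2.0
        ws, G = np.linalg.eigh(S)
        G = G[:, np.argsort(ws)[::-1]]
        S = (G * lam) @ G.T
    ws, G = np.linalg.eigh(S)
    W = G[:, np.argsort(ws)[::-1]]
    X = (B @ W.T) @ Q.T  # XX^T = K, voxel covariance = Q S Q^T
    sd = X.std(axis=0, ddof=1)
    return X / sd.mean()


def _pipeline_rdm_values(X: np.ndarray) -> np.ndarray:
    """The measurement pipeline's RDM of noiseless patterns (z-score, 1 - corr)."""
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    vals = 1.0 - np.corrcoef(Z)
    np.fill_diagonal(vals, 0.0)
    return np.clip((vals + vals.T) / 2.0, 0.0, None)


def generate_responses(
    rdms: Sequence[RDM],
    weights: Sequence[float],
    config: SyntheticConfig,
) -> Tuple[NeuralDataset, PlantedGeometry]:
    """Trial-wise voxel responses with planted representational geometry.

    The target dissimilarity is the weighted sum of the min-max normalized
    input RDMs.  Signal patterns realize that geometry (see module
    docstring); each trial adds isotropic Gaussian noise of SD
    ``config.noise_sd`` (in units of the mean pattern SD) and every image is
    presented ``config.n_repeats`` times.  With ``config.mask`` and
    ``config.signal_mask`` set, patterns occupy the signal voxels of a 3D
    grid and the remaining mask voxels carry pure noise.
    """
    rdms = list(rdms)
    weights = [float(w) for w in weights]
    if len(rdms) != len(weights):
        raise ConfigurationError("rdms and weights must have equal length")
    if not rdms:
        raise ConfigurationError("need at least one RDM to plant")
    if any(w < 0 for w in weights):
        raise ConfigurationError("weights must be nonnegative")
    if sum(weights) == 0:
        raise ConfigurationError("weights must not all be zero")
    ids = list(rdms[0].item_ids)
    for r in rdms[1:]:
        if set(r.item_ids) != set(ids):
            raise ConfigurationError("all RDMs must share item_ids")
    target_vals = np.zeros((len(ids), len(ids)))
    for w, r in zip(weights, rdms):
        target_vals += w * normalize_rdm(r).aligned_values(ids)
    target = RDM(
        item_ids=ids,
        values=target_vals,
        model="+".join(f"{w:g}*{r.model}" for w, r in zip(weights, rdms)),
        normalized=False,
    )

    rng = np.random.default_rng(config.seed)
    if config.mask is not None:
        mask = np.asarray(config.mask, dtype=bool)
        if config.signal_mask is None:
            raise ConfigurationError("volumetric generation requires signal_mask")
        signal_mask = np.asarray(config.signal_mask, dtype=bool)
        if (signal_mask & ~mask).any():
            raise ConfigurationError("signal_mask must lie inside mask")
        voxel_index = np.argwhere(mask)
        in_signal = signal_mask[tuple(voxel_index.T)]
        n_signal = int(in_signal.sum())
        n_total = len(voxel_index)
    else:
        n_signal = n_total = config.n_voxels
        in_signal = np.ones(n_total, dtype=bool)
        mask = np.ones((1, 1, n_total), dtype=bool)
        voxel_index = np.argwhere(mask)

    patterns = _plant_patterns(target.values, n_signal)
    realized = RDM(item_ids=ids, values=_pipeline_rdm_values(patterns), model="realized")
    fid = float(np.corrcoef(lower_triangle(realized.values), target.triangle())[0, 1])
    if fid < 0.95:
        raise ConfigurationError(
            f"planted geometry fidelity {fid:.3f} below 0.95; target not embeddable"
        )

    n_items = len(ids)
    full = np.zeros((n_items, n_total))
    full[:, in_signal] = patterns
    trial_ids: List[str] = []
    betas = np.empty((n_items * config.n_repeats, n_total))
    row = 0
    for rep in range(config.n_repeats):
        noise = rng.normal(scale=config.noise_sd, size=(n_items, n_total)) if config.noise_sd > 0 else 0.0
        betas[row : row + n_items] = full + noise
        trial_ids.extend(ids)
        row += n_items
    data = NeuralDataset(
        betas=betas,
        trial_image_ids=trial_ids,
        voxel_index=voxel_index,
        voxel_size_mm=config.voxel_size_mm,
        mask=mask,
    )
    planted = PlantedGeometry(
        model_names=[r.model for r in rdms],
        weights=weights,
        target=target,
        realized=realized,
        fidelity=fid,
        patterns=patterns,
        seed=config.seed,
    )
    return data, planted


# ------------------------------------------------------------ subject maps

def generate_subject_maps(
    n_subjects: int,
    grid: Tuple[int, int, int],
    blob_spec: Optional[Dict] = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    voxel_size_mm: float = 1.8,
) -> MapStack:
    """Per-subject maps = shared spherical blob (optional) + independent noise.

    ``blob_spec`` is {"center": (i, j, k), "radius": voxels, "amplitude": a};
    None yields exchangeable maps symmetric about zero (the permutation
    null).
    """
    if n_subjects < 2:
        raise InvalidInputError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    base = np.zeros(grid)
    if blob_spec is not None:
        ci, cj, ck = blob_spec["center"]
        radius = float(blob_spec["radius"])
        amp = float(blob_spec["amplitude"])
        ii, jj, kk = np.meshgrid(*[np.arange(g) for g in grid], indexing="ij")
        base[(ii - ci) ** 2 + (jj - cj) ** 2 + (kk - ck) ** 2 <= radius**2] = amp
    maps = base[None] + rng.normal(scale=noise_sd, size=(n_subjects, *grid))
    return MapStack(
        maps=maps,
        subject_ids=[f"sub-{i+1:02d}" for i in range(n_subjects)],
        voxel_size_mm=voxel_size_mm,
    )
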