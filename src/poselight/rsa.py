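"""Core representational similarity analysis.

Response patterns are prepared by averaging repeated presentations of each
image and z-scoring every voxel across images, so each voxel contributes
equally to the distance computation.  The neural RDM is 1 - Pearson
correlation between item patterns.  A model RDM is related to a neural RDM
by Pearson correlation between their strictly-lower-triangle vectors;
partial correlation residualizes both vectors on the control-RDM vectors
(with intercept) first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CollinearityError,
    DegenerateItemError,
    DegenerateRDMError,
    InsufficientDataError,
    InvalidInputError,
    ShapeError,
)
from .rdm import RDM, lower_triangle

__all__ = [
    "NeuralDataset",
    "PatternMatrix",
    "prepare_patterns",
    "neural_rdm",
    "rsa_correlation",
    "partial_rsa",
    "fisher_z",
]


@dataclass
class NeuralDataset:
    """Trial-wise voxel responses on a masked 3D grid.

    betas: (n_trials, n_voxels) response amplitudes;
    trial_image_ids: image shown on each trial (repeats allowed);
    voxel_index: (n_voxels, 3) integer grid coordinates of each voxel;
    voxel_size_mm: isotropic voxel edge length;
    mask: boolean volume; every voxel_index must fall inside it.
    """

    betas: np.ndarray
    trial_image_ids: List[str]
    voxel_index: np.ndarray
    voxel_size_mm: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.trial_image_ids = [str(i) for i in self.trial_image_ids]
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.betas.ndim != 2:
            raise ShapeError(f"betas must be trials x voxels, got {self.betas.shape}")
        if len(self.trial_image_ids) != self.betas.shape[0]:
            raise ShapeError("trial_image_ids length does not match betas rows")
        if self.voxel_index.shape != (self.betas.shape[1], 3):
            raise ShapeError("voxel_index must be (n_voxels, 3)")
        if len(set(self.trial_image_ids)) < 2:
            raise InsufficientDataError("need at least 2 distinct image ids")
        if not self.mask[tuple(self.voxel_index.T)].all():
            raise InvalidInputError("some voxel_index entries fall outside the mask")
        if np.isnan(self.betas).all(axis=0).any():
            raise InvalidInputError("dataset contains all-NaN voxels")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def distinct_image_ids(self) -> List[str]:
        """Distinct image ids in first-appearance order."""
        seen = {}
        for i in self.trial_image_ids:
            seen.setdefault(i, None)
        return list(seen)

    # ----------------------------------------------------------------- I/O
    def to_nifti(self, betas_path: str | Path, mask_path: str | Path, sidecar_path: str | Path) -> None:
        """Write 4D betas + mask NIfTI and a TSV sidecar (trial -> image_id)."""
        import nibabel as nib

        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        vol = np.full(self.mask.shape + (self.betas.shape[0],), np.nan)
        vol[tuple(self.voxel_index.T)] = self.betas.T
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(betas_path))
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(mask_path))
        pd.DataFrame({"trial": np.arange(len(self.trial_image_ids)), "image_id": self.trial_image_ids}).to_csv(
            sidecar_path, sep="\t", index=False
        )

    @classmethod
    def from_nifti(cls, betas_path: str | Path, mask_path: str | Path, sidecar_path: str | Path) -> "NeuralDataset":
        import nibabel as nib

        betas_img = nib.load(str(betas_path))
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.dataobj).astype(bool)
        vol = np.asarray(betas_img.dataobj, dtype=float)
        voxel_index = np.argwhere(mask)
        betas = vol[tuple(voxel_index.T)].T
        voxel_size = float(np.abs(betas_img.affine[0, 0]))
        ids = pd.read_csv(sidecar_path, sep="\t", dtype={"image_id": str})["image_id"].tolist()
        return cls(
            betas=betas,
            trial_image_ids=ids,
            voxel_index=voxel_index,
            voxel_size_mm=voxel_size,
            mask=mask,
        )


@dataclass
class PatternMatrix:
    """Item x voxel patterns after trial averaging and voxel z-scoring.

    Zero-variance voxels are excluded from ``patterns`` and recorded in
    ``excluded_voxels`` (indices into the original voxel axis).
    """

    item_ids: List[str]
    patterns: np.ndarray
    excluded_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    kept_voxels: Optional[np.ndarray] = None

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


def prepare_patterns(
    data: NeuralDataset, voxel_subset: Optional[np.ndarray] = None
) -> PatternMatrix:
    """Average trials per image and z-score each voxel across images.

    Averaging is NaN-aware per voxel (a trial missing a voxel's value does
    not poison the mean).  Voxels constant across items carry no pattern
    information and are excluded, with their indices recorded.
    """
    ids = data.distinct_image_ids()
    if len(ids) < 3:
        raise InsufficientDataError(
            f"need at least 3 distinct images, got {len(ids)}"
        )
    betas = data.betas if voxel_subset is None else data.betas[:, voxel_subset]
    trial_ids = np.asarray(data.trial_image_ids)
    means = np.empty((len(ids), betas.shape[1]))
    for r, image_id in enumerate(ids):
        rows = betas[trial_ids == image_id]
        with np.errstate(invalid="ignore"):
            means[r] = np.nanmean(rows, axis=0)
    sd = means.std(axis=0, ddof=1)
    ok = np.isfinite(sd) & (sd > 0)
    excluded = np.where(~ok)[0]
    patterns = (means[:, ok] - means[:, ok].mean(axis=0)) / sd[ok]
    kept = np.where(ok)[0]
    if voxel_subset is not None:
        voxel_subset = np.asarray(voxel_subset)
        excluded = voxel_subset[excluded]
        kept = voxel_subset[kept]
    return PatternMatrix(item_ids=ids, patterns=patterns, excluded_voxels=excluded, kept_voxels=kept)


def neural_rdm(patterns: PatternMatrix) -> RDM:
    """Neural RDM: 1 - Pearson correlation between item patterns (range [0, 2])."""
    X = patterns.patterns
    if X.shape[1] < 2:
        raise InsufficientDataError(
            f"need at least 2 voxels after exclusion, got {X.shape[1]}"
        )
    sd = X.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        names = [patterns.item_ids[i] for i in flat]
        raise DegenerateItemError(f"zero-variance pattern for items: {names}")
    values = 1.0 - np.corrcoef(X)
    values = np.clip((values + values.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(values, 0.0)
    return RDM(item_ids=list(patterns.item_ids), values=values, model="neural", normalized=False)


def _aligned_triangles(neural: RDM, model: RDM) -> Tuple[np.ndarray, np.ndarray]:
    if set(neural.item_ids) != set(model.item_ids):
        missing = sorted(set(neural.item_ids) ^ set(model.item_ids))
        raise AlignmentError(f"item_id mismatch between RDMs; unmatched ids: {missing}")
    if neural.n_items < 3:
        raise InsufficientDataError("need at least 3 items for RDM correlation")
    x = neural.triangle()
    y = lower_triangle(model.aligned_values(neural.item_ids))
    return x, y


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        raise DegenerateRDMError("constant RDM triangle; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def rsa_correlation(neural: RDM, model: RDM) -> float:
    """Pearson correlation between the lower-triangle vectors of two RDMs."""
    return _pearson(*_aligned_triangles(neural, model))


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Least-squares residual of y on [1, Z]."""
    A = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def partial_rsa(neural: RDM, target: RDM, controls: Sequence[RDM]) -> float:
    """Partial Pearson correlation of neural and target RDMs given controls.

    Both triangle vectors are residualized on the control triangle vectors
    (with intercept) by least squares; the Pearson correlation of the
    residuals is returned.  Equals :func:`rsa_correlation` for an empty
    control list.
    """
    controls = list(controls)
    if not controls:
        return rsa_correlation(neural, target)
    x, y = _aligned_triangles(neural, target)
    if len(controls) >= len(x) - 2:
        raise InsufficientDataError(
            f"{len(controls)} controls for only {len(x)} triangle entries"
        )
    Z = np.column_stack(
        [lower_triangle(c.aligned_values(neural.item_ids)) for c in controls]
    )
    ry = _residualize(y, Z)
    if ry.var() < 1e-12 * max(y.var(), 1.0):
        raise CollinearityError(
            f"target RDM '{target.model}' is linearly dependent on the controls"
        )
    rx = _residualize(x, Z)
    if rx.var() < 1e-12 * max(x.var(), 1.0):
        raise CollinearityError("neural RDM is linearly dependent on the controls")
    return float(np.corrcoef(rx, ry)[0, 1])


def fisher_z(r: float) -> float:
    """Fisher z transform atanh(r), with |r| clipped to 1 - 1e-12 first."""
    r = float(r)
    if abs(r) > 1.0:
        raise InvalidInputError(f"correlation {r} outside [-1, 1]")
    clip = 1.0 - 1e-12
    return float(np.arctanh(np.clip(r, -clip, clip)))
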