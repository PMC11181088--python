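"""Fixed-count spherical searchlight mapping of RSA over a voxel grid.

Each searchlight neighborhood is the fixed number of in-mask voxels nearest
to a center voxel by Euclidean center-to-center distance, with ties broken
lexicographically by grid index so the mapping is deterministic across
platforms.  The neighborhood count (default 100) corresponds, at 1.8 mm
isotropic voxels, to an equivalent-volume sphere of roughly 5.2 mm radius.
RSA is computed within each neighborhood and the correlation is written at
the center voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DegenerateItemError,
    DegenerateRDMError,
    InsufficientDataError,
)
from .rdm import RDM, lower_triangle
from .rsa import (
    NeuralDataset,
    PatternMatrix,
    neural_rdm,
    partial_rsa,
    prepare_patterns,
    rsa_correlation,
)

__all__ = [
    "NeighborhoodSet",
    "BrainMap",
    "build_neighborhoods",
    "equivalent_radius",
    "searchlight_map",
    "SearchlightRSA",
]


@dataclass
class NeighborhoodSet:
    """Searchlight membership: for every in-mask voxel, its `count` nearest neighbors.

    ``centers`` is (n, 3); ``members[i]`` lists indices into ``centers`` in
    nondecreasing distance from center i (the center itself first).
    """

    centers: np.ndarray
    members: np.ndarray  # (n, count) int
    voxel_size_mm: float
    count: int

    def member_coords(self, i: int) -> np.ndarray:
        return self.centers[self.members[i]]


@dataclass
class BrainMap:
    """Scalar brain map: finite inside the mask, NaN outside."""

    data: np.ndarray  # 3D float
    voxel_size_mm: float
    space: str = "subject"  # or "shared"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError(f"BrainMap data must be 3D, got {self.data.shape}")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, space: str = "subject") -> "BrainMap":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            voxel_size_mm=float(np.abs(img.affine[0, 0])),
            space=space,
        )


def equivalent_radius(count: int, voxel_size_mm: float) -> float:
    """Radius in mm of a sphere whose volume equals `count` voxels.

    Solves (4/3) pi r^3 = count * voxel_size^3.  For 100 voxels of 1.8 mm
    this gives about 5.2 mm.
    """
    if count < 1:
        raise ConfigurationError("count must be >= 1")
    if voxel_size_mm <= 0:
        raise ConfigurationError("voxel size must be positive")
    return float((3.0 * count / (4.0 * np.pi)) ** (1.0 / 3.0) * voxel_size_mm)


def build_neighborhoods(
    mask: np.ndarray, voxel_size_mm: float, count: int
) -> NeighborhoodSet:
    """Fixed-count nearest-neighbor searchlights for every in-mask voxel.

    Distances are Euclidean between voxel centers in mm; exact ties are
    broken lexicographically by (i, j, k).  Neighborhoods at mask edges
    still contain `count` members by reaching farther into the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)  # lexicographically sorted by construction
    n = len(coords)
    if n == 0:
        raise ConfigurationError("mask is empty")
    if count > n:
        raise ConfigurationError(f"count {count} exceeds {n} in-mask voxels")
    tree = cKDTree(coords)
    dists, idx = tree.query(coords, k=count)
    if count == 1:
        dists = dists[:, None]
        idx = idx[:, None]
    members = np.empty((n, count), dtype=int)
    for c in range(n):
        kth = dists[c, -1]
        # gather every voxel at distance <= kth (catches ties), then apply
        # the deterministic (distance^2, i, j, k) order in exact integers
        cand = tree.query_ball_point(coords[c], kth * (1 + 1e-9) + 1e-9)
        cand = np.asarray(cand, dtype=int)
        d2 = np.sum((coords[cand] - coords[c]) ** 2, axis=1)  # exact ints
        order = np.lexsort(
            (coords[cand][:, 2], coords[cand][:, 1], coords[cand][:, 0], d2)
        )
        members[c] = cand[order[:count]]
    return NeighborhoodSet(
        centers=coords, members=members, voxel_size_mm=float(voxel_size_mm), count=count
    )


def searchlight_map(
    data: NeuralDataset,
    target: RDM,
    controls: Sequence[RDM] = (),
    neighborhoods: Optional[NeighborhoodSet] = None,
    count: int = 100,
) -> BrainMap:
    """Standard or partial RSA in every searchlight; result written at the center.

    Patterns are prepared once over the whole dataset (averaging and voxel
    z-scoring are voxel-wise operations, so preparation commutes with
    neighborhood restriction).  Centers whose neighborhood degenerates
    (zero-variance item pattern, or fewer than two non-excluded voxels)
    receive NaN.
    """
    if neighborhoods is None:
        neighborhoods = build_neighborhoods(data.mask, data.voxel_size_mm, count)
    if len(neighborhoods.centers) != data.n_voxels or not np.array_equal(
        neighborhoods.centers, data.voxel_index
    ):
        raise ConfigurationError("neighborhoods were built on a different voxel grid")

    prepared = prepare_patterns(data)
    ids = prepared.item_ids
    n_items = len(ids)
    target = target.subset(ids)
    controls = [c.subset(ids) for c in controls]

    # full z-scored pattern matrix indexed by original voxel id; NaN for excluded
    full = np.full((n_items, data.n_voxels), np.nan)
    full[:, prepared.kept_voxels] = prepared.patterns

    tri_i, tri_j = np.tril_indices(n_items, -1)
    y = target.triangle()
    Z = (
        np.column_stack([c.triangle() for c in controls]) if controls else None
    )
    out = np.full(data.mask.shape, np.nan)
    for c in range(len(neighborhoods.centers)):
        cols = neighborhoods.members[c]
        X = full[:, cols]
        X = X[:, ~np.isnan(X[0])]
        if X.shape[1] < 2:
            continue
        sd = X.std(axis=1)
        if (sd == 0).any():
            continue  # degenerate item pattern in this searchlight
        C = np.corrcoef(X)
        x = 1.0 - C[tri_i, tri_j]
        if x.std() == 0 or y.std() == 0:
            continue
        if Z is None:
            r = np.corrcoef(x, y)[0, 1]
        else:
            A = np.column_stack([np.ones(len(x)), Z])
            coef_x, *_ = np.linalg.lstsq(A, x, rcond=None)
            coef_y, *_ = np.linalg.lstsq(A, y, rcond=None)
            rx, ry = x - A @ coef_x, y - A @ coef_y
            if rx.std() == 0 or ry.std() == 0:
                continue
            r = np.corrcoef(rx, ry)[0, 1]
        out[tuple(neighborhoods.centers[c])] = r
    return BrainMap(data=out, voxel_size_mm=data.voxel_size_mm, space="subject")


class SearchlightRSA:
    """Model object: searchlight RSA of one target RDM over a masked dataset.

    Parameters mirror :func:`searchlight_map`; ``fit`` returns a
    :class:`SearchlightResult` carrying the correlation map and run metadata.
    """

    def __init__(
        self,
        data: NeuralDataset,
        target: RDM,
        controls: Sequence[RDM] = (),
        count: int = 100,
    ) -> None:
        self.data = data
        self.target = target
        self.controls = list(controls)
        self.count = count

    def fit(self) -> "SearchlightResult":
        neighborhoods = build_neighborhoods(
            self.data.mask, self.data.voxel_size_mm, self.count
        )
        cmap = searchlight_map(
            self.data, self.target, self.controls, neighborhoods=neighborhoods
        )
        return SearchlightResult(
            map=cmap,
            target_model=self.target.model,
            control_models=[c.model for c in self.controls],
            count=self.count,
            radius_mm=equivalent_radius(self.count, self.data.voxel_size_mm),
        )


@dataclass
class SearchlightResult:
    """Fitted searchlight map plus run metadata."""

    map: BrainMap
    target_model: str
    control_models: List[str]
    count: int
    radius_mm: float

    def summary(self) -> str:
        vals = self.map.data[np.isfinite(self.map.data)]
        lines = [
            "Searchlight RSA",
            f"  target model : {self.target_model}",
            f"  controls     : {', '.join(self.control_models) or '(none)'}",
            f"  neighborhood : {self.count} voxels (~{self.radius_mm:.1f} mm radius)",
            f"  centers      : {vals.size} finite of {self.map.data.size} grid voxels",
            f"  correlation  : mean {vals.mean():.4f}, max {vals.max():.4f}"
            if vals.size
            else "  correlation  : (no finite centers)",
        ]
        return "\n".join(lines)

    def plot(self, axis: int = 2, ax=None):
        """Mid-slice heat map of the correlation volume."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sl = [slice(None)] * 3
        sl[axis] = self.map.data.shape[axis] // 2
        im = ax.imshow(self.map.data[tuple(sl)].T, origin="lower", cmap="viridis")
        ax.set_title(f"searchlight r: {self.target_model}")
        plt.colorbar(im, ax=ax)
        return ax
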