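"""Group-level inference on Fisher-z correlation maps.

Subject maps on a shared grid are tested against zero with a one-tailed
one-sample t test at each voxel.  Family-wise error is controlled with a
cluster-based Monte Carlo permutation test: voxels exceeding an initial
one-tailed threshold are grouped into connected clusters, each cluster is
scored by the sum of its t values (max-sum statistic), and the observed
cluster sums are compared with the distribution of the maximum cluster sum
under random sign flips of whole subject maps — the exchangeable null for a
one-sample test of symmetric-about-zero maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConfigurationError, InsufficientDataError, ShapeError
from .searchlight import BrainMap

__all__ = [
    "MapStack",
    "ClusterResult",
    "group_t_map",
    "cluster_permutation",
    "GroupClusterTest",
]


@dataclass
class MapStack:
    """Aligned per-subject scalar maps on one shared grid."""

    maps: np.ndarray  # (n_subjects, X, Y, Z)
    subject_ids: List[str]
    voxel_size_mm: float = 1.8

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ShapeError(f"maps must be (subjects, X, Y, Z), got {self.maps.shape}")
        if len(self.subject_ids) != self.maps.shape[0]:
            raise ShapeError("subject_ids length does not match maps")
        if self.maps.shape[0] < 2:
            raise InsufficientDataError("need at least 2 subjects")

    @classmethod
    def from_maps(cls, maps: Sequence[BrainMap], subject_ids: Optional[Sequence[str]] = None) -> "MapStack":
        arr = np.stack([m.data for m in maps])
        ids = list(subject_ids) if subject_ids is not None else [f"sub-{i+1:02d}" for i in range(len(maps))]
        return cls(maps=arr, subject_ids=ids, voxel_size_mm=maps[0].voxel_size_mm)

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]


def group_t_map(stack: MapStack) -> BrainMap:
    """Voxel-wise one-sample t statistic (mean / (sd / sqrt(n)), sd with n-1).

    Subjects with NaN at a voxel are excluded there with adjusted n; voxels
    with fewer than 2 finite subjects, or zero across-subject variance, are
    NaN.
    """
    M = stack.maps
    finite = np.isfinite(M)
    n = finite.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(finite, M, 0.0), axis=0) / np.maximum(n, 1), np.nan)
        dev = np.where(finite, M - mean, 0.0)
        var = np.where(n > 1, (dev**2).sum(axis=0) / np.maximum(n - 1, 1), np.nan)
        t = mean / np.sqrt(var / n)
    t[n < 2] = np.nan
    t[var == 0] = np.nan
    return BrainMap(data=t, voxel_size_mm=stack.voxel_size_mm, space="shared")


_CONNECTIVITY_STRUCTURE = {6: 1, 18: 2, 26: 3}


def _label_clusters(supra: np.ndarray, connectivity: int) -> Tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCTURE[connectivity])
    return ndimage.label(supra, structure=structure)


def _max_cluster_sum(t: np.ndarray, t_crit: float, connectivity: int) -> float:
    supra = t > t_crit
    if not supra.any():
        return 0.0
    labels, n = _label_clusters(supra, connectivity)
    sums = ndimage.sum_labels(t, labels, index=np.arange(1, n + 1))
    return float(sums.max())


@dataclass
class ClusterResult:
    """Observed t map, cluster labels/statistics and permutation p-values."""

    t_map: BrainMap
    cluster_labels: np.ndarray  # int volume, 0 = background
    cluster_sizes: np.ndarray
    cluster_sums: np.ndarray  # sum of t per cluster
    p_values: np.ndarray
    initial_p: float
    n_perm: int
    connectivity: int
    seed: int
    alpha: float = 0.05
    null_max_sums: Optional[np.ndarray] = None

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sums)

    def significant(self) -> np.ndarray:
        """Boolean flag per cluster at the alpha level."""
        return self.p_values < self.alpha

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": np.arange(1, self.n_clusters + 1),
                "size": self.cluster_sizes,
                "sum_t": self.cluster_sums,
                "p": self.p_values,
                "significant": self.significant(),
            }
        )

    def summary(self) -> str:
        head = (
            f"Cluster permutation test (max-sum), initial p < {self.initial_p}, "
            f"{self.n_perm} permutations, {self.connectivity}-connectivity, seed {self.seed}"
        )
        if self.n_clusters == 0:
            return head + "\n  no supra-threshold clusters"
        return head + "\n" + self.table().to_string(index=False)

    def save(self, prefix: str | Path) -> None:
        """Write t-map and labels as NIfTI, cluster table as TSV, run record as JSON."""
        prefix = Path(prefix)
        self.t_map.to_nifti(prefix.with_name(prefix.name + "_tmap.nii.gz"))
        BrainMap(
            data=self.cluster_labels.astype(float), voxel_size_mm=self.t_map.voxel_size_mm, space="shared"
        ).to_nifti(prefix.with_name(prefix.name + "_clusters.nii.gz"))
        self.table().to_csv(prefix.with_name(prefix.name + "_clusters.tsv"), sep="\t", index=False)
        record = {
            "initial_p": self.initial_p,
            "n_perm": self.n_perm,
            "connectivity": self.connectivity,
            "seed": self.seed,
            "alpha": self.alpha,
            "n_clusters": int(self.n_clusters),
        }
        prefix.with_name(prefix.name + "_run.json").write_text(json.dumps(record, indent=2))


def cluster_permutation(
    stack: MapStack,
    initial_p: float = 0.001,
    n_perm: int = 10_000,
    seed: int = 0,
    connectivity: int = 26,
    alpha: float = 0.05,
) -> ClusterResult:
    """Max-sum cluster-based Monte Carlo permutation test on a map stack.

    The one-tailed initial threshold is applied on the right tail of the t
    distribution with n-1 degrees of freedom (positive model correlations
    are the hypothesis).  The null distribution is built from `n_perm`
    random sign flips of whole subject maps; cluster p-values use the
    never-zero estimator (1 + #{null >= observed}) / (1 + n_perm).

    Cluster inference is restricted to voxels finite in every subject.
    """
    if stack.n_subjects < 2:
        raise InsufficientDataError("need at least 2 subjects")
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    if not 0.0 < initial_p < 0.5:
        raise ConfigurationError("initial_p must be in (0, 0.5)")
    if connectivity not in _CONNECTIVITY_STRUCTURE:
        raise ConfigurationError("connectivity must be one of 6, 18, 26")

    S = stack.n_subjects
    shape = stack.maps.shape[1:]
    complete = np.isfinite(stack.maps).all(axis=0)
    M = stack.maps[:, complete]  # (S, V) complete voxels only
    t_crit = float(stats.t.isf(initial_p, df=S - 1))

    # observed t (full map, NaN-aware) and its complete-voxel version
    t_full = group_t_map(stack).data
    t_obs = np.full(shape, -np.inf)
    with np.errstate(invalid="ignore"):
        mean = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        tv = np.where(sd > 0, mean / (sd / np.sqrt(S)), np.nan)
    t_obs[complete] = np.where(np.isfinite(tv), tv, -np.inf)

    supra = t_obs > t_crit
    labels, n_clusters = _label_clusters(supra, connectivity)
    if n_clusters:
        sizes = ndimage.sum_labels(np.ones(shape), labels, index=np.arange(1, n_clusters + 1))
        sums = ndimage.sum_labels(np.where(supra, t_obs, 0.0), labels, index=np.arange(1, n_clusters + 1))
    else:
        sizes = np.array([])
        sums = np.array([])

    # permutation null: sign flips of whole subject maps; only voxel means
    # change under a flip, squared values are flip-invariant
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, S))
    sumsq = (M**2).sum(axis=0)
    null_max = np.empty(n_perm)
    t_vol = np.zeros(shape)
    for p in range(n_perm):
        m = flips[p] @ M / S
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (sumsq - S * m**2) / (S - 1)
            tp = np.where(var > 0, m / np.sqrt(var / S), -np.inf)
        t_vol[...] = -np.inf
        t_vol[complete] = tp
        null_max[p] = _max_cluster_sum(t_vol, t_crit, connectivity)

    p_values = np.array(
        [(1 + np.sum(null_max >= s)) / (1 + n_perm) for s in sums]
    )
    return ClusterResult(
        t_map=BrainMap(data=t_full, voxel_size_mm=stack.voxel_size_mm, space="shared"),
        cluster_labels=labels,
        cluster_sizes=sizes.astype(int) if n_clusters else np.array([], dtype=int),
        cluster_sums=sums,
        p_values=p_values,
        initial_p=initial_p,
        n_perm=n_perm,
        connectivity=connectivity,
        seed=seed,
        alpha=alpha,
        null_max_sums=null_max,
    )


class GroupClusterTest:
    """Model object: group inference over a stack of subject z-maps.

    ``fit(seed)`` runs the voxel-wise one-tailed t test and the max-sum
    cluster permutation correction, returning a :class:`ClusterResult`.
    """

    def __init__(
        self,
        stack: MapStack,
        initial_p: float = 0.001,
        n_perm: int = 10_000,
        connectivity: int = 26,
        alpha: float = 0.05,
    ) -> None:
        self.stack = stack
        self.initial_p = initial_p
        self.n_perm = n_perm
        self.connectivity = connectivity
        self.alpha = alpha

    def fit(self, seed: int = 0) -> ClusterResult:
        return cluster_permutation(
            self.stack,
            initial_p=self.initial_p,
            n_perm=self.n_perm,
            seed=seed,
            connectivity=self.connectivity,
            alpha=self.alpha,
        )
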