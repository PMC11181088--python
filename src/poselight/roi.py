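"""ROI-level RSA and the simulation-based noise-ceiling estimator.

ROI RSA runs the standard pipeline (average repeats, z-score voxels,
1 - correlation, triangle Pearson against model RDMs) over all voxels of a
region, optionally after selecting voxels by a localizer t threshold.

The noise ceiling answers: given the trial-to-trial noise in this ROI, how
well could a perfect model correlate with the measured RDM?  For two-repeat
designs it is estimated by modelling observed responses as the sum of a
multivariate Gaussian signal (per image) and Gaussian noise (per trial).
The noise covariance comes from scaled repeat differences, the signal
covariance from per-image means, and the signal distribution is rescaled
post hoc so that simulated split-half reliability matches the empirically
observed reliability of similarity matrices across independent splits.
Monte Carlo simulations then correlate a noiseless similarity matrix (from
signal draws) with similarity matrices built from simulated noisy
measurements; the mean over simulations is the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    CollinearityError,
    ConfigurationError,
    ContractError,
    EmptyROIError,
    InsufficientDataError,
)
from .rdm import RDM, lower_triangle, normalize_rdm
from .rsa import NeuralDataset, fisher_z, neural_rdm, partial_rsa, prepare_patterns, rsa_correlation

__all__ = [
    "RoiDataset",
    "NoiseCeilingEstimate",
    "select_voxels_by_t",
    "roi_rsa",
    "estimate_noise_ceiling",
    "RoiRSA",
    "NoiseCeiling",
]


@dataclass
class RoiDataset:
    """Trial x voxel responses restricted to one ROI."""

    roi: str
    betas: np.ndarray
    trial_image_ids: List[str]
    localizer_t: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.trial_image_ids = [str(i) for i in self.trial_image_ids]
        if self.betas.ndim != 2:
            raise ConfigurationError(f"betas must be trials x voxels, got {self.betas.shape}")
        if self.betas.shape[1] < 1:
            raise InsufficientDataError("ROI needs at least 1 voxel")
        if len(self.trial_image_ids) != self.betas.shape[0]:
            raise ConfigurationError("trial_image_ids length does not match betas")
        if self.localizer_t is not None:
            self.localizer_t = np.asarray(self.localizer_t, dtype=float)
            if self.localizer_t.shape != (self.betas.shape[1],):
                raise ConfigurationError("localizer_t must have one value per voxel")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def distinct_image_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for i in self.trial_image_ids:
            seen.setdefault(i, None)
        return list(seen)

    def to_neural_dataset(self) -> NeuralDataset:
        """View the ROI as a NeuralDataset on a trivial 1 x 1 x V grid."""
        V = self.n_voxels
        mask = np.ones((1, 1, V), dtype=bool)
        idx = np.column_stack([np.zeros(V, int), np.zeros(V, int), np.arange(V)])
        return NeuralDataset(
            betas=self.betas,
            trial_image_ids=self.trial_image_ids,
            voxel_index=idx,
            voxel_size_mm=1.0,
            mask=mask,
        )

    # ----------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.betas, columns=[f"v{i}" for i in range(self.n_voxels)])
        df.insert(0, "image_id", self.trial_image_ids)
        df.to_csv(path, sep="\t", index=False)
        if self.localizer_t is not None:
            pd.DataFrame({"voxel": np.arange(self.n_voxels), "t": self.localizer_t}).to_csv(
                Path(path).with_suffix(".localizer.tsv"), sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, path: str | Path, roi: str = "") -> "RoiDataset":
        df = pd.read_csv(path, sep="\t", dtype={"image_id": str})
        ids = df["image_id"].tolist()
        betas = df.drop(columns=["image_id"]).to_numpy(dtype=float)
        loc = Path(path).with_suffix(".localizer.tsv")
        t = pd.read_csv(loc, sep="\t")["t"].to_numpy() if loc.exists() else None
        return cls(roi=roi or Path(path).stem, betas=betas, trial_image_ids=ids, localizer_t=t)


def select_voxels_by_t(dataset: RoiDataset, threshold: float) -> RoiDataset:
    """Keep voxels with localizer t strictly greater than the threshold."""
    if dataset.localizer_t is None:
        raise ConfigurationError(f"ROI {dataset.roi!r} has no localizer t-values")
    keep = dataset.localizer_t > threshold
    if not keep.any():
        raise EmptyROIError(
            f"no voxels with t > {threshold} in ROI {dataset.roi!r} (max t = {dataset.localizer_t.max():.3g})"
        )
    return RoiDataset(
        roi=dataset.roi,
        betas=dataset.betas[:, keep],
        trial_image_ids=list(dataset.trial_image_ids),
        localizer_t=dataset.localizer_t[keep],
    )


def _subset_and_renormalize(model: RDM, item_ids: Sequence[str]) -> RDM:
    """Model RDMs are renormalized on each subject's image subset.

    Min-max normalization is affine on the off-diagonal, so this leaves
    Pearson/partial correlations unchanged when the subset is the full set,
    while putting every subject's models on the [0, 1] scale.
    """
    return normalize_rdm(model.subset(item_ids))


def roi_rsa(dataset: RoiDataset, target: RDM, controls: Sequence[RDM] = ()) -> float:
    """Standard or partial RSA between the ROI's neural RDM and a model RDM."""
    prepared = prepare_patterns(dataset.to_neural_dataset())
    nrdm = neural_rdm(prepared)
    ids = nrdm.item_ids
    target = _subset_and_renormalize(target, ids)
    controls = [_subset_and_renormalize(c, ids) for c in controls]
    if controls:
        return partial_rsa(nrdm, target, controls)
    return rsa_correlation(nrdm, target)


# ----------------------------------------------------------- noise ceiling

def _similarity_matrix(patterns: np.ndarray) -> np.ndarray:
    """Item x item similarity (Pearson over voxels) after voxel z-scoring.

    Mirrors the measurement pipeline: z-score each voxel across items, then
    correlate item patterns; similarity = correlation (= 1 - the RDM).
    """
    sd = patterns.std(axis=0, ddof=1)
    ok = sd > 0
    Z = (patterns[:, ok] - patterns[:, ok].mean(axis=0)) / sd[ok]
    return np.corrcoef(Z)


def _split_pairs(dataset: RoiDataset) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """First and second presentation per image, erroring on any other design."""
    ids = dataset.distinct_image_ids()
    trial_ids = np.asarray(dataset.trial_image_ids)
    bad = [i for i in ids if (trial_ids == i).sum() != 2]
    if bad:
        raise ContractError(
            f"noise ceiling requires exactly 2 trials per image; violated by: {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    first = np.stack([dataset.betas[trial_ids == i][0] for i in ids])
    second = np.stack([dataset.betas[trial_ids == i][1] for i in ids])
    return ids, first, second


def _psd_factor(cov: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Eigen square root with negative eigenvalues floored at zero."""
    w, U = np.linalg.eigh((cov + cov.T) / 2.0)
    repaired = bool((w < -1e-10 * max(abs(w).max(), 1e-30)).any())
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w), repaired


@dataclass
class NoiseCeilingEstimate:
    """Monte-Carlo noise ceiling for one ROI and subject."""

    ceiling: float
    per_simulation: np.ndarray
    n_simulations: int
    seed: int
    signal_scale: float
    empirical_reliability: float
    simulated_reliability: float
    covariance_repaired: bool = False

    def summary(self) -> str:
        se = self.per_simulation.std(ddof=1) / np.sqrt(len(self.per_simulation))
        return (
            f"Noise ceiling: {self.ceiling:.4f} (MC se {se:.4f}, {self.n_simulations} simulations)\n"
            f"  signal scale       : {self.signal_scale:.4f}\n"
            f"  split-half rel.    : empirical {self.empirical_reliability:.4f}, "
            f"simulated {self.simulated_reliability:.4f}\n"
            f"  seed               : {self.seed}"
        )


def _simulate_reliability(
    Ls: np.ndarray, Ln: np.ndarray, scale: float, zs: np.ndarray, zn1: np.ndarray, zn2: np.ndarray
) -> float:
    """Mean split-half RSM reliability over pre-drawn standard normals."""
    tri = None
    vals = []
    for k in range(zs.shape[0]):
        sig = zs[k] @ (np.sqrt(scale) * Ls).T
        h1 = _similarity_matrix(sig + zn1[k] @ Ln.T)
        h2 = _similarity_matrix(sig + zn2[k] @ Ln.T)
        i, j = np.tril_indices(h1.shape[0], -1)
        vals.append(np.corrcoef(h1[i, j], h2[i, j])[0, 1])
    return float(np.mean(vals))


def estimate_noise_ceiling(
    dataset: RoiDataset,
    n_sim: int = 1000,
    seed: int = 0,
    n_calibration: int = 50,
    tol: float = 1e-3,
) -> NoiseCeilingEstimate:
    """Noise ceiling for a two-repeat ROI dataset.

    Procedure:

    1. noise covariance = covariance of (trial1 - trial2) / sqrt(2) across
       images (repeat differences cancel the signal; the scaling makes the
       estimator consistent for the per-trial noise covariance);
    2. signal covariance = covariance of per-image trial means minus half
       the noise covariance, eigenvalue-floored at zero;
    3. a scalar on the signal covariance is calibrated by bisection (to
       `tol`) so simulated split-half similarity-matrix reliability matches
       the empirical split-half reliability of the two repeats;
    4. each simulation draws item signals and two noisy repeats, builds the
       noiseless similarity matrix from the signals and the noisy one from
       averaged simulated measurements (same averaging/z-scoring pipeline as
       the real data), and records their triangle Pearson correlation;
    5. the ceiling is the mean over `n_sim` simulations.
    """
    ids, first, second = _split_pairs(dataset)
    n_items = len(ids)
    if n_items < 5:
        raise InsufficientDataError(f"noise ceiling needs >= 5 images, got {n_items}")
    rng = np.random.default_rng(seed)

    noise_cov = np.cov((first - second) / np.sqrt(2.0), rowvar=False)
    mean_cov = np.cov((first + second) / 2.0, rowvar=False)
    signal_cov = mean_cov - noise_cov / 2.0
    Ls, repaired = _psd_factor(signal_cov)
    Ln, _ = _psd_factor(noise_cov)
    V = dataset.n_voxels

    # empirical split-half reliability of similarity matrices
    i, j = np.tril_indices(n_items, -1)
    s1 = _similarity_matrix(first)
    s2 = _similarity_matrix(second)
    emp_rel = float(np.corrcoef(s1[i, j], s2[i, j])[0, 1])

    # calibrate the signal scale by bisection with common random numbers
    zs = rng.normal(size=(n_calibration, n_items, V))
    zn1 = rng.normal(size=(n_calibration, n_items, V))
    zn2 = rng.normal(size=(n_calibration, n_items, V))
    lo, hi = 0.0, 1.0
    while (
        _simulate_reliability(Ls, Ln, hi, zs, zn1, zn2) < emp_rel and hi < 1024
    ):
        hi *= 2.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if hi - lo < tol:
            break
        if _simulate_reliability(Ls, Ln, mid, zs, zn1, zn2) < emp_rel:
            lo = mid
        else:
            hi = mid
    scale = (lo + hi) / 2.0
    sim_rel = _simulate_reliability(Ls, Ln, scale, zs, zn1, zn2)

    # Monte Carlo ceiling
    Lss = np.sqrt(scale) * Ls
    per_sim = np.empty(n_sim)
    for k in range(n_sim):
        sig = rng.normal(size=(n_items, V)) @ Lss.T
        noiseless = _similarity_matrix(sig)
        rep1 = sig + rng.normal(size=(n_items, V)) @ Ln.T
        rep2 = sig + rng.normal(size=(n_items, V)) @ Ln.T
        noisy = _similarity_matrix((rep1 + rep2) / 2.0)
        per_sim[k] = np.corrcoef(noiseless[i, j], noisy[i, j])[0, 1]
    return NoiseCeilingEstimate(
        ceiling=float(per_sim.mean()),
        per_simulation=per_sim,
        n_simulations=n_sim,
        seed=seed,
        signal_scale=float(scale),
        empirical_reliability=emp_rel,
        simulated_reliability=sim_rel,
        covariance_repaired=repaired,
    )


# ------------------------------------------------------------ model shells

class RoiRSA:
    """Model object: RSA of one or several model RDMs within an ROI."""

    def __init__(
        self,
        dataset: RoiDataset,
        targets: Sequence[RDM],
        controls: Sequence[RDM] = (),
    ) -> None:
        self.dataset = dataset
        self.targets = list(targets)
        self.controls = list(controls)

    def fit(self) -> "RoiRSAResult":
        rows = []
        for target in self.targets:
            r = roi_rsa(self.dataset, target, self.controls)
            rows.append(
                {
                    "roi": self.dataset.roi,
                    "model": target.model,
                    "r": r,
                    "fisher_z": fisher_z(r),
                    "controls": ",".join(c.model for c in self.controls),
                }
            )
        return RoiRSAResult(table_=pd.DataFrame(rows))


@dataclass
class RoiRSAResult:
    table_: pd.DataFrame

    def table(self) -> pd.DataFrame:
        return self.table_.copy()

    def summary(self) -> str:
        return "ROI RSA\n" + self.table_.to_string(index=False)

    def plot(self, ax=None):
        """Bar plot of model correlations in this ROI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.table_["model"], self.table_["r"])
        ax.set_ylabel("RDM correlation (r)")
        ax.set_title(self.table_["roi"].iloc[0] if len(self.table_) else "ROI RSA")
        ax.tick_params(axis="x", rotation=45)
        return ax


class NoiseCeiling:
    """Model object: Monte-Carlo noise ceiling of a two-repeat ROI dataset."""

    def __init__(self, dataset: RoiDataset, n_sim: int = 1000) -> None:
        self.dataset = dataset
        self.n_sim = n_sim

    def fit(self, seed: int = 0) -> NoiseCeilingEstimate:
        return estimate_noise_ceiling(self.dataset, n_sim=self.n_sim, seed=seed)
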