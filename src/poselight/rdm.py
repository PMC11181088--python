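"""Representational dissimilarity matrices (RDMs).

An RDM is a symmetric nonnegative matrix of pairwise dissimilarities between
stimuli, keyed by image identifiers.  Model RDMs are min-max normalized to
[0, 1] over the off-diagonal before entering any correlation analysis, so
every model contributes on the same scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateRDMError, InvalidInputError, ShapeError

__all__ = ["RDM", "normalize_rdm", "lower_triangle"]

_SYM_TOL = 1e-9


def lower_triangle(values: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle vectorization used throughout for RDM comparison."""
    i, j = np.tril_indices(values.shape[0], -1)
    return values[i, j]


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with ordered item identifiers.

    Parameters
    ----------
    item_ids : ordered stimulus identifiers; must be unique.
    values : square symmetric matrix, nonnegative, zero diagonal.
    model : name of the generating model (metadata).
    normalized : whether off-diagonal entries were min-max mapped to [0, 1].
    extra : free-form metadata carried to the JSON sidecar on save.
    """

    item_ids: List[str]
    values: np.ndarray
    model: str = ""
    normalized: bool = False
    extra: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.item_ids = [str(i) for i in self.item_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if len(set(self.item_ids)) != n:
            raise InvalidInputError("duplicate item_ids in RDM")
        if self.values.shape != (n, n):
            raise ShapeError(
                f"RDM values shape {self.values.shape} does not match {n} item_ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("RDM contains non-finite values")
        if np.abs(self.values - self.values.T).max() > _SYM_TOL:
            raise InvalidInputError("RDM is not symmetric within 1e-9")
        # exact symmetry and zero diagonal from here on
        self.values = (self.values + self.values.T) / 2.0
        if np.abs(np.diag(self.values)).max() > _SYM_TOL:
            raise InvalidInputError("RDM diagonal is not zero")
        np.fill_diagonal(self.values, 0.0)
        if self.values.min() < -_SYM_TOL:
            raise InvalidInputError("RDM has negative dissimilarities")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def triangle(self) -> np.ndarray:
        """Strictly-lower-triangle vector of the dissimilarities."""
        return lower_triangle(self.values)

    def subset(self, item_ids: Sequence[str]) -> "RDM":
        """RDM restricted (and reordered) to the given item ids."""
        item_ids = [str(i) for i in item_ids]
        missing = [i for i in item_ids if i not in set(self.item_ids)]
        if missing:
            raise AlignmentError(f"item_ids missing from RDM: {missing}")
        idx = [self.item_ids.index(i) for i in item_ids]
        return RDM(
            item_ids=list(item_ids),
            values=self.values[np.ix_(idx, idx)],
            model=self.model,
            normalized=self.normalized,
            extra=dict(self.extra),
        )

    def aligned_values(self, item_ids: Sequence[str]) -> np.ndarray:
        return self.subset(item_ids).values

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV (header row of item_ids, square numeric body) + JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.values, index=self.item_ids, columns=self.item_ids)
        df.to_csv(path, sep="\t", index_label="item_id")
        sidecar = {
            "model": self.model,
            "normalized": self.normalized,
            "n_items": self.n_items,
            **self.extra,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RDM":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta: Dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            item_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            model=str(meta.get("model", "")),
            normalized=bool(meta.get("normalized", False)),
            extra={k: v for k, v in meta.items() if k not in ("model", "normalized", "n_items")},
        )


def normalize_rdm(rdm: RDM) -> RDM:
    """Min-max map off-diagonal dissimilarities to [0, 1].

    ``x' = (x - min) / (max - min)`` with min/max taken over the off-diagonal
    only; the diagonal stays zero.  A constant off-diagonal makes the mapping
    undefined and raises :class:`DegenerateRDMError` rather than silently
    producing NaN.
    """
    off = rdm.triangle()
    lo, hi = float(off.min()), float(off.max())
    if hi - lo <= 0.0:
        raise DegenerateRDMError(
            f"RDM '{rdm.model}' has constant off-diagonal ({lo}); cannot normalize"
        )
    vals = (rdm.values - lo) / (hi - lo)
    np.fill_diagonal(vals, 0.0)
    return RDM(
        item_ids=list(rdm.item_ids),
        values=vals,
        model=rdm.model,
        normalized=True,
        extra=dict(rdm.extra),
    )
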