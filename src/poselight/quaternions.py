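"""Unit quaternions for 3D rotations and rotation-distance metrics.

A rotation of angle theta about unit axis n is represented as
``q = (cos(theta/2), n*sin(theta/2))`` stored in (w, x, y, z) order.  Since
q and -q encode the same rotation (the double cover of SO(3)), quaternions
are canonicalized to w >= 0 (and, at w == 0, first nonzero component
positive) so serialization is deterministic.

The dissimilarity between two rotations is the geodesic half-angle
``arccos(|q1 . q2|)``, which is invariant to sign flips of either argument
and bounded by pi/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, ShapeError

__all__ = [
    "UnitQuaternion",
    "rotation_matrix_to_quaternion",
    "quaternion_to_rotation_matrix",
    "viewpoint_distance",
    "joint_rotation_distance",
    "random_rotation_matrix",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion in (w, x, y, z) order, canonical sign w >= 0."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        v = np.array([self.w, self.x, self.y, self.z], dtype=float)
        norm = np.linalg.norm(v)
        if abs(norm - 1.0) > _UNIT_TOL:
            raise InvalidInputError(
                f"quaternion norm {norm:.8g} deviates from 1 by more than {_UNIT_TOL}"
            )
        v = v / norm
        v = _canonical_sign(v)
        object.__setattr__(self, "w", float(v[0]))
        object.__setattr__(self, "x", float(v[1]))
        object.__setattr__(self, "y", float(v[2]))
        object.__setattr__(self, "z", float(v[3]))

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "UnitQuaternion":
        v = np.asarray(v, dtype=float)
        if v.shape != (4,):
            raise ShapeError(f"quaternion needs 4 components, got shape {v.shape}")
        return cls(*v)

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    def dot(self, other: "UnitQuaternion") -> float:
        return float(self.as_array() @ other.as_array())


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip sign so w >= 0; if w == 0, make the first nonzero component positive."""
    for c in v:
        if c > 0:
            return v.copy()
        if c < 0:
            return -v
    raise InvalidInputError("zero quaternion has no canonical sign")


def _check_rotation_matrix(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ShapeError(f"rotation matrix must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InvalidInputError("rotation matrix contains non-finite entries")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > tol:
        raise InvalidInputError(
            f"matrix is not orthonormal: max |R'R - I| = {err:.3g} > {tol}"
        )
    det = np.linalg.det(R)
    if abs(det - 1.0) > tol:
        raise InvalidInputError(f"matrix determinant {det:.8g} != +1 (improper rotation)")
    return R


def rotation_matrix_to_quaternion(R: np.ndarray) -> UnitQuaternion:
    """Convert a proper rotation matrix to its canonical unit quaternion.

    Uses Shepperd's numerically stable branch selection: pick the largest of
    the four squared components from the trace pattern, then fill in the rest
    from off-diagonal differences.
    """
    R = _check_rotation_matrix(R)
    tr = np.trace(R)
    # candidates for the largest component, 4*c^2 for c in (w, x, y, z)
    four_sq = np.array(
        [
            1.0 + tr,
            1.0 + R[0, 0] - R[1, 1] - R[2, 2],
            1.0 - R[0, 0] + R[1, 1] - R[2, 2],
            1.0 - R[0, 0] - R[1, 1] + R[2, 2],
        ]
    )
    i = int(np.argmax(four_sq))
    s = np.sqrt(max(four_sq[i], 0.0)) / 2.0
    if i == 0:
        w = s
        x = (R[2, 1] - R[1, 2]) / (4 * s)
        y = (R[0, 2] - R[2, 0]) / (4 * s)
        z = (R[1, 0] - R[0, 1]) / (4 * s)
    elif i == 1:
        x = s
        w = (R[2, 1] - R[1, 2]) / (4 * s)
        y = (R[0, 1] + R[1, 0]) / (4 * s)
        z = (R[0, 2] + R[2, 0]) / (4 * s)
    elif i == 2:
        y = s
        w = (R[0, 2] - R[2, 0]) / (4 * s)
        x = (R[0, 1] + R[1, 0]) / (4 * s)
        z = (R[1, 2] + R[2, 1]) / (4 * s)
    else:
        z = s
        w = (R[1, 0] - R[0, 1]) / (4 * s)
        x = (R[0, 2] + R[2, 0]) / (4 * s)
        y = (R[1, 2] + R[2, 1]) / (4 * s)
    v = np.array([w, x, y, z])
    return UnitQuaternion.from_array(v / np.linalg.norm(v))


def quaternion_to_rotation_matrix(q: UnitQuaternion) -> np.ndarray:
    """Inverse of :func:`rotation_matrix_to_quaternion`."""
    w, x, y, z = q.w, q.x, q.y, q.z
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def viewpoint_distance(qa: UnitQuaternion, qb: UnitQuaternion) -> float:
    """Rotation dissimilarity ``arccos(|qa . qb|)`` in [0, pi/2].

    The absolute dot product makes the metric well defined under the
    quaternion double cover: q and -q give identical distances.
    """
    if not isinstance(qa, UnitQuaternion) or not isinstance(qb, UnitQuaternion):
        qa = UnitQuaternion.from_array(np.asarray(qa, dtype=float))  # validates norm
        qb = UnitQuaternion.from_array(np.asarray(qb, dtype=float))
    d = abs(qa.dot(qb))
    return float(np.arccos(np.clip(d, -1.0, 1.0)))


def joint_rotation_distance(
    Qa: Sequence[UnitQuaternion], Qb: Sequence[UnitQuaternion]
) -> float:
    """Mean per-joint rotation distance between two equally long quaternion lists."""
    Qa = list(Qa)
    Qb = list(Qb)
    if len(Qa) != len(Qb):
        raise ShapeError(f"joint counts differ: {len(Qa)} vs {len(Qb)}")
    if not Qa:
        raise ShapeError("empty joint rotation lists")
    return float(np.mean([viewpoint_distance(a, b) for a, b in zip(Qa, Qb)]))


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalized 4D Gaussian quaternion."""
    v = rng.normal(size=4)
    v /= np.linalg.norm(v)
    return quaternion_to_rotation_matrix(UnitQuaternion.from_array(v))


def quaternions_close(qa: UnitQuaternion, qb: UnitQuaternion, tol: float = 1e-9) -> bool:
    """Whether two quaternions encode the same rotation within tolerance."""
    return viewpoint_distance(qa, qb) <= tol
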