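"""Body-pose parameterizations and pose-model RDMs.

A pose is a list of K=19 labeled 3D joint locations together with a global
body rotation R (and, optionally, per-joint rotations as unit quaternions).
Four representations are derived from it:

- view-dependent 3D: the raw joint coordinates;
- view-dependent 2D: the same joints with the depth coordinate dropped
  (orthographic projection);
- view-independent 3D: joints after undoing the global rotation,
  ``J_vi = R^-1 J``, so two poses differing only in viewpoint coincide;
- viewpoint: the global rotation itself, as a unit quaternion.

Pose dissimilarity is the mean per-joint position error (MPJPE): the mean
over joints of the Euclidean distance between corresponding joints.
Viewpoint dissimilarity is the quaternion geodesic distance; a fifth,
control representation measures per-joint rotation distances.  No
additional normalization (centering/scaling) is applied to the joint
coordinates beyond the R^-1 alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InvalidInputError,
    ParseError,
    ShapeError,
)
from .quaternions import (
    UnitQuaternion,
    rotation_matrix_to_quaternion,
    joint_rotation_distance,
    viewpoint_distance,
)
from .rdm import RDM

__all__ = [
    "JOINT_NAMES",
    "POSE_MODELS",
    "PoseRecord",
    "project_to_2d",
    "align_view_independent",
    "mean_per_joint_distance",
    "build_model_rdm",
    "load_poses_json",
    "save_poses_json",
    "load_poses_csv",
    "save_poses_csv",
]

#: Canonical joint order; input files may list joints in any order but are
#: re-sorted to this order on load.
JOINT_NAMES: List[str] = [
    "left_ankle",
    "right_ankle",
    "left_knee",
    "right_knee",
    "left_hip",
    "right_hip",
    "left_wrist",
    "right_wrist",
    "left_elbow",
    "right_elbow",
    "left_shoulder",
    "right_shoulder",
    "neck",
    "head",
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
]

N_JOINTS = len(JOINT_NAMES)  # K = 19

POSE_MODELS = (
    "view_dep_3d",
    "view_dep_2d",
    "view_indep_3d",
    "viewpoint",
    "joint_rotation",
)


@dataclass
class PoseRecord:
    """One image's pose: 19 labeled 3D joints, global rotation, optional joint rotations."""

    image_id: str
    joints3d: np.ndarray  # (19, 3) in canonical joint order
    global_rotation: np.ndarray  # (3, 3) proper rotation
    joint_rotations: Optional[List[UnitQuaternion]] = None

    def __post_init__(self) -> None:
        self.image_id = str(self.image_id)
        self.joints3d = np.asarray(self.joints3d, dtype=float)
        if self.joints3d.shape != (N_JOINTS, 3):
            raise ShapeError(
                f"pose {self.image_id!r}: joints3d shape {self.joints3d.shape} != ({N_JOINTS}, 3)"
            )
        if not np.all(np.isfinite(self.joints3d)):
            raise InvalidInputError(f"pose {self.image_id!r}: non-finite joint coordinates")
        R = np.asarray(self.global_rotation, dtype=float)
        if R.shape != (3, 3):
            raise ShapeError(f"pose {self.image_id!r}: global_rotation shape {R.shape} != (3, 3)")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6 or abs(np.linalg.det(R) - 1) > 1e-6:
            raise InvalidInputError(
                f"pose {self.image_id!r}: global_rotation is not a proper rotation matrix"
            )
        self.global_rotation = R
        if self.joint_rotations is not None:
            if len(self.joint_rotations) != N_JOINTS:
                raise ShapeError(
                    f"pose {self.image_id!r}: {len(self.joint_rotations)} joint rotations != {N_JOINTS}"
                )
            self.joint_rotations = [
                q if isinstance(q, UnitQuaternion) else UnitQuaternion.from_array(q)
                for q in self.joint_rotations
            ]

    def viewpoint_quaternion(self) -> UnitQuaternion:
        return rotation_matrix_to_quaternion(self.global_rotation)


def project_to_2d(pose: PoseRecord) -> np.ndarray:
    """Orthographic projection: drop the depth (third) coordinate of every joint."""
    return pose.joints3d[:, :2].copy()


def align_view_independent(pose: PoseRecord) -> np.ndarray:
    """Undo the global rotation: ``J_vi = R^-1 J`` for every joint."""
    R = pose.global_rotation
    # R is orthonormal (validated), so the inverse is the transpose
    return pose.joints3d @ R  # (J R^-T)^T rows: R^T J_k  == R^-1 J_k


def mean_per_joint_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-joint position error between two K x d joint arrays (d in {2, 3})."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"joint array shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] not in (2, 3):
        raise ShapeError(f"joint arrays must be K x 2 or K x 3, got {a.shape}")
    return float(np.linalg.norm(a - b, axis=1).mean())


def _pairwise_mpjpe(stacks: np.ndarray) -> np.ndarray:
    """All-pairs MPJPE for an (n, K, d) stack of joint arrays."""
    diff = stacks[:, None, :, :] - stacks[None, :, :, :]
    return np.linalg.norm(diff, axis=-1).mean(axis=-1)


def build_model_rdm(poses: Sequence[PoseRecord], model: str) -> RDM:
    """Pairwise-dissimilarity RDM for one of the five pose/viewpoint models.

    The result is unnormalized; item order follows the input order.
    """
    poses = list(poses)
    if model not in POSE_MODELS:
        raise ConfigurationError(f"unknown model {model!r}; choose from {POSE_MODELS}")
    if len(poses) < 2:
        raise InvalidInputError("need at least 2 poses to build an RDM")
    ids = [p.image_id for p in poses]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidInputError(f"duplicate image_ids: {dupes}")
    n = len(poses)

    if model == "view_dep_3d":
        values = _pairwise_mpjpe(np.stack([p.joints3d for p in poses]))
    elif model == "view_dep_2d":
        values = _pairwise_mpjpe(np.stack([project_to_2d(p) for p in poses]))
    elif model == "view_indep_3d":
        values = _pairwise_mpjpe(np.stack([align_view_independent(p) for p in poses]))
    elif model == "viewpoint":
        quats = np.stack([p.viewpoint_quaternion().as_array() for p in poses])
        dots = np.clip(np.abs(quats @ quats.T), -1.0, 1.0)
        values = np.arccos(dots)
        np.fill_diagonal(values, 0.0)
    else:  # joint_rotation
        missing = [p.image_id for p in poses if p.joint_rotations is None]
        if missing:
            raise ConfigurationError(
                f"joint_rotation model requires joint_rotations on all poses; missing: {missing}"
            )
        # (n, K, 4) stack; per-joint arccos |dot|, averaged over joints
        Q = np.stack([[q.as_array() for q in p.joint_rotations] for p in poses])
        dots = np.clip(np.abs(np.einsum("ikc,jkc->ijk", Q, Q)), -1.0, 1.0)
        values = np.arccos(dots).mean(axis=-1)
        np.fill_diagonal(values, 0.0)

    values = (values + values.T) / 2.0
    return RDM(item_ids=ids, values=values, model=model, normalized=False)


# --------------------------------------------------------------------- I/O

def _record_to_obj(pose: PoseRecord) -> Dict:
    obj: Dict = {
        "image_id": pose.image_id,
        "joints3d": {
            name: [float(c) for c in pose.joints3d[k]] for k, name in enumerate(JOINT_NAMES)
        },
        "global_rotation": [float(c) for c in pose.global_rotation.ravel()],
    }
    if pose.joint_rotations is not None:
        obj["joint_rotations"] = {
            name: [q.w, q.x, q.y, q.z]
            for name, q in zip(JOINT_NAMES, pose.joint_rotations)
        }
    return obj


def _record_from_obj(obj: Dict) -> PoseRecord:
    try:
        joints = obj["joints3d"]
        missing = [n for n in JOINT_NAMES if n not in joints]
        if missing:
            raise ParseError(
                f"pose {obj.get('image_id')!r}: missing joints {missing}"
            )
        joints3d = np.array([joints[n] for n in JOINT_NAMES], dtype=float)
        R = np.array(obj["global_rotation"], dtype=float).reshape(3, 3)
        jr = None
        if obj.get("joint_rotations") is not None:
            jr_map = obj["joint_rotations"]
            jr = [UnitQuaternion.from_array(jr_map[n]) for n in JOINT_NAMES]
        return PoseRecord(
            image_id=obj["image_id"], joints3d=joints3d, global_rotation=R, joint_rotations=jr
        )
    except KeyError as e:  # pragma: no cover - defensive
        raise ParseError(f"pose record missing field {e}") from e


def save_poses_json(poses: Sequence[PoseRecord], path: str | Path) -> None:
    Path(path).write_text(json.dumps([_record_to_obj(p) for p in poses], indent=1))


def load_poses_json(path: str | Path) -> List[PoseRecord]:
    return [_record_from_obj(o) for o in json.loads(Path(path).read_text())]


def save_poses_csv(poses: Sequence[PoseRecord], path: str | Path) -> None:
    """Long-format CSV: one row per (image, joint), rotation repeated per row."""
    rows = []
    for p in poses:
        R = p.global_rotation.ravel()
        for k, name in enumerate(JOINT_NAMES):
            row = {
                "image_id": p.image_id,
                "joint": name,
                "x": p.joints3d[k, 0],
                "y": p.joints3d[k, 1],
                "z": p.joints3d[k, 2],
            }
            row.update({f"r{i}{j}": R[3 * i + j] for i in range(3) for j in range(3)})
            if p.joint_rotations is not None:
                q = p.joint_rotations[k]
                row.update({"qw": q.w, "qx": q.x, "qy": q.y, "qz": q.z})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_poses_csv(path: str | Path) -> List[PoseRecord]:
    df = pd.read_csv(path, dtype={"image_id": str})
    has_q = "qw" in df.columns
    poses = []
    for image_id, g in df.groupby("image_id", sort=False):
        g = g.set_index("joint")
        missing = [n for n in JOINT_NAMES if n not in g.index]
        if missing:
            raise ParseError(f"pose {image_id!r}: missing joints {missing}")
        g = g.loc[JOINT_NAMES]
        joints3d = g[["x", "y", "z"]].to_numpy(dtype=float)
        R = g.iloc[0][[f"r{i}{j}" for i in range(3) for j in range(3)]].to_numpy(
            dtype=float
        ).reshape(3, 3)
        jr = None
        if has_q and not g[["qw", "qx", "qy", "qz"]].isna().any().any():
            jr = [
                UnitQuaternion.from_array(v)
                for v in g[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
            ]
        poses.append(
            PoseRecord(image_id=image_id, joints3d=joints3d, global_rotation=R, joint_rotations=jr)
        )
    return poses
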