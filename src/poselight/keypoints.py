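"""Stimulus filtering and control representations from COCO-style keypoints.

The stimulus filter keeps images that contain exactly one annotated person
whose 12 limb keypoints (shoulders, elbows, wrists, hips, knees, ankles on
both sides) all carry a visibility flag other than "not annotated" (flag 0).
Face keypoints are ignored because their annotations are unreliable for
small figures.

Control representations capture body geometry unrelated to pose: the person
bounding-box center in polar coordinates about the image center (angle and
eccentricity) and the relative body size from the segmentation area.
Further controls are distances on externally supplied feature embeddings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateItemError,
    InvalidInputError,
    ParseError,
)
from .rdm import RDM

__all__ = [
    "COCO_KEYPOINT_NAMES",
    "LIMB_KEYPOINT_NAMES",
    "Person",
    "KeypointRecord",
    "BodyGeometry",
    "EmbeddingSet",
    "filter_single_full_person",
    "body_geometry",
    "build_control_rdm",
    "load_coco_json",
    "save_coco_json",
    "load_embeddings_tsv",
    "save_embeddings_tsv",
]

#: The COCO-17 keypoint set, in the standard annotation order.
COCO_KEYPOINT_NAMES: List[str] = [
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
]

#: The 12 limb keypoints whose annotation status defines a "full person".
LIMB_KEYPOINT_NAMES: List[str] = COCO_KEYPOINT_NAMES[5:]

CONTROL_KINDS = (
    "polar_angle",
    "polar_distance",
    "body_size",
    "embedding_euclidean",
    "embedding_one_minus_corr",
)


@dataclass
class Person:
    """One annotated person: 17 keypoints with flags, bbox, segmentation area."""

    keypoints: np.ndarray  # (17, 2) pixel coordinates, x rightward, y downward
    visibility: np.ndarray  # (17,) flags: 0 not annotated, 1 occluded, 2 visible
    bbox: Tuple[float, float, float, float]  # (x, y, width, height)
    segmentation_area: float

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=int)
        if self.keypoints.shape != (17, 2) or self.visibility.shape != (17,):
            raise ParseError(
                f"person must have 17 keypoints, got {self.keypoints.shape}/{self.visibility.shape}"
            )
        if not np.all(np.isin(self.visibility, (0, 1, 2))):
            raise ParseError(f"visibility flags must be 0/1/2, got {set(self.visibility)}")

    def limb_flags(self) -> np.ndarray:
        return self.visibility[5:]


@dataclass
class KeypointRecord:
    """All person annotations of one image."""

    image_id: str
    persons: List[Person]
    image_width: int = 0
    image_height: int = 0

    def __post_init__(self) -> None:
        self.image_id = str(self.image_id)


@dataclass
class BodyGeometry:
    """Body position and size of the single person in one image.

    polar_angle is atan2 of the bbox-center vector about the image center
    (radians in (-pi, pi], 0 by convention at the exact center);
    polar_distance is the pixel eccentricity of the bbox center;
    relative_size is segmentation area divided by image area.
    """

    image_id: str
    polar_angle: float
    polar_distance: float
    relative_size: float

    def __post_init__(self) -> None:
        if not -np.pi < self.polar_angle <= np.pi + 1e-12:
            raise InvalidInputError(f"polar_angle {self.polar_angle} outside (-pi, pi]")
        if self.polar_distance < 0:
            raise InvalidInputError("polar_distance must be nonnegative")
        if not 0.0 <= self.relative_size <= 1.0:
            raise InvalidInputError("relative_size must be within [0, 1]")


@dataclass
class EmbeddingSet:
    """One feature vector per item, uniform dimension (e.g. precomputed
    image or caption embeddings used as low/mid/high-level controls)."""

    item_ids: List[str]
    vectors: np.ndarray  # (n_items, dim)

    def __post_init__(self) -> None:
        self.item_ids = [str(i) for i in self.item_ids]
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.item_ids):
            raise InvalidInputError(
                f"vectors shape {self.vectors.shape} does not match {len(self.item_ids)} items"
            )
        if self.vectors.shape[1] < 1:
            raise InvalidInputError("embedding dimension must be >= 1")
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidInputError("embeddings contain NaN or inf")


def filter_single_full_person(records: Sequence[KeypointRecord]) -> List[str]:
    """IDs of images with exactly one person whose 12 limb keypoints are all annotated.

    A keypoint counts as annotated when its visibility flag is nonzero
    (visible or occluded both qualify).  Input order is preserved.
    """
    selected = []
    for rec in records:
        if len(rec.persons) != 1:
            continue
        if np.all(rec.persons[0].limb_flags() > 0):
            selected.append(rec.image_id)
    return selected


def body_geometry(
    record: KeypointRecord, image_width: float, image_height: float
) -> BodyGeometry:
    """Polar position of the person bbox center and relative body size."""
    if len(record.persons) != 1:
        raise InvalidInputError(
            f"image {record.image_id!r} has {len(record.persons)} persons; expected exactly 1"
        )
    if image_width <= 0 or image_height <= 0:
        raise InvalidInputError("image dimensions must be positive")
    person = record.persons[0]
    x, y, w, h = person.bbox
    cx, cy = x + w / 2.0, y + h / 2.0
    dx, dy = cx - image_width / 2.0, cy - image_height / 2.0
    dist = float(np.hypot(dx, dy))
    angle = 0.0 if dist == 0.0 else float(np.arctan2(dy, dx))
    return BodyGeometry(
        image_id=record.image_id,
        polar_angle=angle,
        polar_distance=dist,
        relative_size=float(person.segmentation_area) / (image_width * image_height),
    )


def _circular_abs_diff(angles: np.ndarray) -> np.ndarray:
    """Pairwise absolute angular difference wrapped to [0, pi]."""
    d = np.abs(angles[:, None] - angles[None, :]) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def build_control_rdm(
    source: Union[Sequence[BodyGeometry], EmbeddingSet], kind: str
) -> RDM:
    """Unnormalized control RDM of the requested kind.

    Geometry kinds take a list of :class:`BodyGeometry`; embedding kinds take
    an :class:`EmbeddingSet`.  ``embedding_euclidean`` operates on unit-L2
    scaled vectors ("normalized embeddings"); ``embedding_one_minus_corr`` is
    1 - Pearson correlation between raw vectors.
    """
    if kind not in CONTROL_KINDS:
        raise ConfigurationError(f"unknown control kind {kind!r}; choose from {CONTROL_KINDS}")

    if kind in ("embedding_euclidean", "embedding_one_minus_corr"):
        if not isinstance(source, EmbeddingSet):
            raise ConfigurationError(f"control kind {kind!r} requires an EmbeddingSet")
        ids = source.item_ids
        if len(ids) < 2:
            raise InvalidInputError("need at least 2 items")
        V = source.vectors
        if kind == "embedding_euclidean":
            norms = np.linalg.norm(V, axis=1, keepdims=True)
            zero = np.where(norms.ravel() == 0)[0]
            if zero.size:
                raise DegenerateItemError(
                    f"zero-norm embedding for items: {[ids[i] for i in zero]}"
                )
            U = V / norms
            diff = U[:, None, :] - U[None, :, :]
            values = np.linalg.norm(diff, axis=-1)
        else:
            sd = V.std(axis=1)
            flat = np.where(sd == 0)[0]
            if flat.size:
                raise DegenerateItemError(
                    f"constant embedding (zero variance) for items: {[ids[i] for i in flat]}"
                )
            values = 1.0 - np.corrcoef(V)
        np.fill_diagonal(values, 0.0)
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        return RDM(item_ids=list(ids), values=values, model=kind, normalized=False)

    geoms = list(source)
    if len(geoms) < 2:
        raise InvalidInputError("need at least 2 items")
    ids = [g.image_id for g in geoms]
    if kind == "polar_angle":
        values = _circular_abs_diff(np.array([g.polar_angle for g in geoms]))
        extra = {"center_angle_convention": "angle 0 at image center"}
    elif kind == "polar_distance":
        x = np.array([g.polar_distance for g in geoms])
        values = np.abs(x[:, None] - x[None, :])
        extra = {"units": "pixels"}
    else:  # body_size
        x = np.array([g.relative_size for g in geoms])
        values = np.abs(x[:, None] - x[None, :])
        extra = {}
    np.fill_diagonal(values, 0.0)
    return RDM(item_ids=ids, values=values, model=kind, normalized=False, extra=extra)


# --------------------------------------------------------------------- I/O

def load_coco_json(path: str | Path) -> List[KeypointRecord]:
    """Read a COCO-dialect annotation file (images / annotations arrays)."""
    obj = json.loads(Path(path).read_text())
    images = {img["id"]: img for img in obj.get("images", [])}
    by_image: Dict[str, List[Person]] = {str(i): [] for i in images}
    for ann in obj.get("annotations", []):
        if ann.get("category_id", 1) != 1:
            continue
        kp = np.array(ann["keypoints"], dtype=float)
        if kp.size != 51:
            raise ParseError(
                f"annotation for image {ann.get('image_id')!r}: keypoints length {kp.size} != 51"
            )
        kp = kp.reshape(17, 3)
        person = Person(
            keypoints=kp[:, :2],
            visibility=kp[:, 2].astype(int),
            bbox=tuple(float(v) for v in ann["bbox"]),
            segmentation_area=float(ann["area"]),
        )
        by_image.setdefault(str(ann["image_id"]), []).append(person)
    records = []
    for img_id, img in images.items():
        records.append(
            KeypointRecord(
                image_id=str(img_id),
                persons=by_image.get(str(img_id), []),
                image_width=int(img.get("width", 0)),
                image_height=int(img.get("height", 0)),
            )
        )
    return records


def save_coco_json(records: Sequence[KeypointRecord], path: str | Path) -> None:
    """Write records back to the COCO-dialect JSON layout."""
    images = []
    annotations = []
    ann_id = 1
    for rec in records:
        images.append(
            {
                "id": rec.image_id,
                "width": rec.image_width,
                "height": rec.image_height,
                "file_name": f"{rec.image_id}.jpg",
            }
        )
        for person in rec.persons:
            flat = np.column_stack([person.keypoints, person.visibility]).ravel()
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": rec.image_id,
                    "category_id": 1,
                    "keypoints": [float(v) for v in flat],
                    "bbox": [float(v) for v in person.bbox],
                    "area": float(person.segmentation_area),
                }
            )
            ann_id += 1
    Path(path).write_text(json.dumps({"images": images, "annotations": annotations}))


def load_embeddings_tsv(path: str | Path) -> EmbeddingSet:
    df = pd.read_csv(path, sep="\t", dtype={"item_id": str})
    ids = df["item_id"].tolist()
    vectors = df.drop(columns=["item_id"]).to_numpy(dtype=float)
    return EmbeddingSet(item_ids=ids, vectors=vectors)


def save_embeddings_tsv(emb: EmbeddingSet, path: str | Path) -> None:
    df = pd.DataFrame(emb.vectors, columns=[f"d{i}" for i in range(emb.vectors.shape[1])])
    df.insert(0, "item_id", emb.item_ids)
    df.to_csv(path, sep="\t", index=False)
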