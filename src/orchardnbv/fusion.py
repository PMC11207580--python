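"""Multi-view fusion: axis-aligned 3D boxes, IoU, greedy 3D NMS, global map.

Each scan contributes fruit detections in the camera frame; these are
transformed to the fixed world frame, pooled with earlier detections, and
reduced by confidence-ordered non-maximum suppression so the global map
keeps the most confident estimate of every physical fruit. Suppression is
pure — boxes are kept or removed, never averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .gaussians import GaussianField
from .geometry import RigidTransform, _as_vec3

DEFAULT_NMS_THRESHOLD = 0.25

CLASS_NAMES = {0: "apple", 1: "orange", 2: "lychee"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned fruit bounding box b(x, y, z, l, h, w).

    ``extents`` = (l, h, w) are the box lengths along the (x, z, y) axes
    respectively, in meters. ``confidence`` in [0, 1]; ``occlusion_pred`` is
    the detector's predicted occlusion ratio, if any.
    """

    center: np.ndarray
    extents: np.ndarray
    confidence: float = 1.0
    occlusion_pred: Optional[float] = None
    class_id: int = 0

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        e = np.asarray(self.extents, dtype=float).reshape(3)
        if np.any(e <= 0):
            raise ValueError("box extents must be positive")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        object.__setattr__(self, "extents", e)

    @property
    def half_sizes_xyz(self) -> np.ndarray:
        """Half-lengths along (x, y, z): (l/2, w/2, h/2)."""
        l, h, w = self.extents
        return np.array([l, w, h]) / 2.0

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))

    def corners_min_max(self):
        h = self.half_sizes_xyz
        return self.center - h, self.center + h

    def to_dict(self) -> dict:
        d = {
            "center": [float(v) for v in self.center],
            "extents_lhw": [float(v) for v in self.extents],
            "confidence": float(self.confidence),
            "class_id": int(self.class_id),
        }
        if self.occlusion_pred is not None:
            d["occlusion_pred"] = float(self.occlusion_pred)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Box3D":
        return cls(
            np.array(d["center"]),
            np.array(d["extents_lhw"]),
            d.get("confidence", 1.0),
            d.get("occlusion_pred"),
            int(d.get("class_id", 0)),
        )


@dataclass(frozen=True)
class FruitEstimate:
    """A fused fruit: position, diameter (mean box extent) and provenance."""

    position: np.ndarray
    diameter: float
    confidence: float = 1.0
    source_views: tuple = ()
    class_id: int = 0

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position))
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def to_dict(self) -> dict:
        return {
            "position": [float(v) for v in self.position],
            "diameter": float(self.diameter),
            "confidence": float(self.confidence),
            "source_views": list(self.source_views),
            "class_id": int(self.class_id),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FruitEstimate":
        return cls(
            np.array(d["position"]), d["diameter"], d.get("confidence", 1.0),
            tuple(d.get("source_views", ())), int(d.get("class_id", 0)),
        )


def box_to_fruit(box: Box3D, view_id: Optional[int] = None) -> FruitEstimate:
    """Read a fruit estimate off a box: center position, mean-extent diameter."""
    views = () if view_id is None else (view_id,)
    return FruitEstimate(
        box.center, float(np.mean(box.extents)), box.confidence, views, box.class_id
    )


def iou3d(a: Box3D, b: Box3D) -> float:
    """Axis-aligned 3D intersection-over-union in [0, 1]."""
    amin, amax = a.corners_min_max()
    bmin, bmax = b.corners_min_max()
    overlap = np.minimum(amax, bmax) - np.maximum(amin, bmin)
    if np.any(overlap <= 0):
        return 0.0
    inter = float(np.prod(overlap))
    return inter / (a.volume + b.volume - inter)


def nms3d(
    boxes: Sequence[Box3D], nms_threshold: float = DEFAULT_NMS_THRESHOLD
) -> list:
    """Greedy per-class 3D NMS, descending confidence.

    A box is removed iff it overlaps an already-kept box of the same class
    with IoU >= ``nms_threshold``. Ties in confidence are broken by input
    order (earlier wins), making the result deterministic; the kept boxes
    are returned in their original input order.
    """
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept_idx: list[int] = []
    for i in order:
        box = boxes[i]
        suppressed = any(
            boxes[j].class_id == box.class_id
            and iou3d(boxes[j], box) >= nms_threshold
            for j in kept_idx
        )
        if not suppressed:
            kept_idx.append(i)
    return [boxes[i] for i in sorted(kept_idx)]


def transform_box(T: RigidTransform, box: Box3D) -> Box3D:
    """Express an axis-aligned box in a new frame.

    The center moves rigidly; since the map stores axis-aligned boxes, the
    rotated box is re-bounded axis-aligned: new half-sizes = |R| @ half-sizes
    (exact for the AABB of the rotated box).
    """
    c = T.apply(box.center)
    h = np.abs(T.rotation) @ box.half_sizes_xyz
    # half_sizes_xyz = (l/2, w/2, h/2) -> extents (l, h, w)
    extents = 2.0 * np.array([h[0], h[2], h[1]])
    return replace(box, center=c, extents=extents)


@dataclass
class GlobalMap:
    """Fused fruit estimates and obstacle Gaussians over all scans so far.

    ``boxes`` keeps the surviving world-frame detections so global NMS can
    be re-run when new scans arrive; ``fruits`` is derived from them.
    """

    fruits: list = field(default_factory=list)
    field_: GaussianField = field(default_factory=lambda: GaussianField([]))
    frame: str = "world"
    boxes: list = field(default_factory=list)
    box_views: list = field(default_factory=list)
    n_scans: int = 0

    def to_dict(self) -> dict:
        return {
            "frame": self.frame,
            "n_scans": int(self.n_scans),
            "fruits": [f.to_dict() for f in self.fruits],
            "boxes": [
                dict(b.to_dict(), view_id=int(v))
                for b, v in zip(self.boxes, self.box_views)
            ],
            "field": self.field_.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalMap":
        boxes = [Box3D.from_dict(b) for b in d.get("boxes", [])]
        views = [int(b.get("view_id", 0)) for b in d.get("boxes", [])]
        return cls(
            fruits=[FruitEstimate.from_dict(f) for f in d.get("fruits", [])],
            field_=GaussianField.from_dict(d["field"]) if "field" in d else GaussianField([]),
            frame=d.get("frame", "world"),
            boxes=boxes,
            box_views=views,
            n_scans=int(d.get("n_scans", 0)),
        )


def update_global_map(
    map_: GlobalMap,
    detections: Sequence[Box3D],
    new_field: GaussianField,
    cam_pose: RigidTransform,
    nms_threshold: float = DEFAULT_NMS_THRESHOLD,
) -> GlobalMap:
    """Fold one scan into the global map.

    Detections (camera frame) and the scan's obstacle Gaussians are
    transformed to the world frame through ``cam_pose`` (camera-to-world),
    pooled with the boxes already in the map, and reduced by global 3D NMS
    so the most confident estimate of each fruit survives. Returns a new
    map; the input map is not mutated.
    """
    view_id = map_.n_scans
    world_dets = [transform_box(cam_pose, b) for b in detections]
    pool = list(map_.boxes) + world_dets
    pool_views = list(map_.box_views) + [view_id] * len(world_dets)

    kept = nms3d(pool, nms_threshold)
    kept_ids = {id(b) for b in kept}
    kept_views = [v for b, v in zip(pool, pool_views) if id(b) in kept_ids]

    fruits = [box_to_fruit(b, v) for b, v in zip(kept, kept_views)]
    merged_field = GaussianField(
        list(map_.field_.gaussians), new_field.voxel_size, map_.field_.origin
    )
    merged_field.extend(new_field.transformed(cam_pose))
    return GlobalMap(
        fruits=fruits,
        field_=merged_field,
        frame=map_.frame,
        boxes=kept,
        box_views=kept_views,
        n_scans=view_id + 1,
    )
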