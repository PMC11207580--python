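"""Ground-truth occlusion ratio and single-view AP/AR evaluation.

The occlusion ratio of a fruit is the fraction of its image-plane area
covered by foreground points: the region-of-interest cloud is voxelized,
voxels sufficiently nearer the camera than the fruit center are marked
foreground, both the fruit's own points and the foreground points are
projected through the pinhole model and rasterized (with a one-pixel
dilation so sparse projections form connected areas), and the ratio is
|fruit ∩ foreground| / |fruit|.

Detection quality is scored by greedy confidence-descending matching at a
3D IoU threshold: AP is the area under the precision envelope of the
precision-recall curve (all-point interpolation) and AR is the maximum
recall attained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .fusion import Box3D, iou3d
from .geometry import CameraModel, ColoredPointCloud, RigidTransform, project_points


@dataclass
class OcclusionScene:
    """Inputs of the ground-truth occlusion-ratio computation.

    ``cloud`` is the ROI point cloud in the world/Lidar frame; ``cam_pose``
    is the camera-to-world pose. ``margin`` (meters) is the depth slack
    separating foreground from the fruit; default half the fruit's mean
    extent.
    """

    cloud: ColoredPointCloud
    fruit: Box3D
    cam: CameraModel
    cam_pose: RigidTransform
    voxel_size: float = 0.02
    margin: Optional[float] = None


def _pixel_mask(cam: CameraModel, pts_cam: np.ndarray) -> np.ndarray:
    """Boolean (H, W) raster of projected points, dilated by one pixel."""
    mask = np.zeros((cam.height, cam.width), dtype=bool)
    if len(pts_cam):
        u, v, _, ok = project_points(cam, pts_cam)
        ui = np.round(u[ok]).astype(int)
        vi = np.round(v[ok]).astype(int)
        inside = (ui >= 0) & (ui < cam.width) & (vi >= 0) & (vi < cam.height)
        mask[vi[inside], ui[inside]] = True
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def occlusion_ratio(scene: OcclusionScene) -> float:
    """Fraction of the fruit's image-plane area hidden by foreground points.

    Raises ``ValueError`` when the fruit projects to an empty footprint
    (no points of the ROI cloud fall inside its box and image).
    """
    world_to_cam = scene.cam_pose.inverse()
    pts_cam = world_to_cam.apply(scene.cloud.positions)
    dist = np.linalg.norm(pts_cam, axis=1)
    fruit_center_cam = world_to_cam.apply(scene.fruit.center)
    fruit_dist = float(np.linalg.norm(fruit_center_cam))
    margin = (
        scene.margin
        if scene.margin is not None
        else 0.5 * float(np.mean(scene.fruit.extents))
    )

    # voxelize the ROI in the world frame; classify voxels by mean distance
    idx = np.floor(scene.cloud.positions / scene.voxel_size).astype(np.int64)
    _, inverse = np.unique(idx, axis=0, return_inverse=True)
    nvox = inverse.max() + 1 if len(inverse) else 0
    vox_dist = np.bincount(inverse, weights=dist, minlength=nvox)
    vox_dist /= np.maximum(np.bincount(inverse, minlength=nvox), 1)

    bmin, bmax = scene.fruit.corners_min_max()
    in_fruit = np.all(
        (scene.cloud.positions >= bmin) & (scene.cloud.positions <= bmax), axis=1
    )
    fruit_voxels = np.zeros(nvox, dtype=bool)
    fruit_voxels[inverse[in_fruit]] = True
    fore_voxels = (vox_dist < fruit_dist - margin) & ~fruit_voxels

    fruit_mask = _pixel_mask(scene.cam, pts_cam[fruit_voxels[inverse]])
    if not fruit_mask.any():
        raise ValueError("fruit has an empty pixel footprint in this view")
    fore_mask = _pixel_mask(scene.cam, pts_cam[fore_voxels[inverse]])
    return float((fruit_mask & fore_mask).sum() / fruit_mask.sum())


@dataclass
class EvalResult:
    """AP/AR per IoU threshold plus the underlying PR curves."""

    ap_by_threshold: dict
    ar_by_threshold: dict
    pr_curves: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ap_by_threshold": {str(k): float(v) for k, v in self.ap_by_threshold.items()},
            "ar_by_threshold": {str(k): float(v) for k, v in self.ar_by_threshold.items()},
            "pr_curves": {
                str(k): {
                    "confidence": [float(x) for x in v["confidence"]],
                    "precision": [float(x) for x in v["precision"]],
                    "recall": [float(x) for x in v["recall"]],
                }
                for k, v in self.pr_curves.items()
            },
        }


def _match_greedy(
    detections: Sequence[Box3D], ground_truth: Sequence[Box3D], iou_threshold: float
) -> np.ndarray:
    """True/false-positive flags for detections in confidence-descending order.

    Each ground-truth box is matched at most once, to the highest-confidence
    detection of its class reaching the IoU threshold; among eligible GT
    boxes a detection takes the one with highest IoU.
    """
    order = sorted(
        range(len(detections)), key=lambda i: (-detections[i].confidence, i)
    )
    taken = np.zeros(len(ground_truth), dtype=bool)
    tp = np.zeros(len(detections), dtype=bool)
    for rank, i in enumerate(order):
        det = detections[i]
        best_j, best_iou = -1, -1.0
        for j, gt in enumerate(ground_truth):
            if taken[j] or gt.class_id != det.class_id:
                continue
            iou = iou3d(det, gt)
            if iou >= iou_threshold and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0:
            taken[best_j] = True
            tp[rank] = True
    return tp


def evaluate_ap_ar(
    detections: Sequence[Box3D],
    ground_truth: Sequence[Box3D],
    iou_thresholds: Sequence[float] = (0.25, 0.5),
) -> EvalResult:
    """AP and AR of detections against ground truth at 3D IoU thresholds."""
    ap, ar, curves = {}, {}, {}
    n_gt = len(ground_truth)
    order = sorted(
        range(len(detections)), key=lambda i: (-detections[i].confidence, i)
    )
    confidences = [detections[i].confidence for i in order]
    for thr in iou_thresholds:
        if n_gt == 0 or len(detections) == 0:
            ap[thr] = 0.0
            ar[thr] = 0.0
            curves[thr] = {"confidence": [], "precision": [], "recall": []}
            continue
        tp = _match_greedy(detections, ground_truth, thr)
        cum_tp = np.cumsum(tp)
        ranks = np.arange(1, len(tp) + 1)
        precision = cum_tp / ranks
        recall = cum_tp / n_gt
        # all-point precision envelope
        env = np.maximum.accumulate(precision[::-1])[::-1]
        r_prev = np.concatenate([[0.0], recall[:-1]])
        ap[thr] = float(np.sum((recall - r_prev) * env))
        ar[thr] = float(recall[-1])
        curves[thr] = {
            "confidence": confidences,
            "precision": precision.tolist(),
            "recall": recall.tolist(),
        }
    return EvalResult(ap, ar, curves)
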