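"""Rigid transforms, pinhole camera model, and Lidar-point colorization.

Conventions: right-handed coordinates throughout; the camera frame has +z
pointing forward along the optical axis, +x right and +y down, so that the
pinhole projection u = fx*x/z + u0, v = fy*y/z + v0 lands in an image with
origin at the top-left corner. All lengths are in meters, pixel quantities
in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

#: Points with camera-frame depth below this are treated as unprojectable.
DEPTH_EPSILON = 1e-6


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p -> R @ p + t.

    ``rotation`` must be orthonormal with determinant +1 (checked to 1e-9).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _as_vec3(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quaternion(cls, quat_wxyz, translation) -> "RigidTransform":
        w, x, y, z = np.asarray(quat_wxyz, dtype=float)
        R = Rotation.from_quat([x, y, z, w]).as_matrix()
        return cls(R, translation)

    def quaternion_wxyz(self) -> np.ndarray:
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        # canonical sign: w >= 0 for stable serialization
        q = np.array([w, x, y, z])
        return -q if w < 0 else q

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one 3-vector or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def to_dict(self) -> dict:
        return {
            "quaternion": [float(v) for v in self.quaternion_wxyz()],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_quaternion(d["quaternion"], d["translation"])


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics (no distortion)."""

    fx: float
    fy: float
    u0: float
    v0: float
    width: int
    height: int

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.u0 < self.width and 0 <= self.v0 < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.u0], [0.0, self.fy, self.v0], [0.0, 0.0, 1.0]]
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "u0": self.u0, "v0": self.v0,
            "width": self.width, "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(d["fx"], d["fy"], d["u0"], d["v0"], int(d["width"]), int(d["height"]))


@dataclass
class ColoredPointCloud:
    """Point positions with optional per-point color and intensity.

    ``colors`` holds uint8 RGB triplets; ``color_valid`` marks which entries
    carry a real color (points that could not be colorized keep the flag
    False). All per-point arrays have equal length.
    """

    positions: np.ndarray
    colors: Optional[np.ndarray] = None
    intensity: Optional[np.ndarray] = None
    color_valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        n = len(self.positions)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(n, 3)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float).reshape(n)
        if self.color_valid is None:
            self.color_valid = np.full(n, self.colors is not None)
        else:
            self.color_valid = np.asarray(self.color_valid, dtype=bool).reshape(n)

    def __len__(self) -> int:
        return len(self.positions)

    def copy(self) -> "ColoredPointCloud":
        return ColoredPointCloud(
            self.positions.copy(),
            None if self.colors is None else self.colors.copy(),
            None if self.intensity is None else self.intensity.copy(),
            self.color_valid.copy(),
        )


def apply_transform(T: RigidTransform, cloud: ColoredPointCloud) -> ColoredPointCloud:
    """Rigidly move every point of ``cloud``; per-point attributes are kept."""
    out = cloud.copy()
    out.positions = T.apply(cloud.positions)
    return out


def project_points(cam: CameraModel, points: np.ndarray):
    """Vectorized pinhole projection of camera-frame points.

    Returns ``(u, v, depth, projectable)`` arrays; ``projectable`` is False
    where depth <= DEPTH_EPSILON (point at or behind the camera). u, v are
    NaN for unprojectable points.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    z = p[:, 2]
    ok = z > DEPTH_EPSILON
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(ok, cam.fx * p[:, 0] / z + cam.u0, np.nan)
        v = np.where(ok, cam.fy * p[:, 1] / z + cam.v0, np.nan)
    return u, v, z, ok


def project_point(cam: CameraModel, p) -> tuple[float, float, float]:
    """Project one camera-frame point; returns (u, v, depth).

    Raises ``ValueError`` for points at or behind the camera.
    """
    u, v, z, ok = project_points(cam, _as_vec3(p))
    if not ok[0]:
        raise ValueError(f"point with depth {z[0]:.3g} m is behind the camera")
    return float(u[0]), float(v[0]), float(z[0])


def back_project(cam: CameraModel, u: float, v: float, depth: float) -> np.ndarray:
    """Invert the pinhole projection at known depth (camera frame)."""
    return np.array(
        [(u - cam.u0) * depth / cam.fx, (v - cam.v0) * depth / cam.fy, depth]
    )


def colorize_cloud(
    cloud: ColoredPointCloud,
    T_lidar_to_cam: RigidTransform,
    cam: CameraModel,
    image: np.ndarray,
) -> ColoredPointCloud:
    """Color Lidar points by projecting them into an RGB image.

    Each point is mapped to the camera frame, projected through the pinhole
    model and assigned the nearest pixel's color if it lands inside the image
    with positive depth; other points keep ``color_valid = False``. Point
    geometry is unchanged (the output stays in the Lidar frame).
    """
    img = np.asarray(image)
    if img.shape[:2] != (cam.height, cam.width) or img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"image shape {img.shape} does not match camera "
            f"{cam.height}x{cam.width}x3"
        )
    cam_pts = T_lidar_to_cam.apply(cloud.positions)
    u, v, _, ok = project_points(cam, cam_pts)
    ui = np.full(len(cloud), -1, dtype=int)
    vi = np.full(len(cloud), -1, dtype=int)
    ui[ok] = np.round(u[ok]).astype(int)
    vi[ok] = np.round(v[ok]).astype(int)
    inside = ok & (ui >= 0) & (ui < cam.width) & (vi >= 0) & (vi < cam.height)

    out = cloud.copy()
    colors = np.zeros((len(cloud), 3), dtype=np.uint8)
    colors[inside] = img[vi[inside], ui[inside]]
    out.colors = colors
    out.color_valid = inside
    return out


def look_at(position, target, up=(0.0, 0.0, 1.0)) -> RigidTransform:
    """Camera-to-world pose looking from ``position`` toward ``target``.

    The camera +z axis points at the target; +x is horizontal (perpendicular
    to world ``up``) and +y completes a right-handed frame pointing roughly
    downward. Falls back to an arbitrary horizontal axis when the view
    direction is parallel to ``up``.
    """
    pos = _as_vec3(position)
    f = _as_vec3(target) - pos
    norm = np.linalg.norm(f)
    if norm < 1e-12:
        raise ValueError("look_at target coincides with the camera position")
    z = f / norm
    upv = _as_vec3(up)
    x = np.cross(z, upv)
    if np.linalg.norm(x) < 1e-9:  # looking straight up/down
        x = np.cross(z, [1.0, 0.0, 0.0])
        if np.linalg.norm(x) < 1e-9:
            x = np.cross(z, [0.0, 1.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform(R, pos)
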