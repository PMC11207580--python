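"""Anisotropic-Gaussian obstacle fields and ray-integral occlusion.

A scene's obstacles are represented as a set of unnormalized anisotropic 3D
Gaussians, one per occupied voxel: each Gaussian is an ellipsoid with mean
mu, orientation R and semi-axis scales S, giving covariance
Sigma = R S S^T R^T. Because the probability-density normalization constant
is dropped, every Gaussian evaluates to exactly 1 at its own center, and the
collision index i(X) — the mean Gaussian response at a point — is a soft
occupancy in [0, 1]. The occlusion level of a fruit from a viewpoint is the
arc-length line integral of i(X) along the camera-to-fruit ray.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .geometry import ColoredPointCloud, RigidTransform, _as_vec3

#: Minimum semi-axis scale (meters); keeps Sigma invertible for planar,
#: collinear or single-point voxels. The eigenvalue floor is its square.
SIGMA_FLOOR = 1e-2

#: Gaussians whose mean lies within this multiple of the target-fruit radius
#: of the fruit center are treated as the fruit's own surface, not occluders.
EXCLUSION_FACTOR = 1.2

DEFAULT_VOXEL_SIZE = 0.05
DEFAULT_MIN_POINTS = 5
DEFAULT_NI = 64


@dataclass(frozen=True)
class GaussianObstacle:
    """One ellipsoidal obstacle: mean, orientation and semi-axis scales."""

    mu: np.ndarray
    R: np.ndarray
    S_diag: np.ndarray

    def __post_init__(self):
        mu = _as_vec3(self.mu)
        R = np.asarray(self.R, dtype=float)
        S = np.asarray(self.S_diag, dtype=float).reshape(3)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("R must be a 3x3 orthonormal matrix")
        if np.any(S < SIGMA_FLOOR - 1e-12):
            raise ValueError(f"semi-axis scales must be >= {SIGMA_FLOOR}")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "S_diag", S)

    @property
    def sigma(self) -> np.ndarray:
        """Covariance Sigma = R S S^T R^T (symmetric positive-definite)."""
        return self.R @ np.diag(self.S_diag**2) @ self.R.T

    @property
    def sigma_inv(self) -> np.ndarray:
        return self.R @ np.diag(self.S_diag**-2) @ self.R.T

    def to_dict(self) -> dict:
        return {
            "mu": [float(v) for v in self.mu],
            "R": [float(v) for v in self.R.ravel()],
            "S_diag": [float(v) for v in self.S_diag],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianObstacle":
        return cls(np.array(d["mu"]), np.array(d["R"]).reshape(3, 3), np.array(d["S_diag"]))


def evaluate_gaussian(g: GaussianObstacle, X) -> float:
    """Unnormalized Gaussian response exp(-1/2 (X-mu)^T Sigma^-1 (X-mu)).

    Equals 1 exactly when X is the mean; decays to 0 away from it.
    """
    d = _as_vec3(X) - g.mu
    return float(np.exp(-0.5 * d @ g.sigma_inv @ d))


@dataclass
class GaussianField:
    """The scene's obstacle set, with batched ray-integral evaluation."""

    gaussians: list
    voxel_size: float = DEFAULT_VOXEL_SIZE
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.gaussians = list(self.gaussians)
        self.origin = _as_vec3(self.origin)
        self._stack = None

    def __len__(self) -> int:
        return len(self.gaussians)

    def _stacked(self):
        """Cached (mus, inv_sigmas) arrays of shape (ng, 3) and (ng, 3, 3)."""
        if self._stack is None or self._stack[0].shape[0] != len(self.gaussians):
            if self.gaussians:
                mus = np.stack([g.mu for g in self.gaussians])
                inv = np.stack([g.sigma_inv for g in self.gaussians])
            else:
                mus = np.zeros((0, 3))
                inv = np.zeros((0, 3, 3))
            self._stack = (mus, inv)
        return self._stack

    def transformed(self, T: RigidTransform) -> "GaussianField":
        """The field expressed in a new frame: mu -> R mu + t, axes rotated."""
        gs = [
            GaussianObstacle(T.apply(g.mu), T.rotation @ g.R, g.S_diag)
            for g in self.gaussians
        ]
        return GaussianField(gs, self.voxel_size, T.apply(self.origin))

    def extend(self, other: "GaussianField") -> None:
        self.gaussians.extend(other.gaussians)
        self._stack = None

    def to_dict(self) -> dict:
        return {
            "voxel_size": float(self.voxel_size),
            "origin": [float(v) for v in self.origin],
            "gaussians": [g.to_dict() for g in self.gaussians],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianField":
        return cls(
            [GaussianObstacle.from_dict(g) for g in d["gaussians"]],
            d.get("voxel_size", DEFAULT_VOXEL_SIZE),
            np.array(d.get("origin", [0.0, 0.0, 0.0])),
        )


@dataclass(frozen=True)
class Ray:
    """A viewing ray from the camera center toward a fruit center.

    ``effective_length`` stops one fruit radius short of the center so the
    fruit's own surface does not integrate as its occluder.
    """

    origin: np.ndarray
    target: np.ndarray
    effective_length: float

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        object.__setattr__(self, "target", _as_vec3(self.target))
        if self.effective_length <= 0:
            raise ValueError("effective_length must be positive")

    @classmethod
    def to_fruit(cls, origin, center, radius: float) -> "Ray":
        origin = _as_vec3(origin)
        center = _as_vec3(center)
        dist = float(np.linalg.norm(center - origin))
        return cls(origin, center, dist - radius)

    @property
    def fruit_radius(self) -> float:
        return float(np.linalg.norm(self.target - self.origin)) - self.effective_length


@dataclass(frozen=True)
class OcclusionResult:
    """Line-integrated occlusion level I along one ray (>= 0, meters)."""

    I: float
    n_samples: int
    excluded_ids: tuple


def fit_field(
    cloud: ColoredPointCloud,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    min_points: int = DEFAULT_MIN_POINTS,
    origin=(0.0, 0.0, 0.0),
    cov_scale: float = 1.0,
) -> GaussianField:
    """Fit one anisotropic Gaussian per occupied voxel of a point cloud.

    Points are binned into half-open cubic voxels
    [origin + k*s, origin + (k+1)*s). Each voxel holding at least
    ``min_points`` points yields a Gaussian with mu at the centroid and
    covariance ``cov_scale`` times the sample covariance of its points,
    eigenvalue-floored at SIGMA_FLOOR**2 so degenerate voxels stay
    positive-definite. An empty cloud yields an empty field.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    origin = _as_vec3(origin)
    pts = cloud.positions
    if len(pts) == 0:
        return GaussianField([], voxel_size, origin)

    idx = np.floor((pts - origin) / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    order = np.argsort(inverse, kind="stable")
    boundaries = np.concatenate([[0], np.cumsum(counts)])

    gaussians = []
    for k in range(len(counts)):
        if counts[k] < min_points:
            continue
        vox_pts = pts[order[boundaries[k] : boundaries[k + 1]]]
        mu = vox_pts.mean(axis=0)
        cov = np.cov(vox_pts.T, ddof=1) * cov_scale
        lam, vec = np.linalg.eigh(cov)
        if np.linalg.det(vec) < 0:
            vec = vec.copy()
            vec[:, 0] = -vec[:, 0]
        S = np.sqrt(np.maximum(lam, SIGMA_FLOOR**2))
        gaussians.append(GaussianObstacle(mu, vec, S))
    return GaussianField(gaussians, voxel_size, origin)


def collision_index(
    field: GaussianField, X, excluded_ids: Iterable[int] = ()
) -> float:
    """Mean Gaussian response at X over non-excluded obstacles, in [0, 1].

    Returns 0 for an (effectively) empty field: free space.
    """
    mus, inv = field._stacked()
    excluded = set(excluded_ids)
    keep = np.array([i not in excluded for i in range(len(mus))], dtype=bool)
    n = int(keep.sum())
    if n == 0:
        return 0.0
    d = _as_vec3(X) - mus[keep]
    q = np.einsum("gi,gij,gj->g", d, inv[keep], d)
    return float(np.exp(-0.5 * q).sum() / n)


def _exclusion_masks(mus, targets, radii, exclusion_factor):
    """Eligibility mask (nf, ng): True where a Gaussian may occlude fruit f."""
    if mus.shape[0] == 0:
        return np.zeros((targets.shape[0], 0), dtype=bool)
    d = np.linalg.norm(mus[None, :, :] - targets[:, None, :], axis=-1)
    return d > exclusion_factor * radii[:, None]


def _batch_integral(
    field: GaussianField,
    origins: np.ndarray,
    targets: np.ndarray,
    lengths: np.ndarray,
    radii: np.ndarray,
    ni: int,
    exclusion_factor: float,
    normalize: str,
):
    """Trapezoid-rule occlusion integrals for a batch of rays.

    The inner evaluation is one rank-4 tensor of ray-sample offsets indexed
    (fruit, sample, gaussian, coordinate), reduced with a single einsum.
    Returns (I values (nf,), eligibility mask (nf, ng)).
    """
    mus, inv = field._stacked()
    nf = origins.shape[0]
    mask = _exclusion_masks(mus, targets, radii, exclusion_factor)
    if len(mus) == 0 or not mask.any():
        return np.zeros(nf), mask

    dirs = targets - origins
    dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
    s = np.linspace(0.0, 1.0, ni)[None, :] * lengths[:, None]  # (nf, ni)
    X = origins[:, None, :] + s[:, :, None] * dirs[:, None, :]  # (nf, ni, 3)
    diff = X[:, :, None, :] - mus[None, None, :, :]  # (nf, ni, ng, 3)
    q = np.einsum("fsgi,gij,fsgj->fsg", diff, inv, diff)
    vals = np.exp(-0.5 * q)  # (nf, ni, ng)

    if normalize == "scene":
        denom = np.full(nf, float(len(mus)))
    else:
        denom = np.maximum(mask.sum(axis=1), 1).astype(float)
    i_of_s = (vals * mask[:, None, :]).sum(axis=-1) / denom[:, None]  # (nf, ni)
    I = np.trapezoid(i_of_s, x=s, axis=1)
    return I, mask


def occlusion_level(
    field: GaussianField,
    ray: Ray,
    ni: int = DEFAULT_NI,
    exclusion_factor: float = EXCLUSION_FACTOR,
    normalize: Literal["eligible", "scene"] = "eligible",
) -> OcclusionResult:
    """Occlusion level I of one fruit from one viewpoint.

    I is the trapezoid-rule integral of the collision index over ``ni``
    uniform arc-length samples from the ray origin up to the effective
    length. Gaussians within ``exclusion_factor`` fruit radii of the target
    center are excluded; by default the collision-index normalization counts
    only the remaining (eligible) Gaussians.
    """
    if ni < 2:
        raise ValueError("ni must be >= 2")
    results = batch_occlusion(field, [ray], ni, exclusion_factor, normalize)
    return results[0]


def batch_occlusion(
    field: GaussianField,
    rays: Sequence[Ray],
    ni: int = DEFAULT_NI,
    exclusion_factor: float = EXCLUSION_FACTOR,
    normalize: Literal["eligible", "scene"] = "eligible",
) -> list:
    """Occlusion levels for many rays in one vectorized evaluation.

    Produces values identical to per-ray :func:`occlusion_level`.
    """
    if len(rays) == 0:
        raise ValueError("at least one ray required")
    if ni < 2:
        raise ValueError("ni must be >= 2")
    origins = np.stack([r.origin for r in rays])
    targets = np.stack([r.target for r in rays])
    lengths = np.array([r.effective_length for r in rays])
    radii = np.array([r.fruit_radius for r in rays])
    I, mask = _batch_integral(
        field, origins, targets, lengths, radii, ni, exclusion_factor, normalize
    )
    return [
        OcclusionResult(
            I=float(I[f]),
            n_samples=ni,
            excluded_ids=tuple(np.nonzero(~mask[f])[0].tolist()),
        )
        for f in range(len(rays))
    ]
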