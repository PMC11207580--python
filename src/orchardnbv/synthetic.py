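"""Seeded synthetic orchard scenes: generation, rendering, mock detection.

A scene is a set of spherical fruits inside a tree crown plus branch
(cylinder), leaf (disk) and planar-patch obstacle primitives. Views are
rendered by sampling every surface at a configured areal density, adding
sensor noise along the viewing ray, and keeping per raster cell only the
samples nearest to the camera (a z-buffer with depth tolerance tau). The
raster cell size adapts to the sampling density so that visibility is
decided where samples are dense enough to compete; per-fruit visibility
fractions and ground-truth occlusion ratios come from the same raster. A
noisy mock detector turns a render into 3D boxes, standing in for a learned
detector so the planner/fusion/evaluation stack runs end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.ndimage import minimum_filter

from .fusion import Box3D
from .geometry import (
    CameraModel,
    ColoredPointCloud,
    RigidTransform,
    _as_vec3,
    project_points,
)

CLASS_COLORS = {
    0: (200, 30, 30),    # apple
    1: (240, 140, 20),   # orange
    2: (220, 60, 90),    # lychee
}
OBSTACLE_COLOR = (110, 110, 110)

DEFAULT_DENSITY = 2.0e4   # surface samples per m^2
DEFAULT_TAU = 0.005       # z-buffer depth tolerance, m


@dataclass(frozen=True)
class Fruit:
    center: np.ndarray
    diameter: float
    class_id: int = 0

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        if self.diameter <= 0:
            raise ValueError("fruit diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def to_dict(self) -> dict:
        return {
            "center": [float(v) for v in self.center],
            "diameter": float(self.diameter),
            "class_id": int(self.class_id),
        }


@dataclass(frozen=True)
class Cylinder:
    """A branch segment between two endpoints."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "p0", _as_vec3(self.p0))
        object.__setattr__(self, "p1", _as_vec3(self.p1))
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": "cylinder",
            "p0": [float(v) for v in self.p0],
            "p1": [float(v) for v in self.p1],
            "radius": float(self.radius),
        }


@dataclass(frozen=True)
class Disk:
    """A leaf: a flat disk with a center, unit normal and radius."""

    center: np.ndarray
    normal: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        n = _as_vec3(self.normal)
        norm = np.linalg.norm(n)
        if norm < 1e-12 or self.radius <= 0:
            raise ValueError("disk needs a nonzero normal and positive radius")
        if abs(norm - 1.0) > 1e-12:  # idempotent: round-trips stay exact
            n = n / norm
        object.__setattr__(self, "normal", n)

    def to_dict(self) -> dict:
        return {
            "kind": "disk",
            "center": [float(v) for v in self.center],
            "normal": [float(v) for v in self.normal],
            "radius": float(self.radius),
        }


@dataclass(frozen=True)
class RectPatch:
    """A planar rectangular patch spanned by two half-extent vectors."""

    center: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        object.__setattr__(self, "u", _as_vec3(self.u))
        object.__setattr__(self, "v", _as_vec3(self.v))

    def to_dict(self) -> dict:
        return {
            "kind": "patch",
            "center": [float(v) for v in self.center],
            "u": [float(v) for v in self.u],
            "v": [float(v) for v in self.v],
        }


Obstacle = Union[Cylinder, Disk, RectPatch]


def _obstacle_from_dict(d: dict) -> Obstacle:
    kind = d["kind"]
    if kind == "cylinder":
        return Cylinder(np.array(d["p0"]), np.array(d["p1"]), d["radius"])
    if kind == "disk":
        return Disk(np.array(d["center"]), np.array(d["normal"]), d["radius"])
    if kind == "patch":
        return RectPatch(np.array(d["center"]), np.array(d["u"]), np.array(d["v"]))
    raise ValueError(f"unknown obstacle kind {kind!r}")


@dataclass
class SceneSpec:
    """A fully reproducible scene description."""

    fruits: list
    obstacles: list
    density: float = DEFAULT_DENSITY
    noise_sigma: float = 0.001
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "fruits": [f.to_dict() for f in self.fruits],
            "obstacles": [o.to_dict() for o in self.obstacles],
            "density": float(self.density),
            "noise_sigma": float(self.noise_sigma),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            fruits=[
                Fruit(np.array(f["center"]), f["diameter"], int(f.get("class_id", 0)))
                for f in d["fruits"]
            ],
            obstacles=[_obstacle_from_dict(o) for o in d.get("obstacles", [])],
            density=d.get("density", DEFAULT_DENSITY),
            noise_sigma=d.get("noise_sigma", 0.001),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class SceneConfig:
    """Generator settings emulating a fruit-bearing tree crown.

    Fruits sit inside a spherical crown together with branch and leaf
    obstacles; a camera region south of the crown (negative y) looks
    through the foliage, so typical first views are partially occluded.
    """

    n_fruits: int = 9
    crown_center: tuple = (0.0, 0.0, 1.2)
    crown_radius: float = 0.35
    diameter_mean: float = 0.075
    diameter_sd: float = 0.005
    fruit_class: int = 0
    n_branches: int = 6
    branch_radius: float = 0.02
    n_leaves: int = 25
    leaf_radius: float = 0.05
    min_separation: float = 0.02
    density: float = DEFAULT_DENSITY
    noise_sigma: float = 0.001
    max_retries: int = 2000


def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x


def generate_scene(config: SceneConfig, seed: int) -> SceneSpec:
    """Draw a seeded random scene from the generator settings.

    Fruit diameters come from a normal truncated at +-3 sd; fruit centers
    are rejection-sampled uniformly in the crown under a pairwise
    no-overlap constraint (surface gap >= min_separation). Raises after
    ``max_retries`` failed placements.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(config.crown_center, dtype=float)

    fruits: list[Fruit] = []
    tries = 0
    while len(fruits) < config.n_fruits:
        if tries > config.max_retries:
            raise RuntimeError(
                f"could not place {config.n_fruits} non-overlapping fruits "
                f"in {config.max_retries} attempts"
            )
        tries += 1
        d = _truncated_normal(
            rng,
            config.diameter_mean,
            config.diameter_sd,
            max(config.diameter_mean - 3 * config.diameter_sd, 1e-3),
            config.diameter_mean + 3 * config.diameter_sd,
        )
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = config.crown_radius * rng.uniform() ** (1 / 3)
        pos = c + r * u
        ok = all(
            np.linalg.norm(pos - f.center) >= f.radius + d / 2 + config.min_separation
            for f in fruits
        )
        if ok:
            fruits.append(Fruit(pos, d, config.fruit_class))

    obstacles: list[Obstacle] = []
    for _ in range(config.n_branches):
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        b = rng.normal(size=3)
        b /= np.linalg.norm(b)
        obstacles.append(
            Cylinder(
                c + config.crown_radius * a,
                c + config.crown_radius * b,
                config.branch_radius * rng.uniform(0.6, 1.4),
            )
        )
    for _ in range(config.n_leaves):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = config.crown_radius * rng.uniform() ** (1 / 3)
        normal = rng.normal(size=3)
        obstacles.append(
            Disk(c + r * u, normal, config.leaf_radius * rng.uniform(0.6, 1.4))
        )

    return SceneSpec(
        fruits=fruits,
        obstacles=obstacles,
        density=config.density,
        noise_sigma=config.noise_sigma,
        seed=seed,
    )


def _perp_basis(n: np.ndarray):
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(n, e1)


def _n_samples(density: float, area: float) -> int:
    return max(1, int(round(density * area)))


def sample_surfaces(spec: SceneSpec, rng: np.random.Generator):
    """Sample every surface of the scene at the configured areal density.

    Returns (points (N, 3) world frame, source_ids (N,), colors (N, 3)):
    fruit i contributes id i, obstacle j contributes id -(j+1).
    """
    pts, ids, cols = [], [], []
    for i, f in enumerate(spec.fruits):
        n = _n_samples(spec.density, 4 * math.pi * f.radius**2)
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts.append(f.center + f.radius * d)
        ids.append(np.full(n, i))
        cols.append(np.tile(CLASS_COLORS.get(f.class_id, (200, 30, 30)), (n, 1)))
    for j, ob in enumerate(spec.obstacles):
        if isinstance(ob, Cylinder):
            axis = ob.p1 - ob.p0
            length = np.linalg.norm(axis)
            axis = axis / length
            e1, e2 = _perp_basis(axis)
            n = _n_samples(spec.density, 2 * math.pi * ob.radius * length)
            t = rng.uniform(0, length, n)
            ang = rng.uniform(0, 2 * math.pi, n)
            p = (
                ob.p0
                + t[:, None] * axis
                + ob.radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
            )
        elif isinstance(ob, Disk):
            e1, e2 = _perp_basis(ob.normal)
            n = _n_samples(spec.density, math.pi * ob.radius**2)
            r = ob.radius * np.sqrt(rng.uniform(size=n))
            ang = rng.uniform(0, 2 * math.pi, n)
            p = ob.center + r[:, None] * (
                np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2
            )
        else:  # RectPatch
            area = 4 * np.linalg.norm(np.cross(ob.u, ob.v))
            n = _n_samples(spec.density, area)
            a = rng.uniform(-1, 1, n)
            b = rng.uniform(-1, 1, n)
            p = ob.center + a[:, None] * ob.u + b[:, None] * ob.v
        pts.append(p)
        ids.append(np.full(n, -(j + 1)))
        cols.append(np.tile(OBSTACLE_COLOR, (n, 1)))
    if not pts:
        return np.zeros((0, 3)), np.zeros(0, dtype=int), np.zeros((0, 3), dtype=np.uint8)
    return (
        np.concatenate(pts),
        np.concatenate(ids).astype(int),
        np.concatenate(cols).astype(np.uint8),
    )


def _camera_inside(spec: SceneSpec, pos: np.ndarray) -> bool:
    for f in spec.fruits:
        if np.linalg.norm(pos - f.center) < f.radius:
            return True
    for ob in spec.obstacles:
        if isinstance(ob, Cylinder):
            axis = ob.p1 - ob.p0
            t = np.clip((pos - ob.p0) @ axis / (axis @ axis), 0.0, 1.0)
            if np.linalg.norm(pos - (ob.p0 + t * axis)) < ob.radius:
                return True
    return False


@dataclass
class RenderResult:
    """One rendered view: the visible cloud plus ground-truth visibility."""

    cloud: ColoredPointCloud          # camera frame, visible samples only
    source_ids: np.ndarray            # per rendered point
    visibility_fraction: np.ndarray   # per fruit
    occlusion_ratio: np.ndarray       # per fruit (NaN if no footprint)
    cam: CameraModel
    cam_pose: RigidTransform
    zbuffer_bin_px: int
    tau: float


def render_view(
    spec: SceneSpec,
    cam: CameraModel,
    cam_pose: RigidTransform,
    tau: float = DEFAULT_TAU,
    seed: Optional[int] = None,
) -> RenderResult:
    """Render the scene from a camera pose with exact sample-level visibility.

    Surfaces are sampled at ``spec.density``; samples are jittered along the
    viewing ray by the sensor noise, projected, and competed in a z-buffer
    whose raster cell spans roughly two sample spacings (so visibility is
    decided only where samples are dense enough to collide); all samples
    within ``tau`` of the nearest in their cell are kept. Per-fruit
    occlusion ratios are the fraction of the fruit's raster silhouette
    where another surface wins the depth test.
    """
    pos = cam_pose.translation
    if _camera_inside(spec, pos):
        raise ValueError("camera position lies inside a scene primitive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    world_pts, src, colors = sample_surfaces(spec, rng)

    # sensor noise along the viewing ray
    if spec.noise_sigma > 0 and len(world_pts):
        d = world_pts - pos
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        world_pts = world_pts + rng.normal(0, spec.noise_sigma, len(world_pts))[:, None] * d

    cam_pts = cam_pose.inverse().apply(world_pts)
    u, v, z, ok = project_points(cam, cam_pts)
    inside = ok & (u >= -0.5) & (u < cam.width - 0.5) & (v >= -0.5) & (v < cam.height - 0.5)

    # raster cell size: ~2 sample spacings at the median depth
    spacing = 1.0 / math.sqrt(spec.density)
    z_ref = float(np.median(z[inside])) if inside.any() else 1.0
    f_avg = 0.5 * (cam.fx + cam.fy)
    bin_px = max(1, int(round(f_avg * 2.0 * spacing / z_ref)))
    nbx = (cam.width + bin_px - 1) // bin_px
    nby = (cam.height + bin_px - 1) // bin_px

    cell = np.full(len(world_pts), -1, dtype=np.int64)
    ui = np.clip(np.round(u[inside]).astype(int), 0, cam.width - 1) // bin_px
    vi = np.clip(np.round(v[inside]).astype(int), 0, cam.height - 1) // bin_px
    cell[inside] = vi * nbx + ui

    # per-cell winner (min depth + its source) and best depth from any
    # *other* source; together these give, for every source s, the nearest
    # competing surface min depth per cell in O(1)
    idx_in = np.nonzero(inside)[0]
    zbuf = np.full(nbx * nby, np.inf)
    np.minimum.at(zbuf, cell[idx_in], z[idx_in])
    order = idx_in[np.argsort(z[idx_in], kind="stable")]
    _, first = np.unique(cell[order], return_index=True)
    win_src = np.full(nbx * nby, np.iinfo(np.int64).min, dtype=np.int64)
    win_src[cell[order[first]]] = src[order[first]]
    second = np.full(nbx * nby, np.inf)
    others = idx_in[src[idx_in] != win_src[cell[idx_in]]]
    np.minimum.at(second, cell[others], z[others])

    # competing-surface depth (3x3 neighborhood min, fills sampling holes);
    # the slack 'band' absorbs surface slant across one raster cell
    band = tau + 2.0 * bin_px * z_ref / f_avg

    def competitor_raster(s: int) -> np.ndarray:
        excl = np.where(win_src == s, second, zbuf)
        return minimum_filter(excl.reshape(nby, nbx), size=3).ravel()

    comp = {int(s): competitor_raster(int(s)) for s in np.unique(src)}
    nbhd_all = minimum_filter(zbuf.reshape(nby, nbx), size=3).ravel()
    visible = (
        inside
        & (z <= zbuf[np.clip(cell, 0, None)] + tau)
        & (z <= nbhd_all[np.clip(cell, 0, None)] + band)
    )

    nf = len(spec.fruits)
    vis_frac = np.zeros(nf)
    occ_ratio = np.full(nf, np.nan)
    for i in range(nf):
        mine = src == i
        total = int(mine.sum())
        if total:
            vis_frac[i] = float((mine & visible).sum() / total)
        sil_mask = mine & inside
        if not sil_mask.any():
            continue
        # fruit's own front depth per cell vs nearest competing surface
        fz = np.full(nbx * nby, np.inf)
        idx = np.nonzero(sil_mask)[0]
        np.minimum.at(fz, cell[idx], z[idx])
        sil_cells = np.unique(cell[idx])
        occluded = comp[i][sil_cells] < fz[sil_cells] - band
        occ_ratio[i] = float(occluded.sum() / len(sil_cells))

    cloud = ColoredPointCloud(cam_pts[visible], colors=colors[visible])
    return RenderResult(
        cloud=cloud,
        source_ids=src[visible],
        visibility_fraction=vis_frac,
        occlusion_ratio=occ_ratio,
        cam=cam,
        cam_pose=cam_pose,
        zbuffer_bin_px=bin_px,
        tau=tau,
    )


@dataclass
class MockDetectorConfig:
    """Noise model of the stand-in detector.

    Position noise grows with occlusion (sd = sigma_p * (1 + beta * O)),
    extents get independent noise of sd sigma_d, and fruits with
    O >= o_miss are missed. Confidence is
    clamp(1 - O - quality_weight * |position error| + noise, 0, 1):
    the quality term emulates a calibrated detector whose confidence
    co-varies with localization accuracy, so confidence-ordered fusion
    prefers the better-localized of two otherwise comparable views.
    """

    sigma_p: float = 0.003
    sigma_d: float = 0.002
    beta: float = 2.0
    o_miss: float = 0.8
    conf_sigma: float = 0.02
    quality_weight: float = 20.0  # confidence lost per meter of error


def mock_detect(
    render: RenderResult,
    spec: SceneSpec,
    cfg: MockDetectorConfig = MockDetectorConfig(),
    seed: int = 0,
) -> list:
    """Noisy 3D boxes (camera frame) for the fruits visible in a render."""
    rng = np.random.default_rng(seed)
    world_to_cam = render.cam_pose.inverse()
    boxes = []
    for i, fruit in enumerate(spec.fruits):
        O = render.occlusion_ratio[i]
        if not np.isfinite(O) or O >= cfg.o_miss:
            continue
        err = rng.normal(0.0, cfg.sigma_p * (1.0 + cfg.beta * O), 3)
        center = world_to_cam.apply(fruit.center) + err
        extents = np.maximum(
            fruit.diameter + rng.normal(0.0, cfg.sigma_d, 3), 1e-3
        )
        conf_noise = rng.normal(0.0, cfg.conf_sigma) if cfg.conf_sigma > 0 else 0.0
        confidence = float(np.clip(
            1.0 - O - cfg.quality_weight * np.linalg.norm(err) + conf_noise, 0.0, 1.0
        ))
        boxes.append(
            Box3D(center, extents, confidence, occlusion_pred=float(O),
                  class_id=fruit.class_id)
        )
    return boxes
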