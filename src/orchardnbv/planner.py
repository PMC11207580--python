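"""Next-best-view planning by gradient ascent of information gain.

The information gain of a candidate camera position is the sum over fruits
still needing observation of the reciprocal occlusion level along the
camera-to-fruit ray: views that see the fruit set through less obstacle
mass score higher. The planner prunes fruits that are already observable
below an occlusion threshold, then maximizes IG over the arm's reachable
region with seeded multi-start projected gradient ascent (central finite
differences on the fixed ray quadrature, backtracking line search,
projection onto the region after every step). Everything is deterministic
given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fusion import FruitEstimate, GlobalMap
from .gaussians import (
    DEFAULT_NI,
    EXCLUSION_FACTOR,
    GaussianField,
    Ray,
    batch_occlusion,
)
from .geometry import RigidTransform, _as_vec3, look_at


@dataclass(frozen=True)
class ReachableRegion:
    """Where the arm can place the camera.

    ``kind="box"``: axis-aligned box [lo, hi].
    ``kind="shell"``: spherical shell around ``center`` with radius in
    [r_min, r_max], optionally clipped to z >= z_min.
    """

    kind: str = "box"
    lo: Optional[np.ndarray] = None
    hi: Optional[np.ndarray] = None
    center: Optional[np.ndarray] = None
    r_min: float = 0.0
    r_max: float = 0.0
    z_min: Optional[float] = None

    def __post_init__(self):
        if self.kind == "box":
            lo = _as_vec3(self.lo)
            hi = _as_vec3(self.hi)
            if np.any(hi <= lo):
                raise ValueError("reachable box must have nonempty interior")
            object.__setattr__(self, "lo", lo)
            object.__setattr__(self, "hi", hi)
        elif self.kind == "shell":
            object.__setattr__(self, "center", _as_vec3(self.center))
            if not (0 < self.r_min < self.r_max):
                raise ValueError("shell needs 0 < r_min < r_max")
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def contains(self, p, tol: float = 1e-9) -> bool:
        p = _as_vec3(p)
        if self.kind == "box":
            return bool(np.all(p >= self.lo - tol) and np.all(p <= self.hi + tol))
        r = np.linalg.norm(p - self.center)
        ok = self.r_min - tol <= r <= self.r_max + tol
        if self.z_min is not None:
            ok = ok and p[2] >= self.z_min - tol
        return bool(ok)

    def project(self, p) -> np.ndarray:
        """Nearest feasible point (box: exact; shell: alternating clip)."""
        p = _as_vec3(p)
        if self.kind == "box":
            return np.clip(p, self.lo, self.hi)
        q = p.copy()
        for _ in range(4):
            if self.z_min is not None:
                q[2] = max(q[2], self.z_min)
            d = q - self.center
            r = np.linalg.norm(d)
            if r < 1e-12:
                d = np.array([1.0, 0.0, 0.0])
                r = 1.0
            q = self.center + d / r * np.clip(r, self.r_min, self.r_max)
        if self.z_min is not None:
            q[2] = max(q[2], self.z_min)
        return q

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n seeded uniform samples inside the region, shape (n, 3)."""
        if self.kind == "box":
            return rng.uniform(self.lo, self.hi, size=(n, 3))
        out = np.empty((n, 3))
        k = 0
        while k < n:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = (self.r_min**3 + (self.r_max**3 - self.r_min**3) * rng.uniform()) ** (1 / 3)
            p = self.center + r * u
            if self.z_min is None or p[2] >= self.z_min:
                out[k] = p
                k += 1
        return out

    def to_dict(self) -> dict:
        if self.kind == "box":
            return {
                "kind": "box",
                "lo": [float(v) for v in self.lo],
                "hi": [float(v) for v in self.hi],
            }
        d = {
            "kind": "shell",
            "center": [float(v) for v in self.center],
            "r_min": float(self.r_min),
            "r_max": float(self.r_max),
        }
        if self.z_min is not None:
            d["z_min"] = float(self.z_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReachableRegion":
        if d["kind"] == "box":
            return cls(kind="box", lo=np.array(d["lo"]), hi=np.array(d["hi"]))
        return cls(
            kind="shell",
            center=np.array(d["center"]),
            r_min=d["r_min"],
            r_max=d["r_max"],
            z_min=d.get("z_min"),
        )


@dataclass
class PlannerConfig:
    """Tunables of the NBV search.

    occlusion_threshold: fruits with occlusion level below this are deemed
        sufficiently observable and dropped from the objective.
    iteration_threshold: max accepted ascent steps per restart.
    step_size: initial ascent step, meters (backtracking halves it).
    fd_step: central-difference step for the IG gradient, meters.
    ig_epsilon: floor on the occlusion level inside IG (caps the gain of a
        completely unobstructed fruit at 1/ig_epsilon).
    n_restarts / n_candidates: number of ascent starts, picked from this
        many seeded uniform probes of the region: the best-IG probe plus a
        farthest-point-dispersed subset, so restarts cover distinct basins
        instead of crowding the single best probe.
    """

    occlusion_threshold: float = 0.05
    iteration_threshold: int = 50
    step_size: float = 0.05
    fd_step: float = 1e-3
    ig_epsilon: float = 1e-3
    n_restarts: int = 4
    n_candidates: int = 32
    ni: int = DEFAULT_NI
    exclusion_factor: float = EXCLUSION_FACTOR
    seed: int = 0
    ig_tol: float = 1e-6
    min_step: float = 1e-4

    def __post_init__(self):
        if self.iteration_threshold < 1:
            raise ValueError("iteration_threshold must be >= 1")
        for name in ("occlusion_threshold", "step_size", "fd_step", "ig_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ViewCandidate:
    """A camera placement; orientation looks at the active fruit centroid."""

    position: np.ndarray
    orientation: RigidTransform

    def to_dict(self) -> dict:
        return self.orientation.to_dict()


@dataclass
class NBVResult:
    best_view: ViewCandidate
    ig: float
    ig_trace: list
    optimized_fruits: list
    remaining_fruits: list
    all_optimized: bool = False

    def to_dict(self) -> dict:
        return {
            "best_view": self.best_view.to_dict(),
            "ig": float(self.ig),
            "ig_trace": [float(v) for v in self.ig_trace],
            "optimized_fruits": [f.to_dict() for f in self.optimized_fruits],
            "remaining_fruits": [f.to_dict() for f in self.remaining_fruits],
            "all_optimized": bool(self.all_optimized),
        }


def _fruit_occlusions(
    position: np.ndarray,
    fruits: Sequence[FruitEstimate],
    field: GaussianField,
    cfg: PlannerConfig,
) -> np.ndarray:
    rays = [Ray.to_fruit(position, f.position, f.radius) for f in fruits]
    res = batch_occlusion(field, rays, cfg.ni, cfg.exclusion_factor)
    return np.array([r.I for r in res])


def information_gain(
    position,
    fruits: Sequence[FruitEstimate],
    field: GaussianField,
    cfg: PlannerConfig,
) -> float:
    """IG = sum over fruits of 1 / max(I_f, ig_epsilon)."""
    if len(fruits) == 0:
        raise ValueError("information gain needs a nonempty fruit set")
    I = _fruit_occlusions(_as_vec3(position), fruits, field, cfg)
    return float(np.sum(1.0 / np.maximum(I, cfg.ig_epsilon)))


def ig_gradient(
    position,
    fruits: Sequence[FruitEstimate],
    field: GaussianField,
    cfg: PlannerConfig,
) -> np.ndarray:
    """Central finite-difference gradient of IG w.r.t. camera position.

    Evaluated on the same fixed ni-point quadrature as IG itself, so the
    gradient is deterministic and consistent with the objective.
    """
    p = _as_vec3(position)
    g = np.zeros(3)
    for k in range(3):
        e = np.zeros(3)
        e[k] = cfg.fd_step
        g[k] = (
            information_gain(p + e, fruits, field, cfg)
            - information_gain(p - e, fruits, field, cfg)
        ) / (2 * cfg.fd_step)
    return g


def prune_fruits(
    fruits: Sequence[FruitEstimate],
    position,
    field: GaussianField,
    cfg: PlannerConfig,
):
    """Split fruits into (kept, popped): popped have I < occlusion_threshold
    from ``position`` and need no further views. Order is preserved."""
    fruits = list(fruits)
    if not fruits:
        return [], []
    I = _fruit_occlusions(_as_vec3(position), fruits, field, cfg)
    kept = [f for f, i in zip(fruits, I) if i >= cfg.occlusion_threshold]
    popped = [f for f, i in zip(fruits, I) if i < cfg.occlusion_threshold]
    return kept, popped


def _ascend(
    start: np.ndarray,
    fruits,
    field,
    region: ReachableRegion,
    cfg: PlannerConfig,
):
    """One projected-gradient ascent; returns (position, ig, trace)."""
    p = region.project(start)
    ig = information_gain(p, fruits, field, cfg)
    trace = [ig]
    for _ in range(cfg.iteration_threshold):
        g = ig_gradient(p, fruits, field, cfg)
        gnorm = np.linalg.norm(g)
        if gnorm < 1e-12:
            break
        direction = g / gnorm
        step = cfg.step_size
        accepted = False
        while step >= cfg.min_step:
            cand = region.project(p + step * direction)
            ig_cand = information_gain(cand, fruits, field, cfg)
            if ig_cand > ig:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        improved = ig_cand - ig
        p, ig = cand, ig_cand
        trace.append(ig)
        if improved < cfg.ig_tol:
            break
    return p, ig, trace


def plan_nbv(
    state: GlobalMap,
    cam_pose: RigidTransform,
    region: ReachableRegion,
    cfg: PlannerConfig,
) -> NBVResult:
    """Choose the next-best view for the fruits still under-optimized.

    From the current camera pose, fruits whose occlusion level is already
    below the threshold are popped as optimized. If any remain, IG is
    maximized over the reachable region by multi-start projected gradient
    ascent: ``n_candidates`` seeded uniform probes (plus the current
    position, if feasible) supply the starts — the best-IG probe and a
    farthest-point-dispersed subset — and the highest-IG ascent wins, ties
    broken by restart order.
    """
    position0 = cam_pose.translation
    kept, popped = prune_fruits(state.fruits, position0, state.field_, cfg)
    if not kept:
        centroid = (
            np.mean([f.position for f in popped], axis=0)
            if popped
            else position0 + np.array([0.0, 1.0, 0.0])
        )
        view = ViewCandidate(position0, look_at(position0, centroid))
        return NBVResult(view, 0.0, [], popped, [], all_optimized=True)

    rng = np.random.default_rng(cfg.seed)
    candidates = list(region.sample(rng, cfg.n_candidates))
    if region.contains(position0):
        candidates.append(position0)
    scores = [information_gain(c, kept, state.field_, cfg) for c in candidates]
    # the best-scoring probe seeds the first ascent; the rest are chosen by
    # farthest-point dispersion so the restarts cover distinct basins (the
    # probe IG itself is a poor predictor of where an ascent ends up)
    best_probe = min(range(len(candidates)), key=lambda i: (-scores[i], i))
    chosen = [best_probe]
    while len(chosen) < max(cfg.n_restarts, 1) and len(chosen) < len(candidates):
        dists = [
            min(np.linalg.norm(candidates[i] - candidates[j]) for j in chosen)
            for i in range(len(candidates))
        ]
        nxt = max(
            (i for i in range(len(candidates)) if i not in chosen),
            key=lambda i: (dists[i], -i),
        )
        chosen.append(nxt)
    starts = [candidates[i] for i in chosen]

    best = None
    for ridx, start in enumerate(starts):
        p, ig, trace = _ascend(start, kept, state.field_, region, cfg)
        if best is None or ig > best[1]:
            best = (p, ig, trace, ridx)

    p, ig, trace, _ = best
    centroid = np.mean([f.position for f in kept], axis=0)
    view = ViewCandidate(p, look_at(p, centroid))
    return NBVResult(view, ig, trace, popped, kept, all_optimized=False)
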