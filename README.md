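# orchardnbv

Occlusion-aware next-best-view (NBV) planning and multi-view 3D fruit
detection utilities for orchard robotics.

Harvesting robots must localize small fruits in heavy occlusion: foliage
and branches hide fruit from any single viewpoint, and image-based
detectors degrade exactly where accurate 3D positions matter most. A
practical remedy is to scan from several viewpoints and fuse the
detections — but extra views are expensive, so the robot should move its
camera to the viewpoint that is expected to reveal the most. This package
provides the geometric and planning machinery for that loop, for
roboticists and perception researchers who already have (or simulate) a
3D fruit detector:

- **Anisotropic Gaussian obstacle fields** — the scene cloud is voxelized
  and each occupied voxel becomes an unnormalized 3D Gaussian
  N(X) = exp(−½ (X−μ)ᵀ Σ⁻¹ (X−μ)) with Σ = R S Sᵀ Rᵀ, a differentiable
  soft-occupancy representation whose center value is always 1.
- **Ray-integral occlusion** — the occlusion level of a fruit from a view
  v is I(v) = ∫ i(X) dX along the camera→fruit ray, where
  i(X) = (1/n) Σ exp(−½ (X−μ)ᵀ Σ⁻¹ (X−μ)) is the mean Gaussian response
  (a collision index in [0, 1]); evaluated with a vectorized trapezoid
  rule over a (fruit × sample × gaussian × coordinate) tensor.
- **NBV planning** — information gain IG(v) = Σ_f 1/I_f(v) over the
  fruits still needing observation, maximized over the arm's reachable
  region by seeded multi-start projected gradient ascent; fruits whose
  occlusion level falls below a threshold are pruned as done.
- **Multi-view fusion** — detections b(x, y, z, l, h, w) are transformed
  to the world frame and reduced by greedy confidence-descending 3D NMS,
  so the most confident estimate of every physical fruit survives.
- **Losses and metrics** — the occlusion-aware detection loss
  L = (L_cls + L_reg + L_cntr + L_occ)/n_pos (focal + DIoU + centerness
  BCE + occlusion L1), the image-plane ground-truth occlusion ratio
  Ô = |A_fruit ∩ A_fore| / |A_fruit|, and AP/AR at 3D IoU thresholds.
- **Synthetic orchard scenes** — a seeded generator of fruit-and-foliage
  crowns with a z-buffer renderer (exact sample-level visibility and
  ground-truth occlusion ratios) and a noisy mock detector, so the whole
  planner/fusion/evaluation stack runs end-to-end with no trained network
  and no external data.
- **I/O and CLI** — PLY point clouds (ascii + binary little-endian),
  JSON scenes/fields/detections/maps, SUN-RGBD-style text labels, YAML
  configuration, and an `orchardnbv` command with subcommands
  `generate-scene`, `render`, `mock-detect`, `colorize`, `fit-gaussians`,
  `occlusion`, `fuse`, `plan`, `eval`, `losses`.

## Worked example

A fruit sits 1 m in front of the camera behind a wall of soft obstacles;
the planner finds a viewpoint inside the arm's reachable box that sees
around the wall:

```python
import numpy as np
from orchardnbv import (
    GaussianField, GaussianObstacle, FruitEstimate, GlobalMap,
    PlannerConfig, Ray, ReachableRegion, look_at, occlusion_level, plan_nbv,
)

fruit = FruitEstimate(position=[0.0, 0.0, 1.0], diameter=0.075)
wall = GaussianField([
    GaussianObstacle([x, -0.5, z], np.eye(3), [0.05, 0.05, 0.05])
    for x in np.arange(-0.3, 0.31, 0.1)
    for z in np.arange(0.7, 1.31, 0.1)
])

camera = np.array([0.0, -1.0, 1.0])
ray = Ray.to_fruit(camera, fruit.position, fruit.radius)
print(f"occlusion level from the initial view: {occlusion_level(wall, ray).I:.4f} m")

region = ReachableRegion(kind="box", lo=[-0.6, -1.0, 0.8], hi=[0.6, -0.6, 1.2])
cfg = PlannerConfig(occlusion_threshold=1e-3, seed=0)
result = plan_nbv(GlobalMap(fruits=[fruit], field_=wall),
                  look_at(camera, fruit.position), region, cfg)
p = result.best_view.position
print(f"next-best view: ({p[0]:.3f}, {p[1]:.3f}, {p[2]:.3f}) m")
print(f"information gain: {1/occlusion_level(wall, ray).I:.1f} -> {result.ig:.1f}")
```

prints

```
occlusion level from the initial view: 0.0041 m
next-best view: (-0.580, -0.675, 1.165) m
information gain: 241.9 -> 1000.0
```

The initial ray accumulates 0.0041 m of integrated obstacle occupancy
(IG ≈ 242). The planner moves the camera to the upper-left corner of the
reachable box, where the ray to the fruit clears the wall entirely and the
gain saturates at the unobstructed ceiling 1/ig_epsilon = 1000.

The same loop runs end-to-end on synthetic crowns:

```python
from orchardnbv.pipeline import experiment_config, multiview_trial

trial = multiview_trial(experiment_config(), seed=2, n_views=3)
print([f"{e * 1000:.1f} mm" for e in trial.mean_errors])  # per-view fused error
# ['8.2 mm', '6.5 mm', '6.4 mm']
```

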