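"""Synthetic RGB-D field scenes with full ground truth.

The simulator replaces the unavailable field data: it ray-casts a planar
loess ground (at distance ``h_c`` below / tilt ``alpha`` in front of the
camera) plus near-vertical cylindrical stalks rooted in that plane, and
emits everything a detector pipeline needs — RGB, depth (mm), per-pixel
true ground labels, instance masks, tight boxes, and the true 3D cutting
point of every stalk (its base centre). A configurable noisy binary
classifier stands in for the RPN softmax, with false positives
concentrated on ground-dominated anchors to mimic loess/stalk colour
confusion.

Stalks are finite cylinders perpendicular to the ground plane; occlusion
is resolved by nearest-hit ray casting. Depth noise is Gaussian in
millimetres, clipped at +-3 sigma. Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anchors import LabeledAnchor, ground_ratios
from .camera import CameraModel, default_camera
from .geometry import GROUND, INVALID, NON_GROUND, GroundMask
from .losses import pairwise_iou

#: colour statistics per weather / illumination condition. S = sunny,
#: O = sunny but overshadowed, C = cloudy, D = greenhouse daytime,
#: N = greenhouse nighttime. Sunlight washes out the loess/stalk colour
#: separation (S, O); O additionally casts a shadow band; N is dim.
CONDITIONS = {
    "S": dict(loess=(205, 190, 150), stalk=(125, 155, 100), noise=10.0, shadow=False, gain=1.0),
    "O": dict(loess=(205, 190, 150), stalk=(125, 155, 100), noise=10.0, shadow=True, gain=1.0),
    "C": dict(loess=(170, 155, 125), stalk=(80, 120, 60), noise=8.0, shadow=False, gain=0.9),
    "D": dict(loess=(180, 160, 125), stalk=(70, 115, 55), noise=6.0, shadow=False, gain=1.0),
    "N": dict(loess=(180, 160, 125), stalk=(70, 115, 55), noise=12.0, shadow=False, gain=0.45),
}


@dataclass(frozen=True)
class Stalk:
    """A finite cylinder rooted in the ground plane.

    ``base`` is the 3D centre of the bottom disk (metres, camera frame);
    the axis points away from the plane toward the camera side.
    """

    base: tuple[float, float, float]
    height: float
    radius: float


@dataclass
class SceneConfig:
    camera: CameraModel
    stalks: list[Stalk]
    depth_noise_sigma_mm: float = 2.0
    condition: str = "D"
    max_depth_m: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {sorted(CONDITIONS)}"
            )
        if self.depth_noise_sigma_mm < 0:
            raise ValueError("depth_noise_sigma_mm must be >= 0")
        a = self.camera.alpha
        for i, s in enumerate(self.stalks):
            x, _, z = s.base
            resid = z * math.sin(a) - x * math.cos(a) - self.camera.h_c
            if abs(resid) > 1e-6:
                raise ValueError(
                    f"stalk {i} base {s.base} is not on the ground plane (residual {resid:.2e} m)"
                )
            if s.height <= 0 or s.radius <= 0:
                raise ValueError(f"stalk {i} has nonpositive height or radius")
        bad = [i for i, s in enumerate(self.stalks) if not _stalk_in_frustum(s, self.camera)]
        if bad:
            raise ValueError(f"stalks outside the camera frustum: {bad}")


@dataclass
class Scene:
    """Rendered scene plus ground truth."""

    rgb: np.ndarray  # (H, W, 3) uint8
    depth_mm: np.ndarray  # (H, W) float64, 0 = invalid
    true_ground: np.ndarray  # (H, W) bool, noise-free ground membership
    instance_ids: np.ndarray  # (H, W) int, 0 = none, i >= 1 = stalk i-1
    boxes: np.ndarray  # (n_stalks, 4) tight boxes, half-open pixel coords
    cut_points: np.ndarray  # (n_stalks, 3) true stalk base centres, metres
    condition: str
    config: SceneConfig

    @property
    def n_stalks(self) -> int:
        return len(self.config.stalks)

    @property
    def masks(self) -> list[np.ndarray]:
        return [self.instance_ids == i + 1 for i in range(self.n_stalks)]

    def true_ground_mask(self) -> GroundMask:
        """Noise-free ground-truth labels packaged as a GroundMask."""
        labels = np.full(self.depth_mm.shape, INVALID, dtype=np.uint8)
        labels[self.depth_mm > 0] = NON_GROUND
        labels[self.true_ground] = GROUND
        return GroundMask(labels=labels, t_f=0.0)


def _plane_axis(camera: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Unit plane normal n (camera on the n.p < h_c side) and the
    up-from-plane stalk axis -n."""
    a = camera.alpha
    n = np.array([-math.cos(a), 0.0, math.sin(a)])
    return n, -n


def ground_point_at_depth(camera: CameraModel, z: float, y: float = 0.0) -> tuple[float, float, float]:
    """The on-plane 3D point with camera-frame depth z and lateral offset y."""
    a = camera.alpha
    x = (z * math.sin(a) - camera.h_c) / math.cos(a)
    return (x, y, z)


def _project(camera: CameraModel, p) -> tuple[float, float]:
    x, y, z = p
    return camera.cx + camera.fx * x / z, camera.cy + camera.fy * y / z


def _stalk_in_frustum(stalk: Stalk, camera: CameraModel, margin: float = 4.0) -> bool:
    _, axis = _plane_axis(camera)
    base = np.asarray(stalk.base)
    top = base + stalk.height * axis
    for p in (base, top):
        if p[2] <= 0.05:
            return False
        u, v = _project(camera, p)
        r_px = stalk.radius * camera.fx / p[2]
        if not (margin <= u - r_px and u + r_px < camera.width - margin):
            return False
        if not (margin <= v - r_px and v + r_px < camera.height - margin):
            return False
    return True


def _approx_projected_box(stalk: Stalk, camera: CameraModel, pad: float = 0.0):
    """Loose image-space bounding box of a stalk (base/top +- radius)."""
    _, axis = _plane_axis(camera)
    base = np.asarray(stalk.base)
    top = base + stalk.height * axis
    us, vs = [], []
    for p in (base, top):
        u, v = _project(camera, p)
        r_px = stalk.radius * camera.fx / p[2]
        us += [u - r_px, u + r_px]
        vs += [v - r_px, v + r_px]
    return (min(us) - pad, min(vs) - pad, max(us) + pad, max(vs) + pad)


def simulate_scene(config: SceneConfig) -> Scene:
    """Ray-cast the ground plane and stalk cylinders into an RGB-D scene.

    Depth stores the camera-frame z coordinate in millimetres (0 where no
    surface is hit within ``max_depth_m``). Ground-truth layers are
    computed from the noise-free geometry.
    """
    cam = config.camera
    rng = np.random.default_rng(config.seed)
    a = cam.alpha
    h, w = cam.height, cam.width

    dx = (np.arange(w, dtype=np.float64) - cam.cx)[None, :] / cam.fx
    dy = (np.arange(h, dtype=np.float64) - cam.cy)[:, None] / cam.fy
    dx = np.broadcast_to(dx, (h, w))
    dy = np.broadcast_to(dy, (h, w))

    # z-depth of each candidate surface along the ray p = z * (dx, dy, 1)
    big = np.inf
    denom = math.sin(a) - dx * math.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_ground = np.where(denom > 1e-9, cam.h_c / denom, big)
    z_ground = np.where((z_ground > 0) & (z_ground <= config.max_depth_m), z_ground, big)

    depth = z_ground.copy()
    label = np.where(np.isfinite(z_ground), 0, -1)  # 0 ground, -1 none, i>=1 stalk

    _, axis = _plane_axis(cam)
    for i, stalk in enumerate(config.stalks):
        b = np.asarray(stalk.base)
        # perpendicular (to the axis) components of ray direction and base
        d_dot_a = dx * axis[0] + dy * axis[1] + axis[2]
        dpx = dx - d_dot_a * axis[0]
        dpy = dy - d_dot_a * axis[1]
        dpz = 1.0 - d_dot_a * axis[2]
        b_dot_a = float(b @ axis)
        bp = b - b_dot_a * axis
        A = dpx * dpx + dpy * dpy + dpz * dpz
        B = -2.0 * (dpx * bp[0] + dpy * bp[1] + dpz * bp[2])
        C = float(bp @ bp) - stalk.radius**2
        disc = B * B - 4 * A * C
        hit = disc >= 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z1 = (-B - sq) / (2 * A)
            z2 = (-B + sq) / (2 * A)
        for zr in (z1, z2):  # nearer surface first; fall back for cap grazing
            s = zr * d_dot_a - b_dot_a  # height above the plane along the axis
            ok = hit & (zr > 0.05) & (s >= 0) & (s <= stalk.height) & (zr < depth)
            depth = np.where(ok, zr, depth)
            label = np.where(ok, i + 1, label)

    valid = np.isfinite(depth) & (label >= 0)
    depth_m = np.where(valid, depth, 0.0)

    true_ground = label == 0
    instance_ids = np.where(label > 0, label, 0).astype(np.int64)

    boxes = np.zeros((len(config.stalks), 4), dtype=np.float64)
    for i in range(len(config.stalks)):
        rr, cc = np.nonzero(instance_ids == i + 1)
        if len(rr) == 0:
            raise ValueError(f"stalk {i} is fully occluded and renders no pixel")
        boxes[i] = (cc.min(), rr.min(), cc.max() + 1, rr.max() + 1)

    depth_mm = depth_m * 1000.0
    if config.depth_noise_sigma_mm > 0:
        sigma = config.depth_noise_sigma_mm
        noise = np.clip(rng.normal(0.0, sigma, size=depth_mm.shape), -3 * sigma, 3 * sigma)
        depth_mm = np.where(valid, np.maximum(depth_mm + noise, 1.0), 0.0)

    rgb = _render_rgb(true_ground, instance_ids, valid, config, rng)
    cut_points = np.array([s.base for s in config.stalks], dtype=np.float64).reshape(-1, 3)
    return Scene(
        rgb=rgb,
        depth_mm=depth_mm,
        true_ground=true_ground,
        instance_ids=instance_ids,
        boxes=boxes,
        cut_points=cut_points,
        condition=config.condition,
        config=config,
    )


def _render_rgb(true_ground, instance_ids, valid, config: SceneConfig, rng) -> np.ndarray:
    p = CONDITIONS[config.condition]
    h, w = true_ground.shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    img[~valid] = (40, 45, 60)  # distant background
    img[true_ground] = p["loess"]
    img[instance_ids > 0] = p["stalk"]
    img += rng.normal(0.0, p["noise"], size=img.shape)
    if p["shadow"]:
        # multiplicative shadow band across a third of the image width
        c0 = int(0.3 * w + rng.integers(0, int(0.2 * w)))
        band = slice(c0, c0 + int(0.3 * w))
        img[:, band, :] *= 0.55
    img *= p["gain"]
    return np.clip(img, 0, 255).astype(np.uint8)


def random_scene_config(
    seed: int,
    n_stalks: int = 3,
    camera: CameraModel | None = None,
    depth_range: tuple[float, float] = (0.6, 1.4),
    height_range: tuple[float, float] = (0.15, 0.25),
    radius_range: tuple[float, float] = (0.012, 0.016),
    condition: str = "D",
    depth_noise_sigma_mm: float = 2.0,
    max_tries: int = 200,
) -> SceneConfig:
    """Sample a valid scene layout: stalk bases on the plane, inside the
    frustum, with realistic harvest-ready sizes (12-16 mm radius,
    15-25 cm height, thick 24-32 mm spears) at the configured depth range. Stalks are placed so
    that their projected silhouettes do not overlap (no mutual
    occlusion); explicit :class:`SceneConfig` construction remains
    available for occlusion studies."""
    cam = camera or default_camera()
    rng = np.random.default_rng(seed)
    stalks: list[Stalk] = []
    placed_boxes: list[tuple[float, float, float, float]] = []
    tries = 0
    while len(stalks) < n_stalks:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place stalks inside the frustum")
        z = rng.uniform(*depth_range)
        y = rng.uniform(-0.10, 0.10) * z
        stalk = Stalk(
            base=ground_point_at_depth(cam, z, y),
            height=float(rng.uniform(*height_range)),
            radius=float(rng.uniform(*radius_range)),
        )
        if not _stalk_in_frustum(stalk, cam):
            continue
        box = _approx_projected_box(stalk, cam, pad=max(2.0, cam.width / 80))
        if any(
            not (box[2] <= b[0] or b[2] <= box[0] or box[3] <= b[1] or b[3] <= box[1])
            for b in placed_boxes
        ):
            continue
        stalks.append(stalk)
        placed_boxes.append(box)
    return SceneConfig(
        camera=cam,
        stalks=stalks,
        depth_noise_sigma_mm=depth_noise_sigma_mm,
        condition=condition,
        seed=seed,
    )


@dataclass(frozen=True)
class ClassifierModel:
    """Surrogate for the RPN softmax.

    Anchors overlapping a true stalk box (IoU >= ``iou_positive``) are
    labelled positive with probability ``tp_rate``; ground-dominated
    anchors (true ground fraction >= 0.5) become false positives with
    probability ``loess_fp_rate`` (the loess/stalk colour-confusion
    model); everything else with probability ``other_fp_rate``.

    ``ref_height_px`` optionally models feature completeness: when set, a
    whole stalk is detectable with probability
    ``min(1, projected_length_px / ref_height_px)`` (drawn once per
    stalk), so small/distant stalks are missed more often. Default off.
    """

    tp_rate: float = 0.95
    loess_fp_rate: float = 0.05
    other_fp_rate: float = 0.001
    iou_positive: float = 0.15
    ref_height_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tp_rate", "loess_fp_rate", "other_fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def simulate_classifier_arrays(
    boxes: np.ndarray, scene: Scene, model: ClassifierModel
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised surrogate classifier.

    Returns (softmax_labels, scores) for an (N, 4) anchor array.
    Deterministic given ``model.seed`` (stalk-level detectability draws
    are seeded per stalk index, independent of the anchor set).
    """
    boxes = np.asarray(boxes, dtype=np.float64)
    n = len(boxes)
    rng = np.random.default_rng([int(model.seed), 7])

    rp_true = ground_ratios(boxes, scene.true_ground_mask())
    if scene.n_stalks > 0:
        ious = pairwise_iou(boxes, scene.boxes)
        best = ious.argmax(axis=1)
        best_iou = ious[np.arange(n), best]
    else:
        best = np.zeros(n, dtype=int)
        best_iou = np.zeros(n)

    detectable = np.ones(scene.n_stalks, dtype=bool)
    if model.ref_height_px is not None:
        for j in range(scene.n_stalks):
            x1, y1, x2, y2 = scene.boxes[j]
            length_px = max(x2 - x1, y2 - y1)
            p_det = min(1.0, length_px / model.ref_height_px)
            # one draw per stalk index: couples detectability across
            # scenes that share the classifier seed and stalk ordering
            u = np.random.default_rng([int(model.seed), 1000 + j]).uniform()
            detectable[j] = u < p_det

    if scene.n_stalks:
        is_true = (best_iou >= model.iou_positive) & detectable[best]
    else:
        is_true = np.zeros(n, dtype=bool)
    is_loess = (~is_true) & (np.nan_to_num(rp_true, nan=0.0) >= 0.5)
    p_pos = np.where(is_true, model.tp_rate, np.where(is_loess, model.loess_fp_rate, model.other_fp_rate))
    labels = (rng.uniform(size=n) < p_pos).astype(np.int64)
    u = rng.uniform(size=n)
    scores = np.where(labels == 1, 0.6 + 0.39 * u, 0.01 + 0.39 * u)
    return labels, scores


def simulate_classifier(
    boxes: np.ndarray, scene: Scene, model: ClassifierModel
) -> list[LabeledAnchor]:
    """Object-level wrapper around :func:`simulate_classifier_arrays`."""
    labels, scores = simulate_classifier_arrays(boxes, scene, model)
    return [
        LabeledAnchor(box=tuple(b), score=float(s), softmax_label=int(l))
        for b, s, l in zip(np.asarray(boxes, dtype=float), scores, labels)
    ]
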