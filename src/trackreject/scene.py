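"""Pinhole depth rendering and synthetic sequence generation.

The simulator stands in for real operating-room depth recordings: a rigid
target (an analytic primitive, default a sphere) moves smoothly in front of
a pinhole depth camera while two disruption types can occur — a partial or
total occlusion by a nearer slab, and a sudden displacement of the target.
Sensor noise follows the depth-camera model with per-pixel variance
``df·x² + bn`` plus independent pixel dropout.

Depth convention: a pixel value is the z-distance along the optical axis
(meters); pixels with no surface return carry NaN as the invalid marker.
Pixel indexing is 0-based, row ``i`` (height), column ``j`` (width).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import Pose, quat_multiply, quat_conjugate, quat_normalize, quat_identity

__all__ = [
    "INVALID",
    "CameraIntrinsics",
    "NoiseModel",
    "Sphere",
    "Box",
    "OcclusionEvent",
    "DisplacementEvent",
    "MotionModel",
    "ScenarioConfig",
    "SequenceRecord",
    "render_depth",
    "add_sensor_noise",
    "simulate_sequence",
    "occluder_for_coverage",
    "save_sequence",
    "load_sequence",
]

#: invalid-pixel sentinel in depth images
INVALID = np.nan


def is_valid(img: np.ndarray) -> np.ndarray:
    return np.isfinite(img)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera model plus the depth-sensor constants the filter needs.

    ``d_min``/``d_max`` bound the measurable depth range; ``df`` (depth
    factor, dimensionless) and ``bn`` (base noise, m²) parameterize the
    sensor's depth-dependent noise variance ``df·x² + bn``.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    d_min: float
    d_max: float
    df: float = 4e-6
    bn: float = 4e-6

    def __post_init__(self) -> None:
        if not (self.d_max > self.d_min > 0):
            raise ValueError("require d_max > d_min > 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")

    def ray_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ray direction components (u, v) with unit z."""
        j = np.arange(self.width, dtype=float)
        i = np.arange(self.height, dtype=float)
        u = (j[None, :] - self.cx) / self.fx * np.ones((self.height, 1))
        v = (i[:, None] - self.cy) / self.fy * np.ones((1, self.width))
        return u, v


@dataclass(frozen=True)
class NoiseModel:
    """Depth-sensor noise: variance ``df·x² + bn`` and pixel dropout."""

    df: float = 4e-6
    bn: float = 4e-6
    dropout_p: float = 0.0

    def __post_init__(self) -> None:
        if self.df < 0 or self.bn < 0 or not (0.0 <= self.dropout_p <= 1.0):
            raise ValueError("invalid noise parameters")


@dataclass(frozen=True)
class Sphere:
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in its body frame; ``extents`` are full side lengths."""

    extents: tuple[float, float, float]


def _rotate_vectors(q: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Rotate (...,3) vectors by the unit quaternion q."""
    vq = np.zeros(vec.shape[:-1] + (4,))
    vq[..., 1:] = vec
    out = quat_multiply(quat_multiply(q, vq), quat_conjugate(q))
    return out[..., 1:]


def _render_sphere(center: np.ndarray, radius: float, intr: CameraIntrinsics) -> np.ndarray:
    """Analytic ray-sphere z-depth for one sphere center (camera frame)."""
    u, v = intr.ray_grid()
    a = u * u + v * v + 1.0
    b = u * center[0] + v * center[1] + center[2]
    c = float(center @ center) - radius * radius
    disc = b * b - a * c
    hit = disc >= 0.0
    t = np.full(u.shape, INVALID)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    with np.errstate(invalid="ignore"):
        t_near = (b - sq) / a
        t_far = (b + sq) / a
        # camera inside/behind handling: take nearest positive root
        t_hit = np.where(t_near > 0, t_near, t_far)
        t = np.where(hit & (t_hit > 0), t_hit, INVALID)
    return t


def _render_box(pose_p: np.ndarray, pose_q: np.ndarray, extents: Sequence[float],
                intr: CameraIntrinsics) -> np.ndarray:
    """Slab-test ray-box z-depth for an oriented box."""
    u, v = intr.ray_grid()
    dirs = np.stack([u, v, np.ones_like(u)], axis=-1)  # (H,W,3)
    # transform rays into body frame
    q_inv = quat_conjugate(quat_normalize(pose_q))
    o = _rotate_vectors(q_inv, -pose_p[None, None, :])[0, 0]
    d = _rotate_vectors(q_inv, dirs)
    half = np.asarray(extents, dtype=float) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
        t1 = (-half - o) * inv
        t2 = (half - o) * inv
    tmin = np.max(np.minimum(t1, t2), axis=-1)
    tmax = np.min(np.maximum(t1, t2), axis=-1)
    hit = (tmax >= tmin) & (tmax > 0)
    t_hit = np.where(tmin > 0, tmin, tmax)
    return np.where(hit & (t_hit > 0), t_hit, INVALID)


def render_depth(
    target_shape,
    pose: Pose,
    intrinsics: CameraIntrinsics,
    occluder: Optional[tuple] = None,
    background_depth: Optional[float] = None,
) -> np.ndarray:
    """Render the z-depth image of a posed primitive.

    ``occluder`` is an optional ``(shape, Pose)`` pair rendered into the
    same frame; where both surfaces project to a pixel the nearer one wins.
    ``background_depth``, when given, fills otherwise-empty pixels with a
    constant-depth plane.  Pixels beyond ``d_max`` or nearer than ``d_min``
    are invalid.
    """
    def _one(shape, p: Pose) -> np.ndarray:
        if isinstance(shape, Sphere):
            return _render_sphere(p.p, shape.radius, intrinsics)
        if isinstance(shape, Box):
            return _render_box(p.p, p.q, shape.extents, intrinsics)
        raise TypeError(f"unsupported shape: {type(shape).__name__}")

    img = _one(target_shape, pose)
    if occluder is not None:
        occ_shape, occ_pose = occluder
        occ = _one(occ_shape, occ_pose)
        img = np.where(is_valid(occ) & (~is_valid(img) | (occ < img)), occ, img)
    if background_depth is not None:
        img = np.where(is_valid(img), img, background_depth)
    out_of_range = is_valid(img) & ((img < intrinsics.d_min) | (img > intrinsics.d_max))
    img = np.where(out_of_range, INVALID, img)
    return img


def add_sensor_noise(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator,
                     intrinsics: CameraIntrinsics) -> np.ndarray:
    """Perturb valid pixels with depth-dependent Gaussian noise and dropout.

    Each valid pixel gets zero-mean noise of variance ``df·x² + bn``, is
    clipped back into ``[d_min, d_max]``, and is independently invalidated
    with probability ``dropout_p``.
    """
    valid = is_valid(img)
    std = np.sqrt(noise.df * np.square(np.where(valid, img, 0.0)) + noise.bn)
    noisy = img + rng.normal(0.0, 1.0, img.shape) * std
    noisy = np.clip(noisy, intrinsics.d_min, intrinsics.d_max)
    noisy = np.where(valid, noisy, INVALID)
    if noise.dropout_p > 0:
        drop = rng.random(img.shape) < noise.dropout_p
        noisy = np.where(drop, INVALID, noisy)
    return noisy


def occluder_for_coverage(
    target_img: np.ndarray,
    fraction: float,
    intrinsics: CameraIntrinsics,
    occ_depth: float,
) -> Optional[tuple]:
    """Build a slab occluder covering ``fraction`` of the target's pixels.

    The occluder is a thin box at depth ``occ_depth`` (nearer than the
    target) sweeping in from the left of the target's footprint: its lateral
    extent is chosen so the requested fraction of currently rendered target
    pixels falls behind it.  Returns ``(Box, Pose)`` or None when the target
    is not visible or the fraction is 0.
    """
    if fraction <= 0:
        return None
    cols = np.where(is_valid(target_img))[1]
    if cols.size == 0:
        return None
    if fraction >= 1.0:
        x_left, x_right = -10.0, 10.0
    else:
        # the slab covers whole pixel columns; cut after the column whose
        # cumulative pixel fraction is closest to the requested coverage
        uniq, counts = np.unique(cols, return_counts=True)
        cum = np.cumsum(counts) / cols.size
        cut_col = uniq[int(np.argmin(np.abs(cum - fraction)))]
        j_left = uniq.min() - 1.0
        x_left = (j_left - 0.5 - intrinsics.cx) / intrinsics.fx * occ_depth
        x_right = (cut_col + 0.5 - intrinsics.cx) / intrinsics.fx * occ_depth
    width = max(x_right - x_left, 1e-6)
    center_x = 0.5 * (x_left + x_right)
    # tall enough to span the whole frame vertically
    shape = Box((width, 100.0, 1e-3))
    pose = Pose(p=np.array([center_x, 0.0, occ_depth]))
    return shape, pose


@dataclass(frozen=True)
class OcclusionEvent:
    start: int
    duration: int
    coverage: float
    occ_depth_offset: float = 0.15  # occluder sits this far in front of the target

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage fraction must lie in [0, 1]")
        if self.start < 0 or self.duration < 0:
            raise ValueError("occlusion event frames must be non-negative")

    def active(self, frame: int) -> bool:
        return self.start <= frame < self.start + self.duration


@dataclass(frozen=True)
class DisplacementEvent:
    frame: int
    translation: tuple[float, float, float]
    rotation: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("displacement frame must be non-negative")


@dataclass(frozen=True)
class MotionModel:
    """Smooth random-walk parameters for the ground-truth trajectory.

    Velocities follow an AR(1) walk ``v ← decay·v + N(0, diffusion²)`` so the
    target drifts smoothly rather than jittering frame to frame.
    """

    trans_diffusion: float = 0.001   # m/s kick per frame
    rot_diffusion: float = 0.004     # per quaternion component per frame
    decay: float = 0.95


@dataclass
class ScenarioConfig:
    n_frames: int
    target_shape: object = field(default_factory=lambda: Sphere(0.06))
    initial_position: tuple[float, float, float] = (0.0, 0.0, 0.6)
    motion: MotionModel = field(default_factory=MotionModel)
    occlusion_event: Optional[OcclusionEvent] = None
    displacement_event: Optional[DisplacementEvent] = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    background_depth: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for ev, name in ((self.occlusion_event, "occlusion"), (self.displacement_event, "displacement")):
            if ev is None:
                continue
            frame = ev.start if isinstance(ev, OcclusionEvent) else ev.frame
            if frame >= self.n_frames:
                raise ValueError(f"{name} event frame {frame} >= n_frames {self.n_frames}")


@dataclass
class SequenceRecord:
    """A rendered sequence with per-frame ground truth.

    ``depths`` is (T, H, W); ``positions`` (T, 3) and ``quaternions`` (T, 4)
    hold the ground-truth pose; ``timestamps`` increase by a constant dt.
    """

    depths: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray
    timestamps: np.ndarray
    occluded: np.ndarray  # bool per frame: occlusion event active

    def __len__(self) -> int:
        return self.depths.shape[0]

    def pose(self, t: int) -> Pose:
        return Pose(p=self.positions[t], q=self.quaternions[t])


def simulate_sequence(cfg: ScenarioConfig, intrinsics: CameraIntrinsics, dt: float) -> SequenceRecord:
    """Generate a depth sequence with ground truth, events and sensor noise.

    The ground-truth pose follows a smooth velocity random walk; at the
    displacement event the pose jumps by exactly the configured offset, and
    during the occlusion event a slab occluder hides the configured fraction
    of the target's rendered pixels.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_frames
    H, W = intrinsics.height, intrinsics.width
    depths = np.empty((T, H, W))
    positions = np.empty((T, 3))
    quaternions = np.empty((T, 4))
    occluded = np.zeros(T, dtype=bool)

    p = np.array(cfg.initial_position, dtype=float)
    q = quat_identity()
    v = np.zeros(3)
    w = np.zeros(4)
    m = cfg.motion
    for t in range(T):
        if t > 0:
            v = m.decay * v + rng.normal(0.0, m.trans_diffusion, 3)
            w = m.decay * w + rng.normal(0.0, m.rot_diffusion, 4)
            p = p + v * dt
            q = quat_normalize(q + 0.5 * quat_multiply(q, w) * dt)
        ev = cfg.displacement_event
        if ev is not None and t == ev.frame:
            p = p + np.asarray(ev.translation, dtype=float)
            q = quat_normalize(quat_multiply(q, np.asarray(ev.rotation, dtype=float)))
        positions[t] = p
        quaternions[t] = q

        pose = Pose(p=p, q=q)
        clean = render_depth(cfg.target_shape, pose, intrinsics,
                             background_depth=cfg.background_depth)
        occ = None
        oev = cfg.occlusion_event
        if oev is not None and oev.active(t):
            occluded[t] = True
            occ_depth = max(p[2] - oev.occ_depth_offset, intrinsics.d_min + 1e-3)
            target_only = render_depth(cfg.target_shape, pose, intrinsics)
            occ = occluder_for_coverage(target_only, oev.coverage, intrinsics, occ_depth)
        img = render_depth(cfg.target_shape, pose, intrinsics, occluder=occ,
                           background_depth=cfg.background_depth)
        depths[t] = add_sensor_noise(img, cfg.noise, rng, intrinsics)

    timestamps = np.arange(T, dtype=float) * dt
    return SequenceRecord(depths, positions, quaternions, timestamps, occluded)


def save_sequence(path: str | Path, seq: SequenceRecord, intrinsics: CameraIntrinsics,
                  cfg: ScenarioConfig, dt: float) -> None:
    """Write a sequence archive (.npz) plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        depths=seq.depths,
        positions=seq.positions,
        quaternions=seq.quaternions,
        timestamps=seq.timestamps,
        occluded=seq.occluded,
    )

    def _shape_meta(s):
        if isinstance(s, Sphere):
            return {"kind": "sphere", "radius": s.radius}
        return {"kind": "box", "extents": list(s.extents)}

    meta = {
        "dt": dt,
        "intrinsics": asdict(intrinsics),
        "noise": asdict(cfg.noise),
        "scenario": {
            "n_frames": cfg.n_frames,
            "target_shape": _shape_meta(cfg.target_shape),
            "initial_position": list(cfg.initial_position),
            "motion": asdict(cfg.motion),
            "occlusion_event": asdict(cfg.occlusion_event) if cfg.occlusion_event else None,
            "displacement_event": asdict(cfg.displacement_event) if cfg.displacement_event else None,
            "background_depth": cfg.background_depth,
            "seed": cfg.seed,
        },
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def load_sequence(path: str | Path) -> tuple[SequenceRecord, CameraIntrinsics, dict]:
    """Load a sequence archive; returns (record, intrinsics, metadata dict)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as z:
        seq = SequenceRecord(
            depths=z["depths"], positions=z["positions"], quaternions=z["quaternions"],
            timestamps=z["timestamps"], occluded=z["occluded"],
        )
    meta = json.loads(path.with_suffix(".json").read_text())
    intr = CameraIntrinsics(**meta["intrinsics"])
    return seq, intr, meta
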