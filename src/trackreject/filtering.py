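"""Particle-filter tracking core.

Each frame, K pose hypotheses (particles) are sampled around the previous
tracked pose by the constant-velocity motion model with Gaussian noise on
both velocities; each particle's expected depth image is rendered and scored
against the observation with a per-pixel mixture log-likelihood (uniform
random return + Gaussian sensor noise + truncated-exponential occlusion
term); the particle with the maximum image log-likelihood becomes the new
tracked pose.  All weight arithmetic stays in the log domain.

Per frame the filter also records the diagnostics later used by the reject
models: the maximum log-likelihood, the log-domain effective sample size,
and the mean and variance of the K log-weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .geometry import Pose, quat_multiply, quat_normalize, angular_difference
from .scene import CameraIntrinsics, SequenceRecord, Sphere, is_valid, render_depth

__all__ = [
    "FilterConfig",
    "FilterOutput",
    "TrackingTrace",
    "predict_particles",
    "pixel_log_likelihood",
    "particle_weight",
    "effective_sample_size",
    "filter_step",
    "track_sequence",
]


@dataclass(frozen=True)
class FilterConfig:
    """The seven tracker tunables plus the time step and occlusion rate.

    ``(n_trans, n_rot, vf, w_exp, w_gaus, w_uni, K)`` form the configuration
    vector recorded with every run.  ``n_trans``/``n_rot`` are noise standard
    deviations, ``vf`` the per-frame velocity decay, the three ``w_*`` the
    mixture weights of the observation model, ``K`` the particle count,
    ``lam`` the occlusion-exponential rate (1/m).
    """

    n_trans: float
    n_rot: float
    vf: float
    w_exp: float
    w_gaus: float
    w_uni: float
    K: int
    dt: float = 1.0 / 30.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("particle count K must be >= 1")
        if not (0.0 < self.vf <= 1.0):
            raise ValueError("velocity factor must lie in (0, 1]")
        if min(self.w_exp, self.w_gaus, self.w_uni) < 0:
            raise ValueError("mixture weights must be non-negative")
        if self.lam <= 0:
            raise ValueError("occlusion rate lam must be positive")

    def x_conf(self) -> np.ndarray:
        return np.array([self.n_trans, self.n_rot, self.vf,
                         self.w_exp, self.w_gaus, self.w_uni, float(self.K)])


@dataclass(frozen=True)
class FilterOutput:
    """Per-frame filter diagnostics (the 4-vector fed to the reject models)."""

    ll_max: float
    ess: float
    w_mean: float
    w_var: float
    tracked_pose: Pose

    def x_out(self) -> np.ndarray:
        return np.array([self.ll_max, self.ess, self.w_mean, self.w_var])


class Particles:
    """A population of K poses stored as packed arrays (sequence of Pose)."""

    def __init__(self, p: np.ndarray, q: np.ndarray, v_trans: np.ndarray, v_rot: np.ndarray):
        self.p, self.q, self.v_trans, self.v_rot = p, q, v_trans, v_rot

    def __len__(self) -> int:
        return self.p.shape[0]

    def __getitem__(self, k: int) -> Pose:
        return Pose(self.p[k], self.q[k], self.v_trans[k], self.v_rot[k])


def predict_particles(ref: Pose, cfg: FilterConfig, rng: np.random.Generator) -> Particles:
    """Sample K particles from the motion model around ``ref``.

    New velocities: ``v ← vf·v + ε·dt`` with ε Gaussian per component; the
    new position and orientation come from one backward-Euler step with the
    *new* velocities, the orientation being renormalized after the blend.
    """
    K = cfg.K
    v_trans = cfg.vf * ref.v_trans + rng.normal(0.0, cfg.n_trans, (K, 3)) * cfg.dt
    v_rot = cfg.vf * ref.v_rot + rng.normal(0.0, cfg.n_rot, (K, 4)) * cfg.dt
    p = ref.p + v_trans * cfg.dt
    q = quat_normalize(ref.q + 0.5 * quat_multiply(ref.q[None, :], v_rot) * cfg.dt)
    return Particles(p, q, v_trans, v_rot)


def _mixture_ll(x_o: np.ndarray, x_e: np.ndarray, o_valid: np.ndarray, e_valid: np.ndarray,
                cfg: FilterConfig, intr: CameraIntrinsics) -> np.ndarray:
    """Vectorized per-pixel mixture log-likelihood (broadcasts any shape)."""
    if cfg.w_uni <= 0 and cfg.w_gaus <= 0 and cfg.w_exp <= 0:
        raise ValueError("all mixture weights are zero: log-likelihood undefined")
    uni = cfg.w_uni / (intr.d_max - intr.d_min)
    xo = np.where(o_valid, x_o, 0.0)
    xe = np.where(e_valid, x_e, 1.0)
    var = intr.df * xe * xe + intr.bn
    gaus = cfg.w_gaus * np.exp(-0.5 * (xo - xe) ** 2 / var) / np.sqrt(2.0 * np.pi * var)
    lam = cfg.lam
    expo = cfg.w_exp * lam * np.exp(-lam * xo) / (1.0 - np.exp(-lam * xe))
    dens_case2 = uni + gaus + expo          # x_e >= x_o: occlusion possible
    dens_case3 = uni + gaus                 # x_e <  x_o
    dens = np.where(xe >= xo, dens_case2, dens_case3)
    dens = np.where(o_valid, dens, uni)     # case 4: invalid observation
    with np.errstate(divide="ignore"):
        ll = np.log(dens)
    return np.where(e_valid, ll, 0.0)       # case 1: invalid expectation


def pixel_log_likelihood(x_o: float, x_e: float, cfg: FilterConfig,
                         intr: CameraIntrinsics) -> float:
    """Log-likelihood (nats) that observed depth ``x_o`` fits expected ``x_e``.

    Four cases: an invalid expected pixel scores 0 (any observation fits the
    background); an observation at or nearer than the expectation adds a
    truncated-exponential occlusion term to the uniform+Gaussian mixture; a
    farther observation uses uniform+Gaussian only; an invalid observation
    falls back to the uniform density alone.  ``NaN`` encodes invalid.
    """
    xo = np.asarray(np.nan if x_o is None else float(x_o))
    xe = np.asarray(np.nan if x_e is None else float(x_e))
    return float(_mixture_ll(xo, xe, np.isfinite(xo), np.isfinite(xe), cfg, intr))


def particle_weight(observed: np.ndarray, expected: np.ndarray, cfg: FilterConfig,
                    intr: CameraIntrinsics) -> float:
    """Image log-weight: the sum of per-pixel log-likelihoods."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError(f"image shape mismatch: {observed.shape} vs {expected.shape}")
    ll = _mixture_ll(observed, expected, is_valid(observed), is_valid(expected), cfg, intr)
    return float(ll.sum())


def effective_sample_size(log_weights: np.ndarray) -> float:
    """Log-domain effective sample size of a log-weight vector.

    Normalizes via log-sum-exp and returns ``−ln Σ exp(2·w̃)``, the natural
    log of the classic ESS ``1/Σ pᵢ²``; lies in ``[0, ln K]`` and equals
    ``ln K`` exactly for uniform weights.
    """
    lw = np.asarray(log_weights, dtype=float)
    if lw.size == 0:
        raise ValueError("effective_sample_size requires at least one weight")
    norm = lw - logsumexp(lw)
    return float(-logsumexp(2.0 * norm))


def _render_sphere_stack(centers: np.ndarray, radius: float, intr: CameraIntrinsics,
                         u: Optional[np.ndarray] = None,
                         v: Optional[np.ndarray] = None) -> np.ndarray:
    """Render K sphere-expected images at once over the (sub)grid (u, v)."""
    if u is None or v is None:
        u, v = intr.ray_grid()
    shape = u.shape
    a = (u * u + v * v + 1.0).ravel()                      # (P,)
    b = (centers[:, 0, None] * u.ravel() + centers[:, 1, None] * v.ravel()
         + centers[:, 2, None])                            # (K, P)
    c = np.einsum("ij,ij->i", centers, centers) - radius * radius  # (K,)
    disc = b * b - a[None, :] * c[:, None]
    hit = disc >= 0.0
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t_near = (b - sq) / a[None, :]
        t_far = (b + sq) / a[None, :]
        t_hit = np.where(t_near > 0, t_near, t_far)
        t = np.where(hit & (t_hit > 0), t_hit, np.nan)
        t = np.where((t >= intr.d_min) & (t <= intr.d_max), t, np.nan)
    return t.reshape((centers.shape[0],) + shape)


def _sphere_footprint_bbox(centers: np.ndarray, radius: float,
                           intr: CameraIntrinsics) -> Optional[tuple[int, int, int, int]]:
    """Pixel bbox (i0, i1, j0, j1) containing every particle's silhouette.

    Pixels outside the union of silhouettes have an invalid expected depth
    for every particle and contribute exactly zero to every weight, so
    restricting the likelihood to this box is lossless.  Returns None when
    the geometry is degenerate (sphere touching/behind the camera) and the
    full frame must be used.
    """
    cz = centers[:, 2]
    if np.any(cz - radius <= 1e-3):
        return None
    # conservative projected extent: lateral offset ± radius at nearest depth
    z_near = cz - radius
    j_lo = np.floor((centers[:, 0] - radius) / z_near * intr.fx + intr.cx).min() - 1
    j_hi = np.ceil((centers[:, 0] + radius) / z_near * intr.fx + intr.cx).max() + 1
    i_lo = np.floor((centers[:, 1] - radius) / z_near * intr.fy + intr.cy).min() - 1
    i_hi = np.ceil((centers[:, 1] + radius) / z_near * intr.fy + intr.cy).max() + 1
    i0 = int(np.clip(i_lo, 0, intr.height))
    i1 = int(np.clip(i_hi + 1, 0, intr.height))
    j0 = int(np.clip(j_lo, 0, intr.width))
    j1 = int(np.clip(j_hi + 1, 0, intr.width))
    return i0, i1, j0, j1


def _sphere_weights(observed: np.ndarray, centers: np.ndarray, radius: float,
                    cfg: FilterConfig, intr: CameraIntrinsics) -> np.ndarray:
    """Image log-weights of K sphere particles against one observation."""
    bbox = _sphere_footprint_bbox(centers, radius, intr)
    u, v = intr.ray_grid()
    if bbox is not None:
        i0, i1, j0, j1 = bbox
        if i0 >= i1 or j0 >= j1:  # footprint fully off-frame: all-invalid expectation
            return np.zeros(centers.shape[0])
        u, v = u[i0:i1, j0:j1], v[i0:i1, j0:j1]
        observed = observed[i0:i1, j0:j1]
    stack = _render_sphere_stack(centers, radius, intr, u, v)
    ll = _mixture_ll(observed[None, ...], stack,
                     is_valid(observed)[None, ...], is_valid(stack), cfg, intr)
    return ll.sum(axis=(1, 2))


def filter_step(ref: Pose, observation: np.ndarray, cfg: FilterConfig,
                intr: CameraIntrinsics, target_shape, rng: np.random.Generator,
                ) -> tuple[Pose, FilterOutput]:
    """One prediction/weighting/selection cycle.

    Renders an expected image per particle, scores each against the
    observation, and adopts the argmax-weight particle (lowest index wins a
    tie).  Sphere targets take a fully vectorized path; other shapes render
    per particle.
    """
    parts = predict_particles(ref, cfg, rng)
    if isinstance(target_shape, Sphere):
        # sphere silhouette ignores orientation: render all K at once,
        # restricted to the union footprint (exact, see _sphere_footprint_bbox)
        weights = _sphere_weights(observation, parts.p, target_shape.radius, cfg, intr)
    else:
        weights = np.empty(len(parts))
        for k in range(len(parts)):
            exp_img = render_depth(target_shape, parts[k], intr)
            weights[k] = particle_weight(observation, exp_img, cfg, intr)
    best = int(np.argmax(weights))
    out = FilterOutput(
        ll_max=float(weights[best]),
        ess=effective_sample_size(weights),
        w_mean=float(np.mean(weights)),
        w_var=float(np.var(weights)),
        tracked_pose=parts[best],
    )
    return parts[best], out


@dataclass
class TrackingTrace:
    """Per-frame filter diagnostics plus the tracking-error labels.

    ``delta`` is the Euclidean distance (m) and ``alpha`` the quaternion
    angle (rad) between the tracked pose and the ground truth.
    """

    ll_max: np.ndarray
    ess: np.ndarray
    w_mean: np.ndarray
    w_var: np.ndarray
    delta: np.ndarray
    alpha: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray

    def __len__(self) -> int:
        return self.ll_max.shape[0]

    def x_out(self) -> np.ndarray:
        """(T, 4) array of (ll_max, ess, w_mean, w_var)."""
        return np.stack([self.ll_max, self.ess, self.w_mean, self.w_var], axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "frame": np.arange(len(self)),
            "ll_max": self.ll_max, "ess": self.ess,
            "w_mean": self.w_mean, "w_var": self.w_var,
            "delta": self.delta, "alpha": self.alpha,
        }
        for i, c in enumerate("xyz"):
            d[f"p_{c}"] = self.positions[:, i]
        for i, c in enumerate("wxyz"):
            d[f"q_{c}"] = self.quaternions[:, i]
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackingTrace":
        return cls(
            ll_max=df["ll_max"].to_numpy(), ess=df["ess"].to_numpy(),
            w_mean=df["w_mean"].to_numpy(), w_var=df["w_var"].to_numpy(),
            delta=df["delta"].to_numpy(), alpha=df["alpha"].to_numpy(),
            positions=df[["p_x", "p_y", "p_z"]].to_numpy(),
            quaternions=df[["q_w", "q_x", "q_y", "q_z"]].to_numpy(),
        )


def track_sequence(seq: SequenceRecord, cfg: FilterConfig, intr: CameraIntrinsics,
                   target_shape, init: Optional[Pose] = None,
                   rng: Optional[np.random.Generator] = None) -> TrackingTrace:
    """Run the filter over a whole sequence and score it against ground truth.

    ``init`` defaults to the ground-truth pose of frame 0 with zero
    velocities (the manual initialization).  Per frame the trace records the
    filter diagnostics plus δ (position error, m) and α (angle error, rad).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    T = len(seq)
    trace = TrackingTrace(*(np.empty(T) for _ in range(6)),
                          positions=np.empty((T, 3)), quaternions=np.empty((T, 4)))
    if T == 0:
        return trace
    ref = init.copy() if init is not None else seq.pose(0)
    for t in range(T):
        ref, out = filter_step(ref, seq.depths[t], cfg, intr, target_shape, rng)
        trace.ll_max[t] = out.ll_max
        trace.ess[t] = out.ess
        trace.w_mean[t] = out.w_mean
        trace.w_var[t] = out.w_var
        trace.delta[t] = float(np.linalg.norm(ref.p - seq.positions[t]))
        trace.alpha[t] = angular_difference(ref.q, seq.quaternions[t])
        trace.positions[t] = ref.p
        trace.quaternions[t] = ref.q
    return trace
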