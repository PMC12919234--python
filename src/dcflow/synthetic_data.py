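"""Synthetic trajectory generators with known low-dimensional structure.

Three desk-scale generators:

* :func:`make_ball_videos` — grayscale videos of a soft-edged ball orbiting
  counterclockwise; a one-dimensional periodic latent (the orbit angle)
  embedded nonlinearly in pixel space.
* :func:`make_embedded_oscillator` — a planar harmonic rotation embedded in
  a high-dimensional ambient space by a random orthonormal map plus
  isotropic Gaussian noise; intrinsic dimension 2 by construction.
* :func:`make_constant_shift` — trajectories translated by a fixed vector
  each step; the unique optimal dynamical velocity field is that constant.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .data import TrajectorySet


@dataclass
class BallVideoConfig:
    """Rotating-ball video simulation.

    One video covers exactly one orbit period (``angular_step`` defaults to
    2*pi/n_frames), so the underlying latent trajectory is a closed loop.
    "Counterclockwise" is meant in standard mathematical orientation with
    the image y-axis pointing up (row index decreasing).
    """

    n_videos: int = 10
    n_frames: int = 50
    side: int = 28
    radius_px: float = 3.0
    orbit_radius_px: float = 8.0
    angular_step: float | None = None  # default: 2*pi / n_frames
    edge_px: float = 1.0               # anti-aliasing falloff width
    seed: int = 0

    def step(self) -> float:
        return (2.0 * np.pi / self.n_frames
                if self.angular_step is None else self.angular_step)


@dataclass
class OscillatorConfig:
    """Planar rotation embedded in D ambient dimensions."""

    ambient_dim: int = 20
    latent_dim: int = 2
    angular_frequency: float = 2.0 * np.pi / 50.0  # radians per step
    radius: float = 1.0
    noise_sd: float = 0.05
    n_traj: int = 20
    n_steps: int = 50
    seed: int = 0


def _render_ball(side: int, cx: float, cy: float, radius: float,
                 edge: float) -> np.ndarray:
    """Anti-aliased disk: intensity 1 inside, linear falloff over `edge` px.

    `cy` is in y-up coordinates; row index = side-1 - y.
    """
    ys = np.arange(side)[:, None]          # row index, top = 0
    xs = np.arange(side)[None, :]
    y_up = (side - 1) - ys
    dist = np.sqrt((xs - cx) ** 2 + (y_up - cy) ** 2)
    img = np.clip((radius + edge / 2.0 - dist) / edge, 0.0, 1.0)
    return img.astype(np.float32)


def make_ball_videos(cfg: BallVideoConfig | None = None) -> TrajectorySet:
    """Render videos of a ball orbiting counterclockwise about frame center."""
    cfg = cfg or BallVideoConfig()
    center = (cfg.side - 1) / 2.0
    reach = cfg.orbit_radius_px + cfg.radius_px + cfg.edge_px / 2.0
    if reach > center:
        raise ValueError(
            f"ball leaves the frame: orbit+radius+edge/2 = {reach:.2f} px "
            f"exceeds half-side {center:.2f} px")
    rng = np.random.default_rng(cfg.seed)
    step = cfg.step()
    frames = np.empty((cfg.n_videos, cfg.n_frames, cfg.side * cfg.side),
                      dtype=np.float32)
    for v in range(cfg.n_videos):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for t in range(cfg.n_frames):
            ang = phase + t * step          # increasing angle = counterclockwise
            cx = center + cfg.orbit_radius_px * np.cos(ang)
            cy = center + cfg.orbit_radius_px * np.sin(ang)
            frames[v, t] = _render_ball(cfg.side, cx, cy, cfg.radius_px,
                                        cfg.edge_px).ravel()
    meta = {"generator": "ball_videos", **{k: (v if not isinstance(v, float) else float(v))
                                           for k, v in asdict(cfg).items()}}
    return TrajectorySet(frames, dt=1.0, frame_shape=(cfg.side, cfg.side), meta=meta)


def random_orthonormal(d: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random D x k matrix with orthonormal columns (QR of a Gaussian)."""
    a = rng.standard_normal((d, k))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diagonal(r))[None, :]).astype(np.float64)


def make_embedded_oscillator(cfg: OscillatorConfig | None = None) -> TrajectorySet:
    """Noisy planar rotation embedded in ambient space by an orthonormal map."""
    cfg = cfg or OscillatorConfig()
    if cfg.latent_dim != 2:
        raise ValueError("oscillator latent dimension is 2 (planar rotation)")
    rng = np.random.default_rng(cfg.seed)
    embed = random_orthonormal(cfg.ambient_dim, cfg.latent_dim, rng)
    omega = cfg.angular_frequency
    data = np.empty((cfg.n_traj, cfg.n_steps, cfg.ambient_dim), dtype=np.float32)
    for i in range(cfg.n_traj):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(cfg.n_steps)
        z = cfg.radius * np.stack([np.cos(phase + omega * t),
                                   np.sin(phase + omega * t)], axis=1)
        x = z @ embed.T
        x = x + rng.normal(scale=cfg.noise_sd, size=x.shape)
        data[i] = x.astype(np.float32)
    meta = {"generator": "embedded_oscillator",
            **{k: float(v) if isinstance(v, float) else v
               for k, v in asdict(cfg).items()}}
    ts = TrajectorySet(data, dt=1.0, meta=meta)
    ts.meta["embedding"] = embed.tolist()
    return ts


def make_constant_shift(ambient_dim: int, w: np.ndarray, n_traj: int = 8,
                        n_steps: int = 20, seed: int = 0,
                        start_scale: float = 1.0) -> TrajectorySet:
    """Trajectories advancing by the fixed vector `w` every step, exactly."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (ambient_dim,):
        raise ValueError("shift vector must have length ambient_dim")
    rng = np.random.default_rng(seed)
    starts = rng.normal(scale=start_scale, size=(n_traj, ambient_dim))
    steps = np.arange(n_steps)[None, :, None]
    data = starts[:, None, :] + steps * w[None, None, :]
    return TrajectorySet(data.astype(np.float32), dt=1.0,
                         meta={"generator": "constant_shift",
                               "w": w.tolist(), "seed": seed})
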