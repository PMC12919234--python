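"""Learnable velocity fields for the compressive and dynamical flows.

``u(x, tau)`` estimates the compression velocity d/dtau of a state;
``v(x, tau, s, hist)`` estimates the physical-time velocity d/dt at
compression level tau, within-step time s, optionally conditioned on a
lag-h history at the same tau.  Scalar conditioners enter through
sinusoidal embeddings added at every block; output heads are
zero-initialized so untrained fields return the zero velocity.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat
from .nn import ConditionedMLP, ConvUNet, Module, SinusoidalEmbedding


class VelocityField(Module):
    """A parametric map (state, conditioning) -> velocity in ambient space.

    Parameters
    ----------
    kind
        ``"compressive"`` (conditioned on tau) or ``"dynamical"``
        (conditioned on tau, s and an optional lag-h history).
    arch
        ``"mlp"`` for flat data or ``"conv_multiscale"`` for square frames.
    ambient_dim
        Ambient dimension D (= side**2 for conv).
    history_len
        Lag h; 0 disables history conditioning (dynamical fields only).
    """

    def __init__(self, kind: str, ambient_dim: int, rng: np.random.Generator,
                 arch: str = "mlp", width: int = 256, depth: int = 4,
                 channels: tuple[int, ...] = (32, 64, 128),
                 bottleneck: int = 256, side: int | None = None,
                 history_len: int = 0, emb_dim: int = 32):
        if kind not in ("compressive", "dynamical"):
            raise ValueError(f"unknown field kind {kind!r}")
        if arch not in ("mlp", "conv_multiscale"):
            raise ValueError(f"unknown field architecture {arch!r}")
        if kind == "compressive" and history_len:
            raise ValueError("compressive fields take no history")
        self.kind, self.arch = kind, arch
        self.ambient_dim = ambient_dim
        self.history_len = history_len
        self.emb = SinusoidalEmbedding(emb_dim)
        n_scalars = 1 if kind == "compressive" else 2
        cond_dim = emb_dim * n_scalars
        if arch == "mlp":
            self.net = ConditionedMLP(
                ambient_dim * (1 + history_len), ambient_dim, rng,
                width=width, depth=depth, cond_dim=cond_dim,
                zero_init_head=True)
        else:
            if side is None:
                side = int(round(np.sqrt(ambient_dim)))
            if side * side != ambient_dim:
                raise ValueError("conv fields require ambient_dim = side**2")
            self.side = side
            self.net = ConvUNet(side, rng, channels=channels,
                                cond_dim=cond_dim, c_in=1 + history_len,
                                c_out=1, bottleneck=bottleneck)

    # ------------------------------------------------------------- forward
    def _conditioning(self, tau, s, n: int) -> np.ndarray:
        tau = np.broadcast_to(np.asarray(tau, dtype=np.float32).reshape(-1), (n,))
        if np.any((tau < 0) | (tau > 1)):
            raise ValueError("tau must lie in [0, 1]")
        parts = [self.emb(tau)]
        if self.kind == "dynamical":
            if s is None:
                raise ValueError("dynamical field requires s")
            s = np.broadcast_to(np.asarray(s, dtype=np.float32).reshape(-1), (n,))
            if np.any((s < 0) | (s > 1)):
                raise ValueError("s must lie in [0, 1]")
            parts.append(self.emb(s))
        return np.concatenate(parts, axis=1)

    def __call__(self, x: Tensor, tau, s=None, hist: Tensor | None = None
                 ) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite state passed to velocity field")
        n = x.shape[0]
        cond = self._conditioning(tau, s, n)
        if self.history_len:
            if hist is None:
                raise ValueError(f"field expects a lag-{self.history_len} history")
            if not isinstance(hist, Tensor):
                hist = Tensor(np.asarray(hist, dtype=np.float32))
            if hist.shape != (n, self.history_len, self.ambient_dim):
                raise ValueError(
                    f"history shape {hist.shape} != "
                    f"{(n, self.history_len, self.ambient_dim)}")
            inp = concat([x, hist.reshape(n, self.history_len * self.ambient_dim)],
                         axis=1)
        else:
            if hist is not None and np.asarray(
                    hist.data if isinstance(hist, Tensor) else hist).size:
                raise ValueError("field configured with h=0 but history given")
            inp = x
        return self.net(inp, cond)


def eval_compressive(field: VelocityField, x: np.ndarray, tau: float
                     ) -> np.ndarray:
    """Single-state compressive velocity estimate u(x, tau)."""
    out = field(Tensor(np.asarray(x, dtype=np.float32)[None]),
                np.array([tau]))
    return out.data[0]


def eval_dynamical(field: VelocityField, x: np.ndarray, tau: float, s: float,
                   hist: np.ndarray | None = None) -> np.ndarray:
    """Single-state dynamical velocity estimate v(x, tau, s, hist)."""
    h = None
    if field.history_len:
        h = Tensor(np.asarray(hist, dtype=np.float32)[None])
    out = field(Tensor(np.asarray(x, dtype=np.float32)[None]),
                np.array([tau]), np.array([s]), h)
    return out.data[0]
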