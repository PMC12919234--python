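"""Conditional probability paths (bridges) and their target velocities.

Two linear bridges drive training:

* the compressive tau-bridge between an encoded point ``x^(0)`` and its data
  point ``x^(1)``, with constant target velocity ``x^(1) - x^(0)``;
* the dynamical double-interpolation bridge: consecutive frames are first
  tau-bridged at the *same* compression level, then linearly interpolated in
  the within-step time ``s``, with constant target velocity
  ``(x_{k+1}^(tau) - x_k^(tau)) / dt``.

All functions are generic over plain arrays and autodiff Tensors, and over
single vectors or batches (interpolants may be per-row column vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor


@dataclass
class BridgeSample:
    """One training tuple for either bridge."""

    x_start: np.ndarray
    x_end: np.ndarray
    tau: float
    x_interp: np.ndarray
    target_velocity: np.ndarray
    s: float | None = None             # dynamical bridge only
    history: np.ndarray | None = None  # (h, D), oldest first
    dt: float = 1.0


def _check_unit(name: str, value) -> None:
    v = np.asarray(value.data if isinstance(value, Tensor) else value)
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")


def compressive_bridge(x0, x1, tau):
    """Linear tau-bridge (1 - tau) x^(0) + tau x^(1)."""
    _check_unit("tau", tau)
    return (1.0 - tau) * x0 + tau * x1


def compressive_target(x0, x1):
    """Constant compressive target velocity d/dtau of the bridge: x1 - x0."""
    return x1 - x0


def dynamical_bridge(xk_tau, xk1_tau, s):
    """Within-step interpolation between consecutive frames at equal tau."""
    _check_unit("s", s)
    return (1.0 - s) * xk_tau + s * xk1_tau


def dynamical_target(xk_tau, xk1_tau, dt: float):
    """Constant dynamical target velocity (x_{k+1}^(tau) - x_k^(tau)) / dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (xk1_tau - xk_tau) / dt


def history_at_tau(traj: np.ndarray, encoded: np.ndarray, k: int, h: int,
                   tau: float) -> np.ndarray:
    """Lag-h history frames, each tau-bridged at the same compression level.

    Rows are ordered oldest-first: frames k-h, ..., k-1.  Training samples
    must satisfy ``k >= h``; there is no boundary padding.
    """
    if h < 0:
        raise ValueError("history length h must be nonnegative")
    if k < h:
        raise ValueError(f"index k={k} has incomplete lag-{h} history")
    if h == 0:
        return np.empty((0, np.asarray(traj).shape[-1]), dtype=np.float64)
    idx = np.arange(k - h, k)
    return compressive_bridge(np.asarray(encoded)[idx], np.asarray(traj)[idx], tau)
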