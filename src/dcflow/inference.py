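"""Neural-ODE inference: flowed compression, simulated rollouts, summaries.

The learned fields are integrated with the adaptive embedded Runge–Kutta
4(5) scheme with Dormand–Prince coefficients (SciPy's ``RK45``), in float64.
Two representation modes:

* *flowed*: each observed frame is compressed pointwise to level tau by
  integrating the compressive flow from tau = 1 (backwards in tau);
* *simulated*: an initial frame is compressed, then rolled forward in time
  at fixed tau by integrating the dynamical flow over the within-step
  coordinate s in [0, 1], with velocities scaled by dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._autodiff import Tensor
from .encoder import effective_dimension, latent_coordinates, project_velocity


@dataclass
class IntegratorConfig:
    """Adaptive RK45 (Dormand–Prince) settings."""

    rtol: float = 1e-5
    atol: float = 1e-5
    max_steps: int = 10_000

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")


@dataclass
class LatentSummary:
    """Latent coordinates, projected velocities and effective dimension."""

    mu: np.ndarray                 # (T, M)
    mu_dot: np.ndarray | None      # (T, M) or None
    k_eff: int
    mode: str                      # "flowed" | "simulated"
    d_scales: np.ndarray = field(default_factory=lambda: np.empty(0))


class IntegrationError(RuntimeError):
    """Adaptive stepping failed; carries the partial solution."""

    def __init__(self, message: str, partial: np.ndarray | None = None,
                 frame_index: int | None = None):
        self.partial = partial
        self.frame_index = frame_index
        super().__init__(message)


def integrate(field_fn, x_init: np.ndarray, span: tuple[float, float],
              cfg: IntegratorConfig | None = None) -> np.ndarray:
    """Solve dx/dxi = field_fn(x, xi) from span[0] to span[1] (either order).

    ``field_fn`` maps (state vector, scalar coordinate) -> velocity vector.
    State and arithmetic are float64; local error is controlled by
    (rtol, atol).
    """
    cfg = cfg or IntegratorConfig()
    x_init = np.asarray(x_init, dtype=np.float64)
    if not np.all(np.isfinite(x_init)):
        raise ValueError("non-finite initial state")
    a, b = span
    if a == b:
        return x_init.copy()
    shape = x_init.shape
    nfev = 0

    def rhs(t, y):
        nonlocal nfev
        nfev += 1
        if nfev > cfg.max_steps * 7:  # 6 stages + FSAL reuse per step
            raise _StepBudgetExceeded(y)
        return np.asarray(field_fn(y.reshape(shape), t),
                          dtype=np.float64).ravel()

    try:
        sol = solve_ivp(rhs, (a, b), x_init.ravel(), method="RK45",
                        rtol=cfg.rtol, atol=cfg.atol, dense_output=False)
    except _StepBudgetExceeded as exc:
        raise IntegrationError(
            f"step budget exceeded ({cfg.max_steps} steps)",
            partial=exc.y.reshape(shape)) from None
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}",
                               partial=sol.y[:, -1].reshape(shape))
    return sol.y[:, -1].reshape(shape)


class _StepBudgetExceeded(Exception):
    def __init__(self, y):
        self.y = y


# ----------------------------------------------------------------- flowed

def _u_batch(model, x: np.ndarray, tau: float) -> np.ndarray:
    out = model.u_field(Tensor(np.asarray(x, dtype=np.float32)),
                        np.full(len(x), np.clip(tau, 0.0, 1.0)))
    return out.data.astype(np.float64)


def compress_flowed(frames: np.ndarray, model, tau_target: float,
                    cfg: IntegratorConfig | None = None) -> np.ndarray:
    """Compress each frame independently from tau = 1 to ``tau_target``
    along the learned compressive flow.

    The result is the *flowed* representation, which may differ from the
    encoder endpoint: the flow transports the data marginal, it does not
    reproduce the encoder pointwise.
    """
    if not (0.0 <= tau_target <= 1.0):
        raise ValueError("tau_target must lie in [0, 1]")
    frames = np.asarray(frames, dtype=np.float64)
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        try:
            out[i] = integrate(lambda x, t: _u_batch(model, x[None], t)[0],
                               frame, (1.0, tau_target), cfg)
        except IntegrationError as exc:
            raise IntegrationError(
                f"compressive integration failed on frame {i}: {exc}",
                partial=exc.partial, frame_index=i) from exc
    return out


def decompress_flowed(states: np.ndarray, model, tau_start: float = 0.0,
                      cfg: IntegratorConfig | None = None) -> np.ndarray:
    """Integrate the compressive flow upward from ``tau_start`` to tau = 1."""
    states = np.asarray(states, dtype=np.float64)
    out = np.empty_like(states)
    for i, x in enumerate(states):
        out[i] = integrate(lambda y, t: _u_batch(model, y[None], t)[0],
                           x, (tau_start, 1.0), cfg)
    return out


# --------------------------------------------------------------- simulated

def simulate_rollout(x0_frame: np.ndarray, model, tau: float, n_steps: int,
                     cfg: IntegratorConfig | None = None,
                     history_init: np.ndarray | None = None,
                     compress_initial: bool = True) -> np.ndarray:
    """Autoregressive rollout of the dynamical flow at compression level tau.

    The initial frame is first compressed to level ``tau`` (flowed), then
    each step integrates dx/ds = dt * v(x, tau, s, hist) over s in [0, 1].
    Returns (n_steps + 1, D) including the compressed initial state.  For
    h > 0, ``history_init`` must supply h frames already at level tau
    (oldest first).
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    h = model.v_field.history_len
    if h > 0:
        if history_init is None or len(history_init) != h:
            raise ValueError(f"rollout requires {h} history frames at level tau")
        hist = np.asarray(history_init, dtype=np.float64).copy()
    else:
        hist = None
    if compress_initial and tau < 1.0:
        x = compress_flowed(np.asarray(x0_frame, dtype=np.float64)[None],
                            model, tau, cfg)[0]
    else:
        x = np.asarray(x0_frame, dtype=np.float64).copy()
    out = [x.copy()]
    dt = model.dt
    for _ in range(n_steps):
        def rhs(y, s):
            hist_t = None
            if h > 0:
                hist_t = Tensor(hist.astype(np.float32)[None])
            v = model.v_field(Tensor(y.astype(np.float32)[None]),
                              np.array([tau]),
                              np.array([np.clip(s, 0.0, 1.0)]), hist_t)
            return dt * v.data[0].astype(np.float64)

        x = integrate(rhs, x, (0.0, 1.0), cfg)
        out.append(x.copy())
        if h > 0:
            hist = np.concatenate([hist[1:], x[None]], axis=0)
    return np.stack(out)


# ---------------------------------------------------------------- summaries

def dynamical_velocities(states: np.ndarray, model, tau: float = 0.0,
                         history: np.ndarray | None = None) -> np.ndarray:
    """Dynamical velocities at step starts (s = 0) for a stack of states."""
    n = len(states)
    hist_t = None
    if model.v_field.history_len:
        hist_t = Tensor(np.asarray(history, dtype=np.float32))
    v = model.v_field(Tensor(np.asarray(states, dtype=np.float32)),
                      np.full(n, tau), np.zeros(n), hist_t)
    return v.data.astype(np.float64)


def summarize_latents(states: np.ndarray, model,
                      velocities: np.ndarray | None = None,
                      threshold: float = 0.95,
                      mode: str = "flowed") -> LatentSummary:
    """Project tau = 0 states (and optional velocities) to latent
    coordinates and compute the effective dimension of the scale vector."""
    enc = model.encoder
    mu = latent_coordinates(states, enc)
    mu_dot = None if velocities is None else project_velocity(velocities, enc)
    d = enc.d_values()
    return LatentSummary(mu=mu, mu_dot=mu_dot,
                         k_eff=effective_dimension(d, threshold),
                         mode=mode, d_scales=d)
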