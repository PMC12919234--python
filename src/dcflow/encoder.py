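"""Deterministic dimension-reducing encoder coupling.

The encoder maps an observation ``x`` in ambient dimension D to its source
point

    x^(0) = b + L diag(d)^{1/2} mu(x),

where ``L`` has orthonormal columns (thin QR of an unconstrained matrix,
with a positive-diagonal sign convention that makes the factorization
deterministic), ``d`` holds strictly positive per-coordinate scales, and
``mu`` is a nonlinear feature map whose raw output is norm-capped and then
normalized coordinate-wise by running EMA statistics.  Nested dropout masks
a geometric-length prefix of the normalized features, inducing an ordering
of latent coordinates by importance; together with the QR sign convention
and normalization this renders the learned latent coordinates identifiable
up to a per-coordinate sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, qr_orthonormal
from .nn import Module

EPS_D = 1e-6        # floor on per-coordinate scales d_i
EPS_SIGMA = 1e-4    # floor on EMA std, guards constant features


class IdentityFeatureMap(Module):
    """mu(x) = x; analytic test harness (requires M == D)."""

    def __call__(self, x: Tensor) -> Tensor:
        return x


@dataclass
class NestedDropoutConfig:
    """Geometric prefix-length sampling: K ~ Geom(p), clamped to [k_min, k_max]."""

    p: float
    k_min: int = 1
    k_max: int = 1

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError("nested-dropout rate p must lie in (0, 1]")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")


@dataclass
class EncoderParams:
    """Trainable and running state of the encoder coupling.

    ``d_i = softplus(rho_i) + EPS_D`` keeps scales strictly positive.  The
    EMA statistics ``m``/``sigma`` are treated as constants inside each
    forward pass and updated afterwards from the batch.
    """

    b: Tensor                    # (D,)
    L_raw: Tensor                # (D, M)
    rho: Tensor                  # (M,) unconstrained; d = softplus(rho)+eps
    psi: Module                  # feature map: (N, D) -> (N, M)
    m: np.ndarray                # (M,) EMA mean
    sigma: np.ndarray            # (M,) EMA std, floored
    ema_decay: float = 0.99
    norm_cap: float | None = None   # None: default 3*sqrt(M)

    def __post_init__(self):
        if self.norm_cap is None:
            self.norm_cap = 3.0 * float(np.sqrt(self.latent_dim))

    @property
    def ambient_dim(self) -> int:
        return self.L_raw.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.L_raw.shape[1]

    def d(self) -> Tensor:
        return self.rho.softplus() + EPS_D

    def d_values(self) -> np.ndarray:
        return np.logaddexp(0.0, self.rho.data.astype(np.float64)) + EPS_D

    def basis(self) -> Tensor:
        return qr_orthonormal(self.L_raw)

    def basis_values(self) -> np.ndarray:
        return orthonormal_basis(self.L_raw.data)

    def trainables(self) -> list[Tensor]:
        return [self.b, self.L_raw, self.rho]

    @staticmethod
    def create(ambient_dim: int, latent_dim: int, psi: Module,
               rng: np.random.Generator, d_init: float = 1e-3,
               ema_decay: float = 0.99, norm_cap: float | None = None
               ) -> "EncoderParams":
        if latent_dim > ambient_dim:
            raise ValueError("latent width M must not exceed ambient dimension D")
        L_raw = rng.standard_normal((ambient_dim, latent_dim)).astype(np.float32)
        rho0 = float(np.log(np.expm1(max(d_init, 2 * EPS_D) - EPS_D)))
        return EncoderParams(
            b=Tensor(np.zeros(ambient_dim, dtype=np.float32), requires_grad=True),
            L_raw=Tensor(L_raw, requires_grad=True),
            rho=Tensor(np.full(latent_dim, rho0, dtype=np.float32), requires_grad=True),
            psi=psi,
            m=np.zeros(latent_dim, dtype=np.float32),
            sigma=np.ones(latent_dim, dtype=np.float32),
            ema_decay=ema_decay,
            norm_cap=norm_cap,
        )


# --------------------------------------------------------------- operations

def orthonormal_basis(L_raw: np.ndarray) -> np.ndarray:
    """Q factor of the thin non-pivoted QR of `L_raw`, diag(R) > 0.

    Deterministic: the sign convention removes the per-column +/-1 ambiguity,
    and the result is invariant to positive column scaling of `L_raw`.
    """
    L_raw = np.asarray(L_raw, dtype=np.float64)
    q, r = np.linalg.qr(L_raw, mode="reduced")
    diag = np.diagonal(r)
    if np.any(np.abs(diag) < 1e-10 * max(1.0, float(np.abs(L_raw).max()))):
        raise np.linalg.LinAlgError(
            "degenerate basis: L_raw is (numerically) rank-deficient")
    s = np.sign(diag)
    return q * s[None, :]


def raw_features(x: np.ndarray, psi: Module) -> np.ndarray:
    """Raw (uncapped, unnormalized) feature output of the map `psi`."""
    x = np.asarray(x, dtype=np.float32)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to feature map")
    single = x.ndim == 1
    out = psi(Tensor(x[None] if single else x)).data
    return out[0] if single else out


def cap_norm(f_raw: np.ndarray, c: float) -> np.ndarray:
    """Rescale `f_raw` to l2 norm `c` if it exceeds `c` (identity otherwise)."""
    if c <= 0:
        raise ValueError("norm cap must be positive")
    f_raw = np.asarray(f_raw, dtype=np.float64)
    n = np.linalg.norm(f_raw, axis=-1, keepdims=True)
    scale = np.where(n > c, c / np.maximum(n, 1e-12), 1.0)
    return f_raw * scale


def normalize_features(f_raw: np.ndarray, m: np.ndarray,
                       sigma: np.ndarray) -> np.ndarray:
    """(f_raw - m) / sigma elementwise; does not update the statistics."""
    sigma = np.asarray(sigma)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return (np.asarray(f_raw) - np.asarray(m)) / sigma


def update_ema_stats(batch_features: np.ndarray, m: np.ndarray,
                     sigma: np.ndarray, ema_decay: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """EMA update of coordinate-wise mean/std from a feature batch.

    With fewer than two rows the std update is skipped (mean only); the new
    std is floored at EPS_SIGMA.  Statistics are plain arrays, never part of
    the gradient graph.
    """
    batch = np.asarray(batch_features, dtype=np.float64)
    if batch.ndim != 2:
        raise ValueError("batch_features must be 2-D (N, M)")
    mean = batch.mean(axis=0)
    m_new = ema_decay * np.asarray(m, dtype=np.float64) + (1 - ema_decay) * mean
    if batch.shape[0] >= 2:
        std = batch.std(axis=0, ddof=1)
        s_new = ema_decay * np.asarray(sigma, dtype=np.float64) + (1 - ema_decay) * std
        s_new = np.maximum(s_new, EPS_SIGMA)
    else:
        s_new = np.asarray(sigma, dtype=np.float64)
    return m_new.astype(np.float32), s_new.astype(np.float32)


def sample_prefix_length(cfg: NestedDropoutConfig,
                         rng: np.random.Generator) -> int:
    """One prefix length K ~ Geom(p) on {1,2,...}, clamped to [k_min, k_max]."""
    return int(np.clip(rng.geometric(cfg.p), cfg.k_min, cfg.k_max))


def sample_prefix_lengths(cfg: NestedDropoutConfig, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    return np.clip(rng.geometric(cfg.p, size=n), cfg.k_min, cfg.k_max)


def apply_prefix_mask(f: np.ndarray | Tensor, k: int):
    """Zero all coordinates beyond the first `k` (1-based prefix length)."""
    m = f.shape[-1]
    if not (1 <= k <= m):
        raise ValueError(f"prefix length {k} outside [1, {m}]")
    mask = (np.arange(m) < k).astype(np.float32)
    return f * mask


def _prefix_mask_matrix(ks: np.ndarray, m: int) -> np.ndarray:
    ks = np.asarray(ks, dtype=np.int64)
    if np.any((ks < 1) | (ks > m)):
        raise ValueError("prefix lengths outside [1, M]")
    return (np.arange(m)[None, :] < ks[:, None]).astype(np.float32)


def masked_features(x: Tensor, params: EncoderParams,
                    ks: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Capped, normalized, prefix-masked features of a batch.

    Returns the masked feature Tensor and the capped *raw* features (plain
    array, for the post-step EMA update).
    """
    f_raw = params.psi(x)
    if params.norm_cap is not None:
        f_raw = f_raw.clip_norm(params.norm_cap)
    raw_vals = f_raw.data.copy()
    f = (f_raw - params.m) / params.sigma
    mask = _prefix_mask_matrix(ks, params.latent_dim)
    return f * mask, raw_vals


def encode_batch(x: Tensor, params: EncoderParams,
                 ks: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Masked encodings x^(0,K) of a batch; also returns capped raw features."""
    f_masked, raw_vals = masked_features(x, params, ks)
    L = params.basis()
    scaled = f_masked * params.d() ** 0.5
    x0 = scaled @ L.T + params.b
    return x0, raw_vals


def encode(x: np.ndarray, params: EncoderParams, k: int) -> np.ndarray:
    """Single-observation encoding b + L diag(d)^{1/2} mask_K(mu(x))."""
    x0, _ = encode_batch(Tensor(np.asarray(x, dtype=np.float32)[None]),
                         params, np.array([k]))
    return x0.data[0]


def alignment_loss(batch: Tensor, params: EncoderParams,
                   k_samples: np.ndarray) -> Tensor:
    """Mean squared reconstruction norm ||x - x^(0,K)||^2 under sampled K."""
    x0, _ = encode_batch(batch, params, k_samples)
    resid = batch - x0
    return (resid ** 2).sum(axis=1).mean()


def latent_coordinates(x0: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Normalized latent coordinates (L D^{1/2})^+ (x0 - b).

    Left inverse of the linear part of the encoder; exact on its image.
    Accepts a single vector or a stack of rows.
    """
    L = params.basis_values()
    d = np.maximum(params.d_values(), EPS_D)
    centered = np.asarray(x0, dtype=np.float64) - params.b.data.astype(np.float64)
    return (centered @ L) / np.sqrt(d)


def project_velocity(xdot0: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Same left inverse applied to velocities (no bias subtraction)."""
    L = params.basis_values()
    d = np.maximum(params.d_values(), EPS_D)
    return (np.asarray(xdot0, dtype=np.float64) @ L) / np.sqrt(d)


def effective_dimension(d: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest prefix K with sum_{i<=K} d_i >= threshold * sum_i d_i.

    Uses the stored coordinate order (nested dropout already orders
    coordinates by importance); invariant to uniform rescaling of `d`.
    """
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("scales must be nonnegative")
    total = d.sum()
    if total <= 0:
        raise ValueError("all-zero scale vector has no effective dimension")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(d)
    return int(np.searchsorted(cum, threshold * total - 1e-12 * total) + 1)
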