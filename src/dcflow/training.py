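"""Joint training of the encoder coupling and both velocity fields.

Each optimization step samples, per batch element, one nested-dropout
prefix length K (shared by all three loss terms), bridge coordinates
tau ~ U[0,1] (independently for the compressive and dynamical terms) and
s ~ U[0,1], and minimizes

    L = alpha * L_cf + beta * L_df + eta * L_align

with an adaptive first-order optimizer.  EMA feature statistics are treated
as constants within a step and updated from the batch afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from . import bridges
from .data import TrajectorySet
from .encoder import (EncoderParams, IdentityFeatureMap, NestedDropoutConfig,
                      encode_batch, sample_prefix_lengths, update_ema_stats)
from .fields import VelocityField
from .nn import Adam, ConditionedMLP, ConvFeatureMap, Module


@dataclass
class ModelConfig:
    """Architecture of the encoder feature map and both velocity fields."""

    latent_dim: int | None = None          # default min(D, 256)
    feature_arch: str = "mlp"              # mlp | conv_multiscale | identity
    feature_width: int = 128
    feature_depth: int = 3
    feature_channels: tuple[int, ...] = (32, 64, 128)
    field_arch: str = "mlp"                # mlp | conv_multiscale
    field_width: int = 256
    field_depth: int = 4
    field_channels: tuple[int, ...] = (32, 64, 128)
    field_bottleneck: int = 256
    d_init: float = 1e-3
    norm_cap: float | None = None
    emb_dim: int = 32


@dataclass
class TrainConfig:
    """Optimization hyperparameters and loss weights."""

    alpha: float = 1.0
    beta: float = 1.0
    eta: float = 1.0
    h: int = 0
    nd_p: float = 1.0 / 50.0
    batch_size: int = 32
    n_steps: int = 1000
    learning_rate: float = 1e-3
    encoder_linear_lr: float = 1e-2   # (b, L_raw, rho) move on few parameters
    seed: int = 0
    ema_decay: float = 0.99
    grad_clip: float = 1.0
    stop_encoder_flow_grads: bool = False
    log_every: int = 25
    # two-phase schedule: after lr_drop_frac of the steps, all learning
    # rates are multiplied by lr_drop_factor.  The fine phase settles the
    # stochastic regression (low-SNR velocity targets otherwise leave the
    # fields shrunk toward zero by optimizer noise).  Set lr_drop_frac=1.0
    # for a constant rate.
    lr_drop_frac: float = 0.7
    lr_drop_factor: float = 0.1

    def __post_init__(self):
        if self.alpha + self.beta + self.eta <= 0:
            raise ValueError("at least one loss weight must be positive")
        if self.h < 0:
            raise ValueError("history length h must be nonnegative")


@dataclass
class ModelState:
    """A trained (or initialized) DCF model."""

    encoder: EncoderParams
    u_field: VelocityField
    v_field: VelocityField
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    dt: float = 1.0
    frame_shape: tuple[int, ...] | None = None

    @property
    def ambient_dim(self) -> int:
        return self.encoder.ambient_dim


class TrainingLog:
    """Per-step loss components, exportable as newline-delimited JSON."""

    def __init__(self):
        self.records: list[dict] = []

    def append(self, **kv):
        self.records.append(kv)

    def to_ndjson(self, path):
        with open(path, "w") as f:
            for rec in self.records:
                f.write(json.dumps(rec) + "\n")

    def series(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records])


class TrainingDiverged(RuntimeError):
    """Raised when the loss turns non-finite; carries the offending batch."""

    def __init__(self, step: int, batch: np.ndarray, components: dict):
        self.step, self.batch, self.components = step, batch, components
        super().__init__(
            f"non-finite loss at step {step}: {components}; "
            f"offending batch shape {batch.shape} attached as .batch")


# ------------------------------------------------------------------- build

def build_model(dataset: TrajectorySet, model_cfg: ModelConfig,
                train_cfg: TrainConfig, rng: np.random.Generator) -> ModelState:
    return build_model_from_dims(dataset.n_features, model_cfg, train_cfg, rng,
                                 frame_shape=dataset.frame_shape,
                                 dt=dataset.dt)


def build_model_from_dims(d_amb: int, model_cfg: ModelConfig,
                          train_cfg: TrainConfig, rng: np.random.Generator,
                          frame_shape: tuple[int, ...] | None = None,
                          dt: float = 1.0) -> ModelState:
    m = model_cfg.latent_dim or min(d_amb, 256)
    side = frame_shape[0] if frame_shape else None

    if model_cfg.feature_arch == "identity":
        if m != d_amb:
            raise ValueError("identity feature map requires M == D")
        psi: Module = IdentityFeatureMap()
    elif model_cfg.feature_arch == "conv_multiscale":
        if side is None:
            raise ValueError("conv feature map requires image frames")
        psi = ConvFeatureMap(side, m, rng, channels=tuple(model_cfg.feature_channels))
    else:
        psi = ConditionedMLP(d_amb, m, rng, width=model_cfg.feature_width,
                             depth=model_cfg.feature_depth, cond_dim=0)

    encoder = EncoderParams.create(d_amb, m, psi, rng, d_init=model_cfg.d_init,
                                   ema_decay=train_cfg.ema_decay,
                                   norm_cap=model_cfg.norm_cap)
    fk = dict(arch=model_cfg.field_arch, width=model_cfg.field_width,
              depth=model_cfg.field_depth,
              channels=tuple(model_cfg.field_channels),
              bottleneck=model_cfg.field_bottleneck, side=side,
              emb_dim=model_cfg.emb_dim)
    u_field = VelocityField("compressive", d_amb, rng, **fk)
    v_field = VelocityField("dynamical", d_amb, rng, history_len=train_cfg.h, **fk)
    return ModelState(encoder, u_field, v_field, model_cfg, train_cfg,
                      dt=dt, frame_shape=frame_shape)


# ------------------------------------------------------------------- losses

def _mse(pred: Tensor, target: Tensor) -> Tensor:
    return ((pred - target) ** 2).sum(axis=1).mean()


def compressive_fm_loss(batch: np.ndarray, encoder: EncoderParams,
                        u_field: VelocityField, k_samples: np.ndarray,
                        rng: np.random.Generator) -> Tensor:
    """Monte-Carlo estimate of the compressive flow-matching loss.

    Per element: encode with its sampled K, draw tau ~ U[0,1], evaluate the
    field on the tau-bridge point and regress onto the constant target
    x^(1) - x^(0,K).
    """
    x1 = Tensor(np.asarray(batch, dtype=np.float32))
    x0, _ = encode_batch(x1, encoder, k_samples)
    tau = rng.uniform(size=(len(batch), 1))
    x_tau = bridges.compressive_bridge(x0, x1, tau)
    pred = u_field(x_tau, tau[:, 0])
    return _mse(pred, bridges.compressive_target(x0, x1))


def dynamical_fm_loss(batch_pairs: tuple, encoder: EncoderParams,
                      v_field: VelocityField, k_samples: np.ndarray,
                      h: int, rng: np.random.Generator,
                      dt: float = 1.0) -> Tensor:
    """Monte-Carlo estimate of the dynamical flow-matching loss.

    ``batch_pairs`` is ``(x_k, x_k1, hist)`` with ``hist`` of shape
    (N, h, D) (oldest first) or None when h = 0.  Per element: one shared
    tau for both endpoints and the history, an independent s, and the
    constant target (x_{k+1}^(tau) - x_k^(tau)) / dt.
    """
    x_k, x_k1, hist = batch_pairs
    n = len(x_k)
    xk = Tensor(np.asarray(x_k, dtype=np.float32))
    xk1 = Tensor(np.asarray(x_k1, dtype=np.float32))
    x0_k, _ = encode_batch(xk, encoder, k_samples)
    x0_k1, _ = encode_batch(xk1, encoder, k_samples)
    tau = rng.uniform(size=(n, 1))
    s = rng.uniform(size=(n, 1))
    xk_tau = bridges.compressive_bridge(x0_k, xk, tau)
    xk1_tau = bridges.compressive_bridge(x0_k1, xk1, tau)
    x_interp = bridges.dynamical_bridge(xk_tau, xk1_tau, s)
    hist_t = None
    if h > 0:
        hist = np.asarray(hist, dtype=np.float32)
        flat = Tensor(hist.reshape(n * h, -1))
        x0_h, _ = encode_batch(flat, encoder, np.repeat(k_samples, h))
        hist_tau = bridges.compressive_bridge(
            x0_h.reshape(n, h, -1), Tensor(hist), tau[:, :, None])
        hist_t = hist_tau
    pred = v_field(x_interp, tau[:, 0], s[:, 0], hist_t)
    return _mse(pred, bridges.dynamical_target(xk_tau, xk1_tau, dt))


def total_loss(batch_pairs: tuple, state: ModelState, cfg: TrainConfig,
               rng: np.random.Generator,
               k_samples: np.ndarray | None = None
               ) -> tuple[Tensor, dict, np.ndarray]:
    """Combined objective with a single shared K per batch element.

    Returns (loss, components dict of floats, capped raw feature batch for
    the EMA update).  Both frames of each pair contribute to the alignment
    and compressive terms.
    """
    x_k, x_k1, hist = batch_pairs
    n = len(x_k)
    if k_samples is None:
        nd = NestedDropoutConfig(cfg.nd_p, 1, state.encoder.latent_dim)
        k_samples = sample_prefix_lengths(nd, n, rng)

    frames = Tensor(np.concatenate([x_k, x_k1], axis=0).astype(np.float32))
    ks2 = np.concatenate([k_samples, k_samples])
    x0_all, raw_feats = encode_batch(frames, state.encoder, ks2)

    # alignment over both frames of each pair
    resid = frames - x0_all
    l_align = (resid ** 2).sum(axis=1).mean()

    x0_flow = x0_all.detach() if cfg.stop_encoder_flow_grads else x0_all

    # compressive term over both frames, independent tau per frame
    tau_c = rng.uniform(size=(2 * n, 1))
    x_tau = bridges.compressive_bridge(x0_flow, frames, tau_c)
    u_pred = state.u_field(x_tau, tau_c[:, 0])
    l_cf = _mse(u_pred, bridges.compressive_target(x0_flow, frames))

    # dynamical term on the pair, shared tau, independent s
    x0_k = x0_flow[:n]
    x0_k1 = x0_flow[n:]
    tau_d = rng.uniform(size=(n, 1))
    s = rng.uniform(size=(n, 1))
    xk_tau = bridges.compressive_bridge(x0_k, Tensor(np.asarray(x_k, np.float32)), tau_d)
    xk1_tau = bridges.compressive_bridge(x0_k1, Tensor(np.asarray(x_k1, np.float32)), tau_d)
    x_interp = bridges.dynamical_bridge(xk_tau, xk1_tau, s)
    hist_t = None
    if cfg.h > 0:
        hist = np.asarray(hist, dtype=np.float32)
        flat = Tensor(hist.reshape(n * cfg.h, -1))
        x0_h, _ = encode_batch(flat, state.encoder, np.repeat(k_samples, cfg.h))
        if cfg.stop_encoder_flow_grads:
            x0_h = x0_h.detach()
        hist_t = bridges.compressive_bridge(
            x0_h.reshape(n, cfg.h, -1), Tensor(hist), tau_d[:, :, None])
    v_pred = state.v_field(x_interp, tau_d[:, 0], s[:, 0], hist_t)
    l_df = _mse(v_pred, bridges.dynamical_target(xk_tau, xk1_tau, state.dt))

    total = cfg.alpha * l_cf + cfg.beta * l_df + cfg.eta * l_align
    comps = {"cf": float(l_cf.data), "df": float(l_df.data),
             "align": float(l_align.data), "total": float(total.data)}
    return total, comps, raw_feats


# -------------------------------------------------------------------- train

def _sample_pairs(dataset: TrajectorySet, n: int, h: int,
                  rng: np.random.Generator) -> tuple:
    """Uniform (trajectory, step) pairs with full lag-h history."""
    T = dataset.n_steps
    valid = [i for i in range(dataset.n_traj) if T >= h + 2]
    if len(valid) < dataset.n_traj:
        import warnings
        warnings.warn(f"excluded {dataset.n_traj - len(valid)} trajectories "
                      f"shorter than h+2={h + 2}")
    if not valid:
        raise ValueError("no trajectory long enough for the configured history")
    ti = rng.choice(np.asarray(valid), size=n)
    ki = rng.integers(h, T - 1, size=n)
    x_k = dataset.data[ti, ki]
    x_k1 = dataset.data[ti, ki + 1]
    hist = None
    if h > 0:
        offs = np.arange(-h, 0)
        hist = dataset.data[ti[:, None], ki[:, None] + offs[None, :]]
    return x_k, x_k1, hist


def make_optimizers(state: ModelState, cfg: TrainConfig) -> list[Adam]:
    """Two parameter groups: encoder linear part (few parameters, faster
    rate) and all network weights."""
    linear = state.encoder.trainables()
    nets = (state.encoder.psi.parameters() + state.u_field.parameters()
            + state.v_field.parameters())
    return [Adam(linear, lr=cfg.encoder_linear_lr, grad_clip=cfg.grad_clip),
            Adam(nets, lr=cfg.learning_rate, grad_clip=cfg.grad_clip)]


def train(dataset: TrajectorySet, cfg: TrainConfig,
          model_cfg: ModelConfig | None = None,
          state: ModelState | None = None,
          callback=None) -> tuple[ModelState, TrainingLog]:
    """Jointly optimize encoder and both fields on a trajectory dataset.

    Reproducible given ``cfg.seed``: one seed sequence is split into
    independent streams for initialization, batch order, K, tau and s.
    """
    if dataset.n_steps < cfg.h + 2:
        raise ValueError("dataset trajectories shorter than h + 2")
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, batch_rng, k_rng, bridge_rng = (
        np.random.default_rng(s) for s in ss.spawn(4))
    if state is None:
        state = build_model(dataset, model_cfg or ModelConfig(), cfg, init_rng)
    nd = NestedDropoutConfig(cfg.nd_p, 1, state.encoder.latent_dim)
    opts = make_optimizers(state, cfg)
    log = TrainingLog()
    drop_step = int(cfg.lr_drop_frac * cfg.n_steps)
    for step in range(cfg.n_steps):
        if step == drop_step and cfg.lr_drop_frac < 1.0:
            for o in opts:
                o.lr *= cfg.lr_drop_factor
        pairs = _sample_pairs(dataset, cfg.batch_size, cfg.h, batch_rng)
        ks = sample_prefix_lengths(nd, cfg.batch_size, k_rng)
        try:
            loss, comps, raw_feats = total_loss(pairs, state, cfg, bridge_rng,
                                                k_samples=ks)
        except ValueError as exc:
            # overflow inside the networks surfaces as a non-finite-state
            # rejection; treat it as divergence and attach the batch
            raise TrainingDiverged(step, np.asarray(pairs[0]),
                                   {"error": str(exc)}) from exc
        if not np.isfinite(comps["total"]):
            raise TrainingDiverged(step, np.asarray(pairs[0]), comps)
        for o in opts:
            o.zero_grad()
        loss.backward()
        for o in opts:
            o.step()
        state.encoder.m, state.encoder.sigma = update_ema_stats(
            raw_feats, state.encoder.m, state.encoder.sigma, cfg.ema_decay)
        if step % cfg.log_every == 0 or step == cfg.n_steps - 1:
            log.append(step=step, **comps)
        if callback is not None:
            callback(step, state, comps)
    return state, log


def weight_sensitivity_grid(dataset: TrajectorySet, cfg: TrainConfig,
                            model_cfg: ModelConfig | None = None,
                            weights: tuple[float, ...] = (0.3, 1.0, 3.0),
                            threshold: float = 0.95) -> list[dict]:
    """Re-train over a grid of (alpha, beta, eta) and report K_eff and the
    final alignment loss for each combination (robustness harness)."""
    from dataclasses import replace
    from .encoder import effective_dimension
    out = []
    for a in weights:
        for b in weights:
            for e in weights:
                cfg_i = replace(cfg, alpha=a, beta=b, eta=e)
                state, log = train(dataset, cfg_i, model_cfg)
                out.append({
                    "alpha": a, "beta": b, "eta": e,
                    "k_eff": effective_dimension(state.encoder.d_values(),
                                                 threshold),
                    "final_align": float(log.series("align")[-1]),
                    "final_total": float(log.series("total")[-1]),
                })
    return out
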