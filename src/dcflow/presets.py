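"""Desk-scale study presets shared by the test suite and scripts.

Two reference studies:

* the rotating-ball videos (10 videos x 50 frames of 28x28 pixels) with a
  reduced-width convolutional feature map (channels 16/32/64) and MLP
  velocity fields, nested-dropout rate 1/50, no dynamical history;
* the embedded planar oscillator (D = 20, two intrinsic dimensions) with
  MLP models throughout, the same nested-dropout rate, mild observation
  noise.

Problem sizes are chosen so a full study trains in minutes on one CPU
core.  The data configurations define the study conditions; training seeds
vary across repetitions.
"""

from __future__ import annotations

from .synthetic_data import BallVideoConfig, OscillatorConfig
from .training import ModelConfig, TrainConfig

BALL_EFF_DIM_THRESHOLD = 0.95


def ball_data_config(seed: int = 0) -> BallVideoConfig:
    return BallVideoConfig(n_videos=10, n_frames=50, side=28, seed=seed)


def ball_model_config() -> ModelConfig:
    return ModelConfig(
        feature_arch="conv_multiscale",
        feature_channels=(16, 32, 64),
        field_arch="mlp",
        field_width=256,
        field_depth=4,
    )


def ball_train_config(seed: int = 0, n_steps: int = 3000) -> TrainConfig:
    return TrainConfig(nd_p=1.0 / 50.0, h=0, alpha=1.0, beta=1.0, eta=1.0,
                       n_steps=n_steps, batch_size=32, seed=seed,
                       log_every=200)


def oscillator_data_config(seed: int = 7) -> OscillatorConfig:
    return OscillatorConfig(ambient_dim=20, latent_dim=2, noise_sd=0.05,
                            n_traj=20, n_steps=50, seed=seed)


def oscillator_model_config() -> ModelConfig:
    return ModelConfig(feature_arch="mlp", feature_width=128, feature_depth=3,
                       field_arch="mlp", field_width=128, field_depth=3)


def oscillator_train_config(seed: int = 0, n_steps: int = 6000) -> TrainConfig:
    return TrainConfig(nd_p=1.0 / 50.0, h=0, alpha=1.0, beta=1.0, eta=1.0,
                       n_steps=n_steps, batch_size=32, seed=seed,
                       log_every=200)
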