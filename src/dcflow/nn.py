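"""Neural-network building blocks on top of the autodiff core.

Provides the layers used by the encoder feature maps and the two velocity
fields: dense layers, MLPs with per-block additive scalar conditioning,
strided convolutions, a multiscale convolutional encoder, a small U-Net
style encoder–decoder, sinusoidal scalar embeddings and an Adam optimizer.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, conv2d, upsample2x


class Module:
    """Base class: parameter discovery by attribute traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
        collect(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters (for checkpoints)."""
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    out[prefix] = obj.data
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}[{i}]")
        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]):
        state = self.state_arrays()
        missing = set(state) - set(arrays)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        def walk(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    a = np.asarray(arrays[prefix], dtype=obj.data.dtype)
                    if a.shape != obj.data.shape:
                        raise ValueError(f"shape mismatch for {prefix}")
                    obj.data = a
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}[{i}]")
        walk(self, "")


def _he(rng, fan_in, shape):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out), dtype=np.float32)
        else:
            w = _he(rng, d_in, (d_in, d_out))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class SinusoidalEmbedding(Module):
    """Standard sin/cos embedding of a scalar in [0, 1].

    Frequencies are geometric from 1 to ``max_freq`` radians; the default
    suits unit-interval conditioners (several oscillations across [0, 1]
    at the top end, smooth interpolation between training samples).
    """

    def __init__(self, dim: int, max_freq: float = 30.0):
        if dim % 2:
            raise ValueError("embedding dim must be even")
        self.dim = dim
        half = dim // 2
        self.freqs = np.exp(np.linspace(0.0, np.log(max_freq), half)).astype(np.float32)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=np.float32)).reshape(-1, 1)
        ang = t * self.freqs[None, :]
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class ConditionedMLP(Module):
    """MLP whose hidden blocks each receive an additive projection of a
    conditioning embedding (sinusoidal scalars and/or extra vectors)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 width: int = 256, depth: int = 4, cond_dim: int = 0,
                 zero_init_head: bool = False):
        self.depth = depth
        self.hidden = []
        self.cond_proj = []
        d = d_in
        for _ in range(depth):
            self.hidden.append(Linear(d, width, rng))
            if cond_dim:
                self.cond_proj.append(Linear(cond_dim, width, rng))
            d = width
        self.head = Linear(d, d_out, rng, zero_init=zero_init_head)
        self.cond_dim = cond_dim

    def __call__(self, x: Tensor, cond: np.ndarray | None = None) -> Tensor:
        h = x
        for i, lin in enumerate(self.hidden):
            h = lin(h)
            if self.cond_dim and cond is not None:
                h = h + self.cond_proj[i](Tensor(cond))
            h = h.silu()
        return self.head(h)


class Conv2dLayer(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, padding: int = 1,
                 zero_init: bool = False):
        fan = c_in * k * k
        w = (np.zeros((c_out, c_in, k, k)) if zero_init
             else rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan))
        self.w = Tensor(w.astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ConvFeatureMap(Module):
    """Multiscale convolutional feature extractor for square grayscale frames.

    Stride-2 convolutions halve the side at each level; the final feature is
    a dense projection of the flattened coarsest level.  Acts as the mean
    path of a convolutional encoder (no sampling step).
    """

    def __init__(self, side: int, d_out: int, rng: np.random.Generator,
                 channels: tuple[int, ...] = (32, 64, 128), c_in: int = 1):
        self.side, self.c_in = side, c_in
        self.convs = []
        c = c_in
        s = side
        for ch in channels:
            self.convs.append(Conv2dLayer(c, ch, rng, stride=2, padding=1))
            c = ch
            s = (s + 1) // 2
        self.flat_dim = c * s * s
        self.proj = Linear(self.flat_dim, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h = x.reshape(n, self.c_in, self.side, self.side)
        for conv in self.convs:
            h = conv(h).silu()
        return self.proj(h.reshape(n, self.flat_dim))


class ConvUNet(Module):
    """Small U-Net style encoder–decoder over flattened square frames.

    Scalar conditioning is injected additively per channel at every level;
    the output head is zero-initialized so an untrained field is the zero
    velocity.  Extra conditioning channels (e.g. lag history frames) are
    concatenated to the input image.
    """

    def __init__(self, side: int, rng: np.random.Generator,
                 channels: tuple[int, ...] = (32, 64, 128),
                 cond_dim: int = 32, c_in: int = 1, c_out: int = 1,
                 bottleneck: int = 256):
        if side % (2 ** len(channels)) and side // (2 ** len(channels)) < 1:
            raise ValueError("image side too small for channel schedule")
        self.side, self.c_in, self.c_out = side, c_in, c_out
        self.cond_dim = cond_dim
        self.down = []
        self.down_cond = []
        c = c_in
        s = side
        sides = []
        for ch in channels:
            self.down.append(Conv2dLayer(c, ch, rng, stride=2, padding=1))
            self.down_cond.append(Linear(cond_dim, ch, rng))
            sides.append(s)
            c, s = ch, (s + 1) // 2
        self.mid_in = Linear(c * s * s, bottleneck, rng)
        self.mid_cond = Linear(cond_dim, bottleneck, rng)
        self.mid_out = Linear(bottleneck, c * s * s, rng)
        self.bott_shape = (c, s, s)
        self.up = []
        self.up_cond = []
        rev = list(reversed(channels))
        for i, ch in enumerate(rev):
            c_next = rev[i + 1] if i + 1 < len(rev) else channels[0]
            # input: upsampled current + skip connection of same width
            self.up.append(Conv2dLayer(ch + ch, c_next, rng, stride=1, padding=1))
            self.up_cond.append(Linear(cond_dim, c_next, rng))
        self.head = Conv2dLayer(channels[0], c_out, rng, k=1, padding=0,
                                zero_init=True)
        self.sides = sides

    def __call__(self, x: Tensor, cond: np.ndarray) -> Tensor:
        n = x.shape[0]
        h = x.reshape(n, self.c_in, self.side, self.side)
        skips = []
        cond_t = Tensor(np.asarray(cond, dtype=np.float32))
        for conv, cproj in zip(self.down, self.down_cond):
            h = conv(h)
            bias = cproj(cond_t)  # n x ch
            h = (h + bias.reshape(n, -1, 1, 1)).silu()
            skips.append(h)
        c, s, _ = self.bott_shape
        z = self.mid_in(h.reshape(n, c * s * s))
        z = (z + self.mid_cond(cond_t)).silu()
        h = self.mid_out(z).reshape(n, c, s, s)
        for i, (conv, cproj) in enumerate(zip(self.up, self.up_cond)):
            skip = skips[len(skips) - 1 - i]
            h = concat([h, skip], axis=1)
            h = conv(h)
            h = (h + cproj(cond_t).reshape(n, -1, 1, 1)).silu()
            h = upsample2x(h)
            target = self.sides[len(self.sides) - 1 - i]
            if h.shape[2] > target:
                h = h[:, :, :target, :target]
        out = self.head(h)
        return out.reshape(n, self.c_out * self.side * self.side)


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_clip: float | None = 1.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.grad_clip is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > self.grad_clip:
                scale = self.grad_clip / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
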