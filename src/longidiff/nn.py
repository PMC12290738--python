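"""Neural-network building blocks for the noise-prediction network.

Layers own their parameters as :class:`~longidiff.autodiff.Tensor` leaves;
``Module.named_parameters`` walks the attribute tree so optimizers and
checkpoints see a flat, stably-ordered name -> array mapping.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, concat, conv2d, group_norm, matmul, silu,
                       softmax, swap_last2, upsample_nearest2)

__all__ = ["Module", "Conv2d", "Linear", "GroupNorm", "ResBlock",
           "SelfAttention2d", "Downsample", "Upsample", "TimeEmbedding",
           "Adam", "sinusoidal_embedding"]


class Module:
    """Base class: parameter discovery and train/eval plumbing."""

    def named_parameters(self, prefix: str = ""):
        for name in sorted(vars(self)):
            obj = getattr(self, name)
            key = f"{prefix}{name}"
            if isinstance(obj, Tensor) and obj.requires_grad:
                yield key, obj
            elif isinstance(obj, Module):
                yield from obj.named_parameters(f"{key}.")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    scale = np.sqrt(1.0 / fan_in)
    return (rng.standard_normal(shape) * scale).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, pad: int | None = None, dtype=np.float32,
                 init_scale: float = 1.0):
        fan_in = in_ch * kernel * kernel
        w = init_scale * _kaiming(rng, (out_ch, in_ch, kernel, kernel),
                                  fan_in, dtype)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng, dtype=np.float32):
        self.w = Tensor(_kaiming(rng, (in_f, out_f), in_f, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int, dtype=np.float32):
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.groups = groups

    def __call__(self, x: Tensor) -> Tensor:
        return group_norm(x, self.gamma, self.beta, self.groups)


def sinusoidal_embedding(t: np.ndarray, dim: int, dtype=np.float32) -> np.ndarray:
    """Transformer-style sin/cos position encoding of integer timesteps."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.pad(emb, ((0, 0), (0, 1)))
    return emb.astype(dtype)


class TimeEmbedding(Module):
    """Sinusoidal encoding followed by two fully-connected layers."""

    def __init__(self, dim: int, rng, dtype=np.float32):
        self.dim = dim
        self.fc1 = Linear(dim, dim, rng, dtype)
        self.fc2 = Linear(dim, dim, rng, dtype)
        self.dtype = dtype

    def __call__(self, t: np.ndarray) -> Tensor:
        emb = Tensor(sinusoidal_embedding(t, self.dim, self.dtype))
        return self.fc2(silu(self.fc1(emb)))


class ResBlock(Module):
    """GN -> SiLU -> conv, timestep bias injection, GN -> SiLU -> conv, shortcut."""

    def __init__(self, in_ch: int, out_ch: int, temb_dim: int, groups: int, rng,
                 dtype=np.float32):
        g_in = groups if in_ch % groups == 0 else 1
        self.norm1 = GroupNorm(in_ch, g_in, dtype)
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, dtype=dtype)
        self.temb_proj = Linear(temb_dim, out_ch, rng, dtype)
        self.norm2 = GroupNorm(out_ch, groups, dtype)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, dtype=dtype, init_scale=0.01)
        self.skip = None if in_ch == out_ch else Conv2d(in_ch, out_ch, 1, rng,
                                                        pad=0, dtype=dtype)

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(silu(self.norm1(x)))
        tb = self.temb_proj(silu(temb))
        n, c = tb.shape
        h = h + tb.reshape(n, c, 1, 1)
        h = self.conv2(silu(self.norm2(h)))
        s = x if self.skip is None else self.skip(x)
        return h + s


class SelfAttention2d(Module):
    """Single-head spatial self-attention with a residual connection."""

    def __init__(self, channels: int, groups: int, rng, dtype=np.float32):
        self.norm = GroupNorm(channels, groups, dtype)
        self.q = Conv2d(channels, channels, 1, rng, pad=0, dtype=dtype)
        self.k = Conv2d(channels, channels, 1, rng, pad=0, dtype=dtype)
        self.v = Conv2d(channels, channels, 1, rng, pad=0, dtype=dtype)
        self.proj = Conv2d(channels, channels, 1, rng, pad=0, dtype=dtype,
                           init_scale=0.01)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        xn = self.norm(x)
        q = self.q(xn).reshape(n, c, h * w)
        k = self.k(xn).reshape(n, c, h * w)
        v = self.v(xn).reshape(n, c, h * w)
        attn = softmax(matmul(swap_last2(q), k) * (c ** -0.5), axis=-1)
        out = matmul(v, swap_last2(attn)).reshape(n, c, h, w)
        return x + self.proj(out)


class Downsample(Module):
    def __init__(self, channels: int, rng, dtype=np.float32):
        self.conv = Conv2d(channels, channels, 3, rng, stride=2, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


class Upsample(Module):
    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        self.conv = Conv2d(in_ch, out_ch, 3, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(upsample_nearest2(x))


class Adam:
    """Adam with bias correction; state is checkpointable via get/set_state."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.step_count = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.step_count += 1
        b1t = 1.0 - self.b1 ** self.step_count
        b2t = 1.0 - self.b2 ** self.step_count
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def get_state(self) -> dict:
        return {"step_count": self.step_count,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def set_state(self, state: dict):
        self.step_count = int(state["step_count"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
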