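"""The noise-prediction network eps_theta.

A UNet-like 2D encoder-decoder over unit channel stacks: residual blocks
with shortcut connections and group normalization, down/upsampling across
resolution levels, self-attention at the coarsest level(s), and a sinusoidal
timestep embedding passed through two fully-connected layers and injected
into every residual block.  The same backbone (with a fixed t = 0 embedding
and condition-only input channels) serves the autoencoder baselines.

Checkpoints are .npz archives storing the spec as JSON next to the named
parameter arrays; see :func:`save_checkpoint` / :func:`load_checkpoint`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, concat, silu
from .unitizer import UnitLayout

__all__ = ["DenoiserSpec", "Denoiser", "build_denoiser", "predict",
           "spec_for_layout", "PRESETS", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT_VERSION = 1

#: Architecture presets.  "tiny" is the desk-scale configuration used by the
#: tests and the synthetic experiments; "paper-p"/"paper-pf" mirror the
#: full-scale channel multipliers (64 for past-only, 128 for past+following).
PRESETS: dict[str, dict] = {
    "tiny": dict(base_channels=16, depth=2, channel_mults=(1, 2),
                 attention_levels=(1,), groups=8, time_embed_dim=64,
                 predict_type="x0"),
    "paper-p": dict(base_channels=64, depth=3, channel_mults=(1, 2, 4),
                    attention_levels=(2,), groups=32, time_embed_dim=256,
                    predict_type="x0"),
    "paper-pf": dict(base_channels=128, depth=3, channel_mults=(1, 2, 4),
                     attention_levels=(2,), groups=32, time_embed_dim=512,
                     predict_type="x0"),
}


@dataclass(frozen=True)
class DenoiserSpec:
    """Static architecture description of the noise predictor."""

    in_channels: int
    out_channels: int
    image_size: tuple[int, int]       # (H, W)
    base_channels: int = 16
    depth: int = 2
    channel_mults: tuple[int, ...] = (1, 2)
    attention_levels: tuple[int, ...] = (1,)
    groups: int = 8
    time_embed_dim: int = 64
    #: what the network output parameterizes.  "eps": the injected noise
    #: directly.  "x0": the clean-image estimate, from which the noise
    #: prediction is formed algebraically (an exact reparameterization of
    #: eps_theta that is far better conditioned at high noise levels).
    predict_type: str = "eps"
    #: input channel blocks (of out_channels each) whose mean is added to the
    #: network output.  With "x0" prediction this encodes the temporal-
    #: smoothness prior of longitudinal trajectories: the clean-image
    #: estimate is the adjacent-visit mean plus a learned correction.
    residual_blocks: tuple[int, ...] = ()

    def __post_init__(self):
        if self.predict_type not in ("eps", "x0"):
            raise ValueError(
                f"predict_type must be 'eps' or 'x0', got {self.predict_type!r}")
        if self.residual_blocks:
            if self.predict_type != "x0":
                raise ValueError(
                    "residual_blocks requires predict_type='x0' (the output "
                    "must live in image space)")
            n_blocks = self.in_channels // self.out_channels
            if any(not 0 <= b < n_blocks for b in self.residual_blocks):
                raise ValueError(
                    f"residual_blocks {self.residual_blocks} outside the "
                    f"{n_blocks} input blocks")
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if len(self.channel_mults) != self.depth:
            raise ValueError("channel_mults must have one entry per level")
        h, w = self.image_size
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"image size {self.image_size} must be divisible by "
                f"2^(depth-1) = {div}")


def spec_for_layout(layout: UnitLayout, n_cond: int, preset: str = "tiny",
                    include_target: bool = True) -> DenoiserSpec:
    """Derive channel counts from a unit layout and condition kind.

    ``include_target=True`` gives the diffusion input (noisy target stacked
    with the conditions); ``False`` gives the condition-only autoencoder
    input.
    """
    if n_cond not in (1, 2):
        raise ValueError(f"n_cond must be 1 or 2, got {n_cond}")
    c = layout.unit_channels
    n_in = (1 + n_cond) * c if include_target else n_cond * c
    kwargs = dict(PRESETS[preset])
    if kwargs.get("predict_type") == "x0":
        first = 1 if include_target else 0
        kwargs["residual_blocks"] = tuple(range(first, first + n_cond))
    return DenoiserSpec(in_channels=n_in, out_channels=c,
                        image_size=(layout.H, layout.W), **kwargs)


class Denoiser(nn.Module):
    """eps_theta: predicts the injected noise from (noisy unit, conditions, t)."""

    def __init__(self, spec: DenoiserSpec, rng: np.random.Generator,
                 dtype=np.float32):
        self.spec = spec
        chs = [spec.base_channels * m for m in spec.channel_mults]
        g = spec.groups
        te = spec.time_embed_dim
        self.time_embed = nn.TimeEmbedding(te, rng, dtype)
        self.stem = nn.Conv2d(spec.in_channels, chs[0], 3, rng, dtype=dtype)
        self.down_res: list[nn.Module] = []
        self.down_attn: list[nn.Module | None] = []
        self.downs: list[nn.Module] = []
        prev = chs[0]
        for lvl, ch in enumerate(chs):
            self.down_res.append(nn.ResBlock(prev, ch, te, g, rng, dtype))
            self.down_attn.append(
                nn.SelfAttention2d(ch, g, rng, dtype)
                if lvl in spec.attention_levels else None)
            if lvl < spec.depth - 1:
                self.downs.append(nn.Downsample(ch, rng, dtype))
            prev = ch
        self.mid = nn.ResBlock(chs[-1], chs[-1], te, g, rng, dtype)
        self.ups: list[nn.Module] = []
        self.up_res: list[nn.Module] = []
        for lvl in range(spec.depth - 2, -1, -1):
            self.ups.append(nn.Upsample(prev, chs[lvl], rng, dtype))
            self.up_res.append(nn.ResBlock(2 * chs[lvl], chs[lvl], te, g, rng,
                                           dtype))
            prev = chs[lvl]
        self.out_norm = nn.GroupNorm(chs[0], g, dtype)
        self.out_conv = nn.Conv2d(chs[0], spec.out_channels, 3, rng,
                                  dtype=dtype, init_scale=0.01)

    # differentiable path ----------------------------------------------------
    def forward(self, x: Tensor, t: np.ndarray) -> Tensor:
        spec = self.spec
        if x.shape[1] != spec.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, model expects "
                f"{spec.in_channels}")
        temb = self.time_embed(t)
        h = self.stem(x)
        skips = []
        for lvl in range(spec.depth):
            h = self.down_res[lvl](h, temb)
            if self.down_attn[lvl] is not None:
                h = self.down_attn[lvl](h)
            if lvl < spec.depth - 1:
                skips.append(h)
                h = self.downs[lvl](h)
        h = self.mid(h, temb)
        for i, lvl in enumerate(range(spec.depth - 2, -1, -1)):
            h = self.ups[i](h)
            h = concat([h, skips[lvl]], axis=1)
            h = self.up_res[i](h, temb)
        out = self.out_conv(silu(self.out_norm(h)))
        if spec.residual_blocks:
            c = spec.out_channels
            base = np.mean([x.data[:, b * c:(b + 1) * c]
                            for b in spec.residual_blocks], axis=0)
            out = out + Tensor(base)
        return out

    # inference path ---------------------------------------------------------
    def predict(self, x: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Noise prediction for a numpy batch (N, C_in, H, W); no gradients."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got {x.shape}")
        out = self.forward(Tensor(x), np.asarray(t))
        return out.data


def build_denoiser(spec: DenoiserSpec, rng: np.random.Generator) -> Denoiser:
    """Seeded construction; two builds from equal generator states coincide."""
    return Denoiser(spec, rng)


def predict(model: Denoiser, noisy_unit_plus_conditions: np.ndarray,
            t) -> np.ndarray:
    """Functional wrapper around :meth:`Denoiser.predict`."""
    x = np.asarray(noisy_unit_plus_conditions)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    t_arr = np.atleast_1d(np.asarray(t, dtype=int))
    if t_arr.size == 1 and x.shape[0] > 1:
        t_arr = np.full(x.shape[0], int(t_arr[0]))
    out = model.predict(x, t_arr)
    return out[0] if squeeze else out


def save_checkpoint(path, model: Denoiser, step: int = 0,
                    optimizer_state: dict | None = None,
                    rng_state: dict | None = None):
    """Self-describing versioned .npz checkpoint (spec JSON + parameters)."""
    payload = {
        "__format_version__": np.int64(CHECKPOINT_FORMAT_VERSION),
        "__spec_json__": np.frombuffer(
            json.dumps(asdict(model.spec)).encode(), dtype=np.uint8),
        "__step__": np.int64(step),
    }
    for name, p in model.named_parameters():
        payload[f"param/{name}"] = p.data
    if optimizer_state is not None:
        payload["opt/step_count"] = np.int64(optimizer_state["step_count"])
        for i, m in enumerate(optimizer_state["m"]):
            payload[f"opt/m/{i}"] = m
        for i, v in enumerate(optimizer_state["v"]):
            payload[f"opt/v/{i}"] = v
    if rng_state is not None:
        payload["__rng_json__"] = np.frombuffer(
            json.dumps(rng_state).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Returns (model, step, optimizer_state or None, rng_state or None)."""
    with np.load(path) as z:
        version = int(z["__format_version__"])
        if version != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {version}")
        spec_dict = json.loads(bytes(z["__spec_json__"]).decode())
        for key in ("image_size", "channel_mults", "attention_levels",
                    "residual_blocks"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = DenoiserSpec(**spec_dict)
        model = Denoiser(spec, np.random.default_rng(0))
        for name, p in model.named_parameters():
            p.data = z[f"param/{name}"].copy()
        step = int(z["__step__"])
        opt_state = None
        if "opt/step_count" in z:
            n = len(model.parameters())
            opt_state = {
                "step_count": int(z["opt/step_count"]),
                "m": [z[f"opt/m/{i}"].copy() for i in range(n)],
                "v": [z[f"opt/v/{i}"].copy() for i in range(n)],
            }
        rng_state = None
        if "__rng_json__" in z:
            rng_state = json.loads(bytes(z["__rng_json__"]).decode())
    return model, step, opt_state, rng_state
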