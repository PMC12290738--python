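"""Conditional denoising-diffusion mathematics for visit imputation.

The forward process corrupts the missing-visit image x_0 with a fixed
Gaussian variance schedule beta_t, t = 1..T:

    q(x_t | x_{t-1}) = N(sqrt(1 - beta_t) x_{t-1}, beta_t I)
    q(x_t | x_0)     = N(sqrt(abar_t) x_0, (1 - abar_t) I),
    abar_t = prod_{s<=t} (1 - beta_s).

The reverse (denoising) process is parameterized by a network eps_theta that
predicts the injected noise from the noisy target stacked channel-wise with
the clean condition images (the adjacent past visit, or past and following
visits).  Conditions are never diffused; noise is added to the target only.
Ancestral sampling runs the learned transition from pure noise down to t=1,
per generation unit, and the units are reassembled into a volume.

Convention: abar_0 := 1, so the posterior variance at t=1 is zero and the
final denoising transition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .unitizer import UnitLayout, assemble, extract_unit, generation_units

__all__ = ["DiffusionSchedule", "NoisyState", "ConditionSet", "make_schedule",
           "forward_sample", "forward_step", "estimate_x0", "posterior_params",
           "denoise_step", "sample", "training_loss"]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Variance schedule and all derived per-step quantities (1-indexed in t)."""

    T: int
    beta: np.ndarray           # beta[t-1] = beta_t
    alpha: np.ndarray          # 1 - beta_t
    alpha_bar: np.ndarray      # cumulative product of alpha
    posterior_var: np.ndarray  # beta~_t = (1 - abar_{t-1}) / (1 - abar_t) * beta_t

    def _check_t(self, t: int):
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep t={t} outside [1, {self.T}]")

    def abar(self, t: int) -> float:
        self._check_t(t)
        return float(self.alpha_bar[t - 1])

    def abar_prev(self, t: int) -> float:
        self._check_t(t)
        return 1.0 if t == 1 else float(self.alpha_bar[t - 2])


@dataclass(frozen=True)
class NoisyState:
    """A diffused array at step t (t = 0 denotes clean data)."""

    x_t: np.ndarray
    t: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.x_t)):
            raise ValueError("NoisyState contains non-finite entries")


@dataclass(frozen=True)
class ConditionSet:
    """Observed neighbours conditioning the generation of the missing visit.

    kind "P": one image (the past visit); kind "PF": two images ordered
    past then following.  Images must share the target's shape.
    """

    kind: str
    images: tuple[np.ndarray, ...]

    def __post_init__(self):
        if self.kind not in ("P", "PF"):
            raise ValueError(f"kind must be 'P' or 'PF', got {self.kind!r}")
        expected = 1 if self.kind == "P" else 2
        if len(self.images) != expected:
            raise ValueError(
                f"kind={self.kind} requires {expected} image(s), "
                f"got {len(self.images)}")
        shapes = {img.shape for img in self.images}
        if len(shapes) != 1:
            raise ValueError(f"condition images differ in shape: {shapes}")

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def shape(self):
        return self.images[0].shape

    def extract_units(self, indices) -> "ConditionSet":
        """Condition set restricted to the target unit's slice indices."""
        return ConditionSet(self.kind, tuple(
            extract_unit(img, indices).data for img in self.images))


def make_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02,
                  kind: str = "linear") -> DiffusionSchedule:
    """Build a linear variance schedule and its derived quantities."""
    if T < 1:
        raise ValueError(f"T must be a positive integer, got {T}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"require 0 < beta_start <= beta_end < 1, got beta_start="
            f"{beta_start}, beta_end={beta_end}")
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    abar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    posterior_var = (1.0 - abar_prev) / (1.0 - alpha_bar) * beta
    return DiffusionSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar,
                             posterior_var=posterior_var)


def _check_like(a: np.ndarray, b: np.ndarray, what: str):
    if np.shape(a) != np.shape(b):
        raise ValueError(f"{what}: shape {np.shape(a)} != {np.shape(b)}")


def forward_sample(x0, t: int, eps, sched: DiffusionSchedule) -> NoisyState:
    """Closed-form draw from q(x_t | x_0) given the noise realisation eps."""
    x0 = np.asarray(x0, dtype=float)
    eps = np.asarray(eps, dtype=float)
    _check_like(eps, x0, "eps vs x0")
    ab = sched.abar(t)
    return NoisyState(np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps, t)


def forward_step(x_prev, t: int, noise, sched: DiffusionSchedule) -> NoisyState:
    """Single diffusion step q(x_t | x_{t-1}) with given noise realisation."""
    x_prev = np.asarray(x_prev, dtype=float)
    noise = np.asarray(noise, dtype=float)
    _check_like(noise, x_prev, "noise vs x_prev")
    b = float(sched.beta[t - 1]) if 1 <= t <= sched.T else sched._check_t(t)
    return NoisyState(np.sqrt(1.0 - b) * x_prev + np.sqrt(b) * noise, t)


def estimate_x0(x_t, t: int, eps_pred, sched: DiffusionSchedule) -> np.ndarray:
    """Invert the closed-form forward draw: (x_t - sqrt(1-abar_t) eps) / sqrt(abar_t)."""
    x_t = np.asarray(x_t, dtype=float)
    eps_pred = np.asarray(eps_pred, dtype=float)
    ab = sched.abar(t)
    return (x_t - np.sqrt(1.0 - ab) * eps_pred) / np.sqrt(ab)


def posterior_params(x_t, t: int, eps_pred, sched: DiffusionSchedule,
                     clip_x0: tuple[float, float] | None = None
                     ) -> tuple[np.ndarray, float]:
    """Mean and variance of the denoising transition p(x_{t-1} | x_t).

    mean = sqrt(abar_{t-1}) beta_t / (1 - abar_t) * x0_hat
         + sqrt(alpha_t) (1 - abar_{t-1}) / (1 - abar_t) * x_t,
    var  = (1 - abar_{t-1}) / (1 - abar_t) * beta_t.

    The condition enters only through ``eps_pred``, which the caller obtains
    from the network under the chosen condition set.  ``clip_x0`` optionally
    clamps the estimated clean image to the data range before the mean is
    formed; ancestral sampling uses this to keep imperfect noise predictions
    from driving the chain out of distribution.
    """
    x_t = np.asarray(x_t, dtype=float)
    ab = sched.abar(t)
    ab_prev = sched.abar_prev(t)
    beta = float(sched.beta[t - 1])
    alpha = float(sched.alpha[t - 1])
    x0_hat = estimate_x0(x_t, t, eps_pred, sched)
    if clip_x0 is not None:
        x0_hat = np.clip(x0_hat, clip_x0[0], clip_x0[1])
    coef0 = np.sqrt(ab_prev) * beta / (1.0 - ab)
    coeft = np.sqrt(alpha) * (1.0 - ab_prev) / (1.0 - ab)
    mean = coef0 * x0_hat + coeft * x_t
    var = float(sched.posterior_var[t - 1])
    return mean, var


def _predict_type(model) -> str:
    return getattr(getattr(model, "spec", None), "predict_type", "eps")


def _predict_eps(model, x_t: np.ndarray, cond: ConditionSet, t: int,
                 sched: DiffusionSchedule) -> np.ndarray:
    """Noise prediction under the condition, for either network
    parameterization ("eps" direct, or "x0" converted algebraically)."""
    stacked = np.concatenate([x_t, *cond.images], axis=0)
    out = model.predict(stacked[None], np.array([t]))[0]
    if _predict_type(model) == "x0":
        ab = sched.abar(t)
        out = (x_t - np.sqrt(ab) * out) / np.sqrt(1.0 - ab)
    return out


def denoise_step(x_t, t: int, model, cond: ConditionSet,
                 sched: DiffusionSchedule, rng: np.random.Generator,
                 clip_x0: tuple[float, float] | None = None) -> NoisyState:
    """One ancestral sampling step x_t -> x_{t-1} under the condition.

    No noise is injected at t = 1, so the final transition is deterministic.
    """
    x_t = np.asarray(x_t, dtype=float)
    eps_pred = _predict_eps(model, x_t, cond, t, sched)
    mean, var = posterior_params(x_t, t, eps_pred, sched, clip_x0=clip_x0)
    if t > 1 and var > 0.0:
        mean = mean + np.sqrt(var) * rng.standard_normal(mean.shape)
    return NoisyState(mean, t - 1)


def sample(model, cond: ConditionSet, layout: UnitLayout,
           sched: DiffusionSchedule, rng: np.random.Generator,
           clip_x0: tuple[float, float] | None = (0.0, 1.0)) -> np.ndarray:
    """Impute a full volume by unit-wise ancestral sampling and reassembly.

    By default the running x0 estimate is clipped to [0, 1], the range of
    min-max normalized images.
    """
    if cond.shape != layout.volume_shape:
        raise ValueError(
            f"condition shape {cond.shape} does not match layout volume "
            f"{layout.volume_shape}")
    from .unitizer import LocalContinuousUnit  # local import to avoid cycle noise
    units = []
    for indices in generation_units(layout):
        cond_unit = cond.extract_units(indices)
        x = rng.standard_normal((layout.unit_channels, layout.H, layout.W))
        for t in range(sched.T, 0, -1):
            x = denoise_step(x, t, model, cond_unit, sched, rng,
                             clip_x0=clip_x0).x_t
        units.append(LocalContinuousUnit(data=x, slice_indices=tuple(indices)))
    return assemble(units, layout)


def training_loss(model, target_unit, cond_units: ConditionSet, t, eps,
                  sched: DiffusionSchedule, return_graph: bool = False):
    """Noise-prediction objective: mean squared error between the injected
    noise and the network's prediction on the diffused target stacked with
    the clean condition units.

    ``target_unit`` and ``eps`` may be a single unit (C, H, W) or a batch
    (N, C, H, W); ``t`` is then a scalar or an array of length N.  With
    ``return_graph=True`` the differentiable loss node is returned for
    optimization; otherwise a float.
    """
    target = np.asarray(target_unit, dtype=np.float32)
    eps = np.asarray(eps, dtype=np.float32)
    _check_like(eps, target, "eps vs target_unit")
    squeeze = target.ndim == 3
    if squeeze:
        target = target[None]
        eps = eps[None]
        cond_imgs = [np.asarray(c, dtype=np.float32)[None]
                     for c in cond_units.images]
    else:
        cond_imgs = [np.asarray(c, dtype=np.float32) for c in cond_units.images]
    t_arr = np.atleast_1d(np.asarray(t, dtype=int))
    if t_arr.size == 1:
        t_arr = np.full(target.shape[0], int(t_arr[0]))
    ab = sched.alpha_bar[t_arr - 1].astype(np.float32)[:, None, None, None]
    x_t = np.sqrt(ab) * target + np.sqrt(1.0 - ab) * eps
    net_in = Tensor(np.concatenate([x_t, *cond_imgs], axis=1))
    pred = model.forward(net_in, t_arr)
    if _predict_type(model) == "x0":
        # eps_hat = (x_t - sqrt(abar) g) / sqrt(1 - abar); the objective is
        # still the squared noise-prediction error.
        eps_hat = (Tensor(x_t) - pred * np.sqrt(ab)) * (1.0 / np.sqrt(1.0 - ab))
    else:
        eps_hat = pred
    diff = eps_hat - Tensor(eps)
    loss = (diff * diff).mean()
    return loss if return_graph else loss.item()
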