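"""Comparator imputers: forward filling, adjacent-visit averaging, and
autoencoder regression with the same backbone as the diffusion model.

naive_p copies the past observed image; naive_pf averages the past and
following images voxelwise.  The autoencoders take the clean condition
units only (no noisy target channel, constant t = 0 embedding) and are
trained under an l2 reconstruction loss until the loss plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._train_utils import draw_unit_batch, training_targets
from .autodiff import Tensor
from .denoiser import Denoiser, DenoiserSpec, build_denoiser, spec_for_layout
from .diffusion import ConditionSet
from .unitizer import LocalContinuousUnit, UnitLayout, assemble, generation_units

__all__ = ["naive_p", "naive_pf", "train_ae", "ae_impute", "AETrainConfig"]


def naive_p(past: np.ndarray) -> np.ndarray:
    """Forward filling: the missing visit is the past image, unchanged."""
    past = np.asarray(past)
    if not np.all(np.isfinite(past)):
        raise ValueError("past image contains non-finite values")
    return past.copy()


def naive_pf(past: np.ndarray, following: np.ndarray) -> np.ndarray:
    """Voxelwise mean of the adjacent past and following images."""
    past = np.asarray(past)
    following = np.asarray(following)
    if past.shape != following.shape:
        raise ValueError(
            f"shape mismatch: past {past.shape} vs following {following.shape}")
    return 0.5 * (past + following)


@dataclass
class AETrainConfig:
    """Autoencoder training settings (l2 objective, plateau stopping)."""

    lr: float = 1e-4
    batch_size: int = 16
    max_steps: int = 20000
    plateau_window: int = 500
    plateau_tol: float = 1e-3   # relative improvement threshold (0.1%)
    seed: int = 0
    log_every: int = 100


def _ae_loss(model: Denoiser, target: np.ndarray, cond_arrays, t0: np.ndarray,
             return_graph: bool):
    net_in = Tensor(np.concatenate(cond_arrays, axis=1))
    pred = model.forward(net_in, t0)
    diff = pred - Tensor(target)
    loss = (diff * diff).mean()
    return loss if return_graph else loss.item()


def train_ae(records, layout: UnitLayout, spec: DenoiserSpec,
             cfg: AETrainConfig, kind: str,
             log: list | None = None) -> Denoiser:
    """Fit the autoencoder by SGD on mean squared unit reconstruction error.

    Stops when the running-mean loss over ``plateau_window`` steps improves
    by less than ``plateau_tol`` twice consecutively, or at ``max_steps``.
    """
    targets = training_targets(records, kind)
    rng = np.random.default_rng(cfg.seed)
    model = build_denoiser(spec, rng)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    t0 = None
    window_losses: list[float] = []
    prev_window_mean = None
    stalls = 0
    for step in range(1, cfg.max_steps + 1):
        target, cond_arrays = draw_unit_batch(
            records, targets, layout, kind, cfg.batch_size, rng)
        if t0 is None or t0.shape[0] != target.shape[0]:
            t0 = np.zeros(target.shape[0], dtype=int)
        model.zero_grad()
        loss = _ae_loss(model, target, cond_arrays, t0, return_graph=True)
        loss.backward()
        opt.step()
        window_losses.append(loss.item())
        if log is not None and step % cfg.log_every == 0:
            log.append({"step": step, "loss": float(np.mean(
                window_losses[-cfg.log_every:]))})
        if len(window_losses) >= cfg.plateau_window:
            mean = float(np.mean(window_losses))
            window_losses.clear()
            if prev_window_mean is not None:
                rel = (prev_window_mean - mean) / max(prev_window_mean, 1e-12)
                stalls = stalls + 1 if rel < cfg.plateau_tol else 0
                if stalls >= 2:
                    break
            prev_window_mean = mean
    return model


def ae_impute(model: Denoiser, cond: ConditionSet,
              layout: UnitLayout) -> np.ndarray:
    """Deterministic unit-wise prediction over the generation units."""
    expected = cond.n_images * layout.unit_channels
    if model.spec.in_channels != expected:
        raise ValueError(
            f"checkpoint expects {model.spec.in_channels} input channels but "
            f"condition kind {cond.kind} with this layout provides {expected}")
    units = []
    for indices in generation_units(layout):
        cu = cond.extract_units(indices)
        stacked = np.concatenate(cu.images, axis=0).astype(np.float32)
        pred = model.predict(stacked[None], np.array([0]))[0]
        units.append(LocalContinuousUnit(data=pred.astype(np.float64),
                                         slice_indices=tuple(indices)))
    return assemble(units, layout)
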