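"""End-to-end orchestration: training, imputation, evaluation, folds, config.

The diffusion trainer follows the study protocol: per step it samples a
batch of (subject, missing visit) targets, draws one random local-continuous
unit per target with matched condition units, draws t uniformly in [1, T]
and Gaussian noise, and descends on the noise-prediction loss with Adam.
Runs are fully reproducible from (config, seed); checkpoints carry model,
optimizer and generator state so a resumed run is bitwise identical to an
uninterrupted one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import baselines, metrics
from ._train_utils import draw_unit_batch, training_targets
from .cohort import (CohortSpec, LongitudinalRecord, apply_missingness,
                     default_regions, generate_cohort, imputation_targets,
                     read_nifti, write_nifti)
from .denoiser import (Denoiser, DenoiserSpec, build_denoiser, load_checkpoint,
                       save_checkpoint, spec_for_layout)
from .diffusion import (ConditionSet, DiffusionSchedule, make_schedule, sample,
                        training_loss)
from .nn import Adam
from .unitizer import UnitLayout, make_layout

__all__ = ["TrainConfig", "FoldPlan", "make_folds", "train_diffusion",
           "impute_records", "evaluate_imputations", "load_config",
           "default_config", "IMPUTER_NAMES"]

IMPUTER_NAMES = ("naive-p", "naive-pf", "ae-p", "ae-pf", "diff-p", "diff-pf")


@dataclass
class TrainConfig:
    """Diffusion-model training settings."""

    lr: float = 1e-4
    batch_size: int = 16
    max_steps: int = 5000
    optimizer: str = "adam"
    seed: int = 0
    checkpoint_every: int = 1000
    condition_kind: str = "PF"
    log_every: int = 100

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size <= 0 or self.max_steps <= 0:
            raise ValueError("lr, batch_size and max_steps must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.condition_kind not in ("P", "PF"):
            raise ValueError("condition_kind must be 'P' or 'PF'")


def train_diffusion(records: list[LongitudinalRecord], layout: UnitLayout,
                    spec: DenoiserSpec, sched: DiffusionSchedule,
                    cfg: TrainConfig, out_dir=None, resume_from=None,
                    log: list | None = None) -> tuple[Denoiser, int]:
    """Train the noise predictor; returns (model, completed steps)."""
    kind = cfg.condition_kind
    targets = training_targets(records, kind)
    n_cond = 1 if kind == "P" else 2
    if spec.in_channels != (1 + n_cond) * layout.unit_channels:
        raise ValueError(
            f"denoiser expects {spec.in_channels} input channels but kind "
            f"{kind} with this layout needs "
            f"{(1 + n_cond) * layout.unit_channels}")
    if resume_from is not None:
        model, start_step, opt_state, rng_state = load_checkpoint(resume_from)
        rng = np.random.default_rng()
        rng.bit_generator.state = rng_state
        opt = Adam(model.parameters(), lr=cfg.lr)
        if opt_state is not None:
            opt.set_state(opt_state)
    else:
        rng = np.random.default_rng(cfg.seed)
        model = build_denoiser(spec, rng)
        opt = Adam(model.parameters(), lr=cfg.lr)
        start_step = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    recent: list[float] = []
    for step in range(start_step + 1, cfg.max_steps + 1):
        target, cond_arrays = draw_unit_batch(
            records, targets, layout, kind, cfg.batch_size, rng)
        t = rng.integers(1, sched.T + 1, size=target.shape[0])
        eps = rng.standard_normal(target.shape).astype(np.float32)
        cond = ConditionSet(kind, tuple(cond_arrays))
        model.zero_grad()
        loss = training_loss(model, target, cond, t, eps, sched,
                             return_graph=True)
        loss.backward()
        opt.step()
        recent.append(loss.item())
        if log is not None and step % cfg.log_every == 0:
            log.append({"step": step,
                        "loss": float(np.mean(recent[-cfg.log_every:]))})
            recent = recent[-cfg.log_every:]
        if out_dir is not None and (step % cfg.checkpoint_every == 0
                                    or step == cfg.max_steps):
            save_checkpoint(out_dir / f"checkpoint_{step:06d}.npz", model,
                            step=step, optimizer_state=opt.get_state(),
                            rng_state=rng.bit_generator.state)
    return model, cfg.max_steps


def _conditions_for(rec: LongitudinalRecord, r: int, kind: str) -> ConditionSet:
    imgs = [rec.visits[r - 1].image]
    if kind == "PF":
        imgs.append(rec.visits[r + 1].image)
    return ConditionSet(kind, tuple(imgs))


def impute_records(records: list[LongitudinalRecord], imputer: str,
                   layout: UnitLayout | None = None,
                   sched: DiffusionSchedule | None = None,
                   model: Denoiser | None = None,
                   rng: np.random.Generator | None = None
                   ) -> dict[tuple[int, int], np.ndarray]:
    """Impute every missing visit whose required neighbours are observed.

    Returns {(record index, visit index): imputed volume}.  Visits whose
    neighbours are themselves missing are skipped.
    """
    if imputer not in IMPUTER_NAMES:
        raise ValueError(f"unknown imputer {imputer!r}; one of {IMPUTER_NAMES}")
    kind = "P" if imputer.endswith("-p") else "PF"
    needs_model = imputer.startswith(("ae", "diff"))
    if needs_model:
        if model is None or layout is None:
            raise ValueError(f"imputer {imputer} requires a model and layout")
        n_cond = 1 if kind == "P" else 2
        n_in = ((1 + n_cond) if imputer.startswith("diff") else n_cond)
        expected = n_in * layout.unit_channels
        if model.spec.in_channels != expected:
            raise ValueError(
                f"checkpoint has {model.spec.in_channels} input channels but "
                f"imputer {imputer} with this layout needs {expected}")
    if imputer.startswith("diff"):
        if sched is None:
            raise ValueError("diffusion imputers require a schedule")
        if rng is None:
            raise ValueError("diffusion imputers require a seeded generator")
    out: dict[tuple[int, int], np.ndarray] = {}
    for ri, r in imputation_targets(records, kind):
        rec = records[ri]
        if imputer == "naive-p":
            vol = baselines.naive_p(rec.visits[r - 1].image)
        elif imputer == "naive-pf":
            vol = baselines.naive_pf(rec.visits[r - 1].image,
                                     rec.visits[r + 1].image)
        elif imputer.startswith("ae"):
            vol = baselines.ae_impute(model, _conditions_for(rec, r, kind),
                                      layout)
        else:
            vol = sample(model, _conditions_for(rec, r, kind), layout, sched,
                         rng)
        out[(ri, r)] = vol
    return out


def evaluate_imputations(imputed: dict[tuple[int, int], np.ndarray],
                         records: list[LongitudinalRecord],
                         data_range: float = 1.0
                         ) -> tuple[list[metrics.MetricReport], dict]:
    """Masked SSIM/PSNR/MSE plus regional error and progression rates.

    Regional volumes of imputed, observed and previous images are all
    extracted with the same nearest-class-mean segmentation, calibrated on
    the observed past visit, so an oracle imputation scores error rate 0.
    """
    reports = []
    mses = []
    for (ri, r), vol in sorted(imputed.items()):
        rec = records[ri]
        truth = rec.visits[r].image
        mask = rec.brain_mask
        past = rec.visits[r - 1].image
        cm = metrics.class_means_from(past, rec.labelmaps[r - 1], mask)
        y_hat = metrics.region_volumes(
            metrics.segment_by_intensity(vol, mask, cm),
            float(np.prod(rec.spacing)))
        y_obs = metrics.region_volumes(
            metrics.segment_by_intensity(truth, mask, cm),
            float(np.prod(rec.spacing)))
        y_prev = metrics.region_volumes(
            metrics.segment_by_intensity(past, mask, cm),
            float(np.prod(rec.spacing)))
        rep = metrics.MetricReport(
            ssim=metrics.ssim(vol, truth, mask, data_range=data_range),
            psnr_db=metrics.psnr(vol, truth, mask, data_range=data_range),
            error_rate=metrics.error_rate(y_hat, y_obs),
            progression_rate=metrics.progression_rate(y_hat, y_prev),
            progression_gap=metrics.progression_gap(y_hat, y_obs, y_prev))
        reports.append(rep)
        mses.append(metrics.masked_mse(vol, truth, mask))
    summary = {
        "n_targets": len(reports),
        "ssim": float(np.mean([r.ssim for r in reports])),
        "psnr_db": float(np.mean([r.psnr_db for r in reports])),
        "masked_mse": float(np.mean(mses)),
        "error_rate": float(np.mean([r.mean_error_rate for r in reports])),
        "progression_rate": float(np.mean(
            [r.mean_progression_rate for r in reports])),
        "progression_gap": float(np.mean(
            [r.mean_progression_gap for r in reports])),
    }
    return reports, summary


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint test folds with an 8:1 train:validation split of the rest."""

    n_folds: int
    folds: tuple[dict, ...]   # each: {"test": [...], "train": [...], "val": [...]}

    def __post_init__(self):
        seen = set()
        for f in self.folds:
            for sid in f["test"]:
                if sid in seen:
                    raise ValueError(f"subject {sid} in more than one test fold")
                seen.add(sid)


def make_folds(subject_ids: list[str], n_folds: int = 10,
               seed: int = 0) -> FoldPlan:
    """Random disjoint partition into test folds; remaining subjects are
    split 8:1 into training and validation for each fold."""
    ids = list(subject_ids)
    if n_folds < 2 or n_folds > len(ids):
        raise ValueError(f"n_folds must be in [2, {len(ids)}]")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    test_sets = [perm[i::n_folds] for i in range(n_folds)]
    folds = []
    for i in range(n_folds):
        rest = [s for s in perm if s not in test_sets[i]]
        n_val = max(1, round(len(rest) / 9))
        folds.append({"test": list(test_sets[i]), "train": rest[n_val:],
                      "val": rest[:n_val]})
    return FoldPlan(n_folds=n_folds, folds=tuple(folds))


def run_phantom_study(seed: int, train_steps: int = 1200,
                      n_subjects: int = 24, n_test: int = 4,
                      imputers: tuple[str, ...] = ("diff-pf", "naive-p",
                                                   "naive-pf"),
                      lr: float = 3e-4, batch_size: int = 8,
                      T: int = 50) -> dict[str, dict]:
    """Scaled end-to-end imputation study on the synthetic cohort.

    Generates a 24-subject, 5-visit, 32^3 phantom cohort (0.95 per-visit
    axis shrinkage, noise sd 0.02), applies the past+following missingness
    pattern, trains the tiny diffusion imputer on all but ``n_test``
    held-out subjects, and evaluates the requested imputers on the held-out
    subjects.  Returns {imputer: evaluation summary}.

    The diffusion chain uses T = 50 with the linear beta range rescaled by
    1000/T from the full-length default, so the terminal marginal is still
    (numerically) a standard normal.
    """
    root = np.random.SeedSequence(seed)
    s_cohort, s_train, s_sample = [int(c.generate_state(1)[0] % (2 ** 31))
                                   for c in root.spawn(3)]
    cohort = CohortSpec(n_subjects=n_subjects, n_visits=5,
                        shape=(32, 32, 32),
                        regions=default_regions(rho=0.95),
                        noise_sd=0.02, seed=s_cohort)
    records = apply_missingness(generate_cohort(cohort), "PF")
    train, test = records[:-n_test], records[-n_test:]
    layout = make_layout(32, 32, 32, K=5, J=1)
    scale = 1000 / T
    sched = make_schedule(T, 1e-4 * scale, min(0.02 * scale, 0.999))
    model = None
    if any(name.startswith("diff") for name in imputers):
        spec = spec_for_layout(layout, 2, "tiny")
        cfg = TrainConfig(lr=lr, batch_size=batch_size, max_steps=train_steps,
                          checkpoint_every=train_steps, condition_kind="PF",
                          seed=s_train)
        model, _ = train_diffusion(train, layout, spec, sched, cfg)
    results = {}
    for name in imputers:
        imputed = impute_records(
            test, name, layout=layout, sched=sched,
            model=model if name.startswith("diff") else None,
            rng=np.random.default_rng(s_sample))
        _, summary = evaluate_imputations(imputed, test)
        results[name] = summary
    return results


# -- configuration ------------------------------------------------------------

def default_config() -> dict:
    """Nested default configuration for the command-line pipeline."""
    return {
        "cohort": {"n_subjects": 24, "n_visits": 5, "shape": [32, 32, 32],
                   "rho": 0.95, "noise_sd": 0.02, "seed": 0},
        "layout": {"K": 5, "J": 1},
        "schedule": {"T": 1000, "beta_start": 1e-4, "beta_end": 0.02},
        "denoiser": {"preset": "tiny"},
        "train": {"lr": 1e-4, "batch_size": 16, "max_steps": 5000,
                  "checkpoint_every": 1000, "condition_kind": "PF",
                  "seed": 0},
        "eval": {"data_range": 1.0},
    }


def load_config(path) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            if not isinstance(values, dict):
                raise ValueError(f"config section {section!r} must be a map")
            cfg[section].update(values)
    return cfg


def write_resolved_config(cfg: dict, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg))


def cohort_from_config(cfg: dict, seed: int | None = None) -> CohortSpec:
    c = cfg["cohort"]
    return CohortSpec(
        n_subjects=int(c["n_subjects"]), n_visits=int(c["n_visits"]),
        shape=tuple(int(s) for s in c["shape"]),
        regions=default_regions(rho=float(c["rho"])),
        noise_sd=float(c["noise_sd"]),
        seed=int(c["seed"] if seed is None else seed))


def layout_from_config(cfg: dict, shape) -> UnitLayout:
    return make_layout(shape[0], shape[1], shape[2],
                       K=int(cfg["layout"]["K"]), J=int(cfg["layout"]["J"]))


def schedule_from_config(cfg: dict) -> DiffusionSchedule:
    s = cfg["schedule"]
    return make_schedule(int(s["T"]), float(s["beta_start"]),
                         float(s["beta_end"]))
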