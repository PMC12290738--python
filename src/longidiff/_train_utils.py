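"""Shared batch construction for the diffusion and autoencoder trainers."""

from __future__ import annotations

import numpy as np

from .cohort import LongitudinalRecord, imputation_targets
from .unitizer import UnitLayout, extract_unit, sample_training_unit


def draw_unit_batch(records: list[LongitudinalRecord],
                    targets: list[tuple[int, int]], layout: UnitLayout,
                    kind: str, batch_size: int, rng: np.random.Generator):
    """Sample (target units, condition units) for one training step.

    Targets are (record, visit) pairs flagged missing whose true image is
    retained; one random local-continuous unit is drawn per target and the
    condition images are extracted at exactly the same slice indices.
    Returns (target batch (N,C,H,W), list of condition batches).
    """
    if not targets:
        raise ValueError("empty training set: no imputable targets")
    n_cond = 1 if kind == "P" else 2
    picks = rng.integers(0, len(targets), size=batch_size)
    tgt, conds = [], [[] for _ in range(n_cond)]
    for p in picks:
        ri, r = targets[p]
        rec = records[ri]
        unit = sample_training_unit(rec.visits[r].image, layout, rng)
        tgt.append(unit.data)
        neighbours = [rec.visits[r - 1].image]
        if n_cond == 2:
            neighbours.append(rec.visits[r + 1].image)
        for j, img in enumerate(neighbours):
            conds[j].append(extract_unit(img, unit.slice_indices).data)
    target = np.stack(tgt).astype(np.float32)
    cond_arrays = [np.stack(c).astype(np.float32) for c in conds]
    return target, cond_arrays


def training_targets(records, kind: str) -> list[tuple[int, int]]:
    targets = imputation_targets(records, kind)
    if not targets:
        raise ValueError("empty training set: no imputable targets")
    return targets
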