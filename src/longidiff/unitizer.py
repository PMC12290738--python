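"""Slicing 3D volumes into local-continuous units and back.

A volume of shape (L, H, W) is split into K segments along the slice axis.
A *unit* stacks one clip of 2J+1 consecutive slices from every segment into
a (K*(2J+1), H, W) array, so a 2D network sees both local slice continuity
(within a clip) and global coverage (one clip per segment).  For training,
clip centers are drawn at random inside each segment; for generation, clips
are taken in order so that every slice of the volume is produced exactly
once, and the generated units are reassembled into the original shape.

When K*(2J+1) does not divide L, the trailing clip of a segment is completed
by replicating the segment's last slice; replicated slots are recorded in the
layout's pad plan and dropped at reassembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["UnitLayout", "LocalContinuousUnit", "make_layout",
           "sample_training_unit", "generation_units", "extract_unit",
           "assemble"]


@dataclass(frozen=True)
class LocalContinuousUnit:
    """One stacked unit plus the source slice index of each channel."""

    data: np.ndarray                 # (K*(2J+1), H, W)
    slice_indices: tuple[int, ...]

    def __post_init__(self):
        if self.data.shape[0] != len(self.slice_indices):
            raise ValueError("slice_indices length must match leading axis")


@dataclass(frozen=True)
class UnitLayout:
    """Segment/clip geometry for one volume shape."""

    L: int
    H: int
    W: int
    K: int
    J: int
    segment_bounds: tuple[tuple[int, int], ...]
    clip_len: int
    units_per_volume: int
    # (unit index, position within unit) slots whose slice is a replicated pad
    pad_plan: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    @property
    def unit_channels(self) -> int:
        return self.K * self.clip_len

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.L, self.H, self.W)


def make_layout(L: int, H: int, W: int, K: int, J: int) -> UnitLayout:
    """Partition [0, L) into K near-equal segments and plan clip coverage.

    Earlier segments receive the extra slices when K does not divide L.
    Every segment must be at least one clip (2J+1 slices) long.
    """
    if min(L, H, W) <= 0:
        raise ValueError(f"volume dimensions must be positive, got {(L, H, W)}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if J < 0:
        raise ValueError(f"J must be >= 0, got {J}")
    clip_len = 2 * J + 1
    base, rem = divmod(L, K)
    bounds = []
    start = 0
    for k in range(K):
        length = base + (1 if k < rem else 0)
        if length < clip_len:
            raise ValueError(
                f"segment {k} has {length} slices, shorter than a clip of "
                f"{clip_len}; reduce K or J")
        bounds.append((start, start + length))
        start += length
    n_units = math.ceil(L / (K * clip_len))
    pads = set()
    for k, (s, e) in enumerate(bounds):
        covered = n_units * clip_len
        n_pad = covered - (e - s)
        for p in range(n_pad):  # pads sit at the tail of the last clip(s)
            flat = covered - 1 - p
            unit_i, pos_in_clip = divmod(flat, clip_len)
            pads.add((unit_i, k * clip_len + pos_in_clip))
    return UnitLayout(L=L, H=H, W=W, K=K, J=J,
                      segment_bounds=tuple(bounds), clip_len=clip_len,
                      units_per_volume=n_units, pad_plan=frozenset(pads))


def _check_volume(volume: np.ndarray, layout: UnitLayout):
    if volume.shape != layout.volume_shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match layout "
            f"{layout.volume_shape}")


def sample_training_unit(volume: np.ndarray, layout: UnitLayout,
                         rng: np.random.Generator) -> LocalContinuousUnit:
    """Draw one random clip per segment and stack them in segment order.

    Clip centers are uniform over the segment interior, skipping the first
    and last J slices so every clip stays inside its segment.
    """
    _check_volume(volume, layout)
    indices: list[int] = []
    for (s, e) in layout.segment_bounds:
        center = int(rng.integers(s + layout.J, e - layout.J))
        indices.extend(range(center - layout.J, center + layout.J + 1))
    idx = tuple(indices)
    return LocalContinuousUnit(data=volume[list(idx)], slice_indices=idx)


def generation_units(layout: UnitLayout) -> list[list[int]]:
    """Ordered slice-index lists covering the whole volume.

    The i-th unit takes the i-th consecutive clip from every segment.  Padded
    slots repeat the segment's last slice index and are identified by the
    layout's pad plan.
    """
    units = []
    for i in range(layout.units_per_volume):
        idx = []
        for (s, e) in layout.segment_bounds:
            for p in range(layout.clip_len):
                idx.append(min(s + i * layout.clip_len + p, e - 1))
        units.append(idx)
    return units


def extract_unit(volume: np.ndarray, indices) -> LocalContinuousUnit:
    """Gather the given slice indices into a stacked unit."""
    indices = tuple(int(i) for i in indices)
    return LocalContinuousUnit(data=volume[list(indices)], slice_indices=indices)


def assemble(units: list[LocalContinuousUnit], layout: UnitLayout) -> np.ndarray:
    """Reassemble generated units into an (L, H, W) volume.

    Units may arrive in any order; they are matched to the layout's
    generation units by their slice indices.  Padded slots are discarded.
    Missing or doubly-written real slices raise.
    """
    gen = {tuple(idx): i for i, idx in enumerate(generation_units(layout))}
    out = np.zeros(layout.volume_shape, dtype=units[0].data.dtype)
    written = np.zeros(layout.L, dtype=bool)
    for unit in units:
        key = tuple(unit.slice_indices)
        if key not in gen:
            raise ValueError(f"unit indices {key} are not a generation unit "
                             "of this layout")
        unit_i = gen[key]
        for pos, sl in enumerate(key):
            if (unit_i, pos) in layout.pad_plan:
                continue
            if written[sl]:
                raise ValueError(f"slice {sl} written more than once")
            out[sl] = unit.data[pos]
            written[sl] = True
    if not written.all():
        missing = np.flatnonzero(~written)
        raise ValueError(f"slices {missing.tolist()} were never generated")
    return out
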