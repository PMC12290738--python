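"""Slicing a 3D volume into local-continuous units and exact reassembly.

A 32-slice volume is split into 5 segments; each unit stacks one 3-slice
clip per segment, so a 2D network sees local continuity and global
coverage at once.  Generation units partition every slice exactly once
(replicated padding slots are dropped on reassembly).
"""

import numpy as np

from longidiff.unitizer import (assemble, extract_unit, generation_units,
                                make_layout, sample_training_unit)

layout = make_layout(L=32, H=32, W=32, K=5, J=1)
print("segments:", layout.segment_bounds)
print("clip length:", layout.clip_len, " units per volume:",
      layout.units_per_volume)
print("padded slots (unit, position):", sorted(layout.pad_plan))

volume = np.random.default_rng(0).random((32, 32, 32))
unit = sample_training_unit(volume, layout, np.random.default_rng(1))
print("\nrandom training unit stacks slices:", unit.slice_indices)
print("unit shape (K*(2J+1), H, W):", unit.data.shape)

units = [extract_unit(volume, idx) for idx in generation_units(layout)]
print("\nordered generation units:")
for u in units:
    print(" ", u.slice_indices)
print("round trip identical:",
      np.array_equal(assemble(units, layout), volume))
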