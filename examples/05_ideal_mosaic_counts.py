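"""Counts on the idealized wild-type lattice: type ratio and density.

The crystalline zebrafish cone mosaic repeats a 12-cone motif
(1 UV : 1 blue : 2 red : 2 green); within each column the pentamer
green-red-blue-red-green is bounded by single UV cones.
"""

from conemosaic import (classify_rods, generate_ideal_mosaic,
                        planimetric_density, render_stack, segment_cells)
from conemosaic.pipeline import cone_type_ratio

lattice = generate_ideal_mosaic(12, 12)
print(f"(red+green)/blue ratio: {lattice.cone_ratio():.2f}")

stack = render_stack(generate_ideal_mosaic(8, 10), z_slices=1)
field = segment_cells(stack.zo1)
field = classify_rods(field, stack.zo1, stack.reporter, seed=0)
density = planimetric_density(field)
print(f"planimetric density (#/10^3 um^2): "
      f"cones {density['cone']:.1f}, rods {density['rod']:.1f}")

ratio, counts = cone_type_ratio(
    {i: t for i, t in enumerate(lattice.types) if t != "rod"})
print(f"counts: {counts} -> ratio {ratio:.2f}")

# The 4.0 ratio is the motif's arithmetic identity; the density uses the
# two-of-four-sides edge rule so that tiling the field with windows
# counts every profile exactly once.
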