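"""Render a fragmented (mutant-like) mosaic and measure cone adjacency.

The renderer produces a two-channel z-stack (junction marker + rod
reporter) at 0.1 um/pixel with full ground truth. The pipeline segments
cell profiles, separates rods from cones by k-means on the reporter
intensity, and identifies adjacent cone pairs by morphological closing
and inertia-tensor measures at two threshold settings.
"""

from conemosaic import (adjacency_graphs, classify_rods,
                        generate_fragmented_mosaic, render_stack,
                        segment_cells)

lattice = generate_fragmented_mosaic(n_fragments=25, mean_length=4.0,
                                     seed=3)
stack = render_stack(lattice, z_slices=1)
field = segment_cells(stack.zo1)
field = classify_rods(field, stack.zo1, stack.reporter, seed=0)
result = adjacency_graphs(field, max_centroid_dist=75.0)

n_rods = sum(1 for v in field.cell_class.values() if v == "rod")
print(f"segmented {len(field.labels)} profiles: "
      f"{len(field.cones())} cones, {n_rods} rods")
print(result.table().to_string(index=False))

# Each row gives the percentage of cones with n identified neighbors at
# one threshold setting; 2-fold coordination marks membership in a
# single-cell-wide chain, the signature of polarized cone-cone adhesion.
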