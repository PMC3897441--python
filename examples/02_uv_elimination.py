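"""Eliminate one presumptive UV cone, fast versus slow.

The UV cone's edge tensions are tripled and its preferred area shrunk by
0.4 at regular intervals; its edges are lost through T1 neighbor
exchanges until the cell is deleted at the cutoff area. With slow
relaxation the protein field has time to protect the within-column
interfaces, so the column usually closes over the vacancy; with fast
relaxation the loss order is arbitrary and a precursor often breaks in.
"""

import numpy as np

from conemosaic import Parameters, descend_sweeps
from conemosaic.growth import (advance_front, eliminate_uv,
                               initialize_growth)

for mode in ("fast", "slow"):
    rng = np.random.default_rng(7)
    packing, front = initialize_growth(2, 1, 12, Parameters(), rng=rng)
    packing, front = advance_front(packing, front, rng)
    descend_sweeps(packing, 10)
    uv = front.uv_cells[front.current_column][0]
    packing, event = eliminate_uv(packing, front, uv, mode)
    print(f"{mode:>4}: outcome {event.outcome} "
          f"(shrink intervals {event.shrink_steps}, "
          f"T1s {event.t1_count}, ambiguous {event.ambiguous})")

# column_intact means the two along-column neighbors now share an edge;
# column_broken means the column was interrupted, classically by a
# precursor cell infringing on the cone column.
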