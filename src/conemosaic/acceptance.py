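"""Desk-scale reproduction of the headline mosaic statistics.

Each function recomputes one headline quantity from scratch by running
the package: the idealized-mosaic cone-type ratio, the first-column UV
spacing, and the column-break prevalence under fast UV elimination.
"""

from __future__ import annotations

import numpy as np

from .geometry import Parameters
from .growth import GrowthConfig, initialize_growth, advance_front, \
    run_growth_experiment
from .synth import generate_ideal_mosaic

__all__ = ["ideal_mosaic_ratio", "first_column_uv_spacing",
           "column_break_percentage"]


def ideal_mosaic_ratio(n_columns: int = 12, n_rows: int = 12) -> float:
    """(red+green)/blue cone ratio of the idealized wild-type lattice."""
    return generate_ideal_mosaic(n_columns, n_rows).cone_ratio()


def first_column_uv_spacing(seed: int = 0, cells_per_column: int = 24) -> float:
    """Mean number of non-UV cones between successive UV cones in the
    first differentiated column."""
    rng = np.random.default_rng(seed)
    packing, front = initialize_growth(0, 1, cells_per_column,
                                       Parameters(seed=seed), rng=rng,
                                       settle=False)
    packing, front = advance_front(packing, front, rng)
    col = front.current_column
    rows = sorted(packing.cells[c].row for c in front.uv_cells[col])
    if len(rows) < 2:
        raise RuntimeError("need at least two UV cones to measure spacing")
    gaps = [(rows[(i + 1) % len(rows)] - rows[i]) % cells_per_column - 1
            for i in range(len(rows))]
    return float(np.mean(gaps))


def column_break_percentage(seed: int = 0, n_events_min: int = 100,
                            n_columns: int = 8, cells_per_column: int = 12,
                            n_established: int = 3,
                            progress: bool = False) -> dict:
    """Percentage of UV eliminations that break the cone column under
    fast relaxation (shrink factor 0.4, threefold UV edge tension).

    Accumulates at least ``n_events_min`` elimination events over as many
    seeded growth simulations as needed (>= 3).
    """
    rng = np.random.default_rng(seed)
    broken = intact = amb = total = 0
    runs = 0
    while total < n_events_min or runs < 3:
        run_seed = int(rng.integers(2 ** 31 - 1))
        cfg = GrowthConfig(n_columns=n_columns,
                           cells_per_column=cells_per_column,
                           n_established=n_established,
                           mode="mutant", relaxation="fast", seed=run_seed)
        _, _, rep = run_growth_experiment(cfg)
        broken += rep.n_broken
        intact += rep.n_intact
        amb += rep.n_ambiguous
        total += rep.n_events
        runs += 1
        if progress:
            print(f"  run {runs} (seed {run_seed}): {rep.n_events} events, "
                  f"running fraction {broken / total:.3f}")
    return {"percent_broken": 100.0 * broken / total, "n_events": total,
            "n_broken": broken, "n_intact": intact, "n_ambiguous": amb,
            "n_runs": runs}
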