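"""The propagating differentiation front and UV-cone elimination.

New cone columns are added at the margin by converting the next column of
precursor cells; uniformly spaced cells in the new column are marked as
presumptive UV cones (about five cones between successive UV cones, and
in later columns the cell nearest the midpoint of the previous column's
UV pair).  In the mutant scenario each presumptive UV cone is then
eliminated: its edge tensions are tripled, its preferred area is shrunk
by the factor rho at regular sweep intervals while its protein total
follows its perimeter, its edges are lost through T1 transitions, and the
cell is deleted once it falls below the cutoff area.  The outcome of each
elimination is classified by whether the column closes over the vacated
space (intact) or a precursor cell bridges the gap (broken).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import pcp
from .geometry import (CellType, Packing, Parameters, descend_sweeps,
                       relax, remove_cell, t1_transition)
from .lattice import build_columnar_packing, column_map

__all__ = [
    "FrontState",
    "EliminationEvent",
    "GrowthConfig",
    "GrowthReport",
    "GrowthExhausted",
    "StalledElimination",
    "initialize_growth",
    "advance_front",
    "eliminate_uv",
    "classify_outcome",
    "run_growth_experiment",
]

#: spectral type by phase relative to the UV position within a column:
#: uv, then the pentamer green-red-blue-red-green
_PHASE_TYPES = (CellType.UV, CellType.GREEN, CellType.RED, CellType.BLUE,
                CellType.RED, CellType.GREEN)
UV_PERIOD = 6          # one UV per six column cells: five cones between


class GrowthExhausted(RuntimeError):
    """No precursor column is left to convert."""


class StalledElimination(RuntimeError):
    """A UV cone failed to shrink below the cutoff within the budget."""


@dataclass
class FrontState:
    current_column: int                    # last converted column index
    n_established: int
    columns: dict[int, list[int]] = field(default_factory=dict)
    uv_cells: dict[int, list[int]] = field(default_factory=dict)
    #: y positions of UV marks per column, recorded at marking time (UV
    #: cells are later eliminated in the mutant; the midpoint rule for the
    #: next column works from these recorded marks)
    uv_marks: dict[int, list[float]] = field(default_factory=dict)
    grid_columns: dict[int, list[int]] = field(default_factory=dict)

    def cone_cells(self) -> list[int]:
        return [c for ids in self.columns.values() for c in ids]


@dataclass
class EliminationEvent:
    uv_cell: int
    column: int
    shrink_steps: int
    t1_count: int
    final_area: float
    outcome: str                           # column_intact | column_broken
    ambiguous: bool
    neighbors_before: tuple[int, int]

    def to_dict(self) -> dict:
        return {"uv_cell": self.uv_cell, "column": self.column,
                "shrink_steps": self.shrink_steps, "t1_count": self.t1_count,
                "final_area": self.final_area, "outcome": self.outcome,
                "ambiguous": self.ambiguous,
                "neighbors_before": list(self.neighbors_before)}


# --------------------------------------------------------------------------

def initialize_growth(n_established: int, n_grow: int, cells_per_column: int,
                      params: Parameters | None = None,
                      n_buffer: int = 3,
                      rng: np.random.Generator | None = None,
                      settle: bool = True) -> tuple[Packing, FrontState]:
    """Build the starting packing: ``n_established`` polarized cone columns
    against the central-retina wall, then precursors out to the margin."""
    params = params or Parameters()
    rng = rng or np.random.default_rng(params.seed)
    n_total = n_established + n_grow + n_buffer
    packing = build_columnar_packing(n_total, cells_per_column, params)
    grid_cols = column_map(packing)
    front = FrontState(current_column=n_established - 1,
                       n_established=n_established,
                       grid_columns=grid_cols)

    offset0 = int(rng.integers(UV_PERIOD))
    for col in range(n_established):
        ids = grid_cols[col]
        off = (offset0 + 3 * col) % UV_PERIOD
        uv_here = []
        for cid in ids:
            r = packing.cells[cid].row
            phase = (r - off) % UV_PERIOD
            packing.cells[cid].type = _PHASE_TYPES[phase]
            if phase == 0:
                uv_here.append(cid)
        front.columns[col] = list(ids)
        front.uv_cells[col] = uv_here
        front.uv_marks[col] = [float(packing.cell_centroid(c)[1])
                               for c in uv_here]
    pcp.initialize_polarized_pcp(packing, front.cone_cells())
    packing.invalidate()
    if settle:
        relax(packing, max_steps=500)
    return packing, front


def _ydist(packing: Packing, y1: float, y2: float) -> float:
    d = abs(y1 - y2)
    return min(d, packing.Ly - d)


def advance_front(packing: Packing, front: FrontState,
                  rng: np.random.Generator) -> tuple[Packing, FrontState]:
    """Convert the next precursor column to cone cells and mark UV cones."""
    col = front.current_column + 1
    ids = [c for c in front.grid_columns.get(col, []) if c in packing.cells]
    if not ids or any(packing.cells[c].type is not CellType.PRECURSOR
                      for c in ids):
        raise GrowthExhausted(f"no precursor column at index {col}")
    ids.sort(key=lambda c: packing.cells[c].row)
    n = len(ids)

    prev_marks = front.uv_marks.get(col - 1, [])
    uv_rows: list[int] = []
    if len(prev_marks) >= 2:
        # midpoint rule between successive UV pairs of the previous column
        ys = sorted(prev_marks)
        cys = [float(packing.cell_centroid(c)[1]) for c in ids]
        taken: set[int] = set()
        for i, y1 in enumerate(ys):
            y2 = ys[(i + 1) % len(ys)]
            gap = (y2 - y1) % packing.Ly
            ymid = (y1 + 0.5 * gap) % packing.Ly
            order = sorted(range(n), key=lambda j: _ydist(packing, cys[j], ymid))
            for j in order:
                if j not in taken:
                    taken.add(j)
                    uv_rows.append(j)
                    break
    else:
        # first cone column: every sixth cell, seeded random offset
        off = int(rng.integers(UV_PERIOD))
        uv_rows = [j for j in range(n) if (j - off) % UV_PERIOD == 0]

    uv_rows = sorted(uv_rows)
    uv_ids = []
    phase_of = {}
    for j in uv_rows:
        phase_of[j] = 0
    # spectral types by distance to the nearest UV mark, so every UV is
    # flanked by green cones even when gaps deviate from five
    if uv_rows:
        for j in range(n):
            if j in phase_of:
                continue
            d = min(min((j - u) % n, (u - j) % n) for u in uv_rows)
            phase_of[j] = min(d, 3)
    else:
        for j in range(n):
            phase_of[j] = 1 + (j % (UV_PERIOD - 1))

    for j, cid in enumerate(ids):
        ph = phase_of[j]
        packing.cells[cid].type = _PHASE_TYPES[ph]
        packing.cells[cid].column = col
        if ph == 0:
            uv_ids.append(cid)

    pcp.initialize_random_pcp(packing, ids, rng)
    front.columns[col] = list(ids)
    front.uv_cells[col] = uv_ids
    front.uv_marks[col] = [float(packing.cell_centroid(c)[1])
                           for c in uv_ids]
    front.current_column = col
    packing.invalidate()
    return packing, front


# --------------------------------------------------------------------------

def _column_neighbors(packing: Packing, front: FrontState,
                      uv_cell: int) -> tuple[int, int]:
    col = packing.cells[uv_cell].column
    ids = [c for c in front.columns.get(col, []) if c in packing.cells]
    k = ids.index(uv_cell)
    return ids[(k - 1) % len(ids)], ids[(k + 1) % len(ids)]


def eliminate_uv(packing: Packing, front: FrontState, uv_cell: int,
                 mode: str = "fast",
                 max_intervals: int = 30) -> tuple[Packing, EliminationEvent]:
    """Run the elimination protocol on one presumptive UV cone.

    ``mode='fast'`` relaxes ``tau`` sweeps per shrink interval,
    ``mode='slow'`` ten times as many, so in the slow limit the packing
    and the protein field equilibrate between successive area reductions.
    """
    if mode not in ("fast", "slow"):
        raise ValueError("mode must be 'fast' or 'slow'")
    p = packing
    cell = p.cells[uv_cell]
    if cell.type is not CellType.UV:
        raise ValueError(f"cell {uv_cell} is not a UV cone")
    pars = p.params
    column = cell.column
    u, d = _column_neighbors(p, front, uv_cell)
    cell.tension_factor = pars.uv_tension_factor
    p.invalidate()

    sweeps = pars.shrink_interval * (1 if mode == "fast" else 10)
    mean_a0 = float(np.mean([c.preferred_area for c in p.cells.values()]))
    a_min = pars.cutoff_area * mean_a0
    t1_total = 0
    k = 0
    removed = False
    final_area = a_min
    jammed_triangle = 0
    for k in range(1, max_intervals + 1):
        cell.preferred_area *= pars.shrink_factor
        perim_before = p.cell_perimeter(uv_cell)
        area_before = p.cell_area(uv_cell)
        p.invalidate()
        t1_total += descend_sweeps(p, sweeps)
        if uv_cell not in p.cells:      # collapsed via T1s to nothing
            removed = True
            break
        # protein total follows the perimeter so concentrations stay finite
        perim_after = p.cell_perimeter(uv_cell)
        if perim_before > 0:
            fac = perim_after / perim_before
            for eid in cell.edge_cycle:
                if uv_cell in p.edges[eid].pcp_amount:
                    p.edges[eid].pcp_amount[uv_cell] *= fac
            p.invalidate()
        area = p.cell_area(uv_cell)
        if (area >= a_min and len(cell.edge_cycle) > 3
                and area > 0.9 * area_before):
            # shrinkage jammed against neighbor pressure: the next edge to
            # go is the currently shortest one.  Tension and protein state
            # act through the lengths: given enough relaxation, taut
            # (protein-poor, high-tension) edges out-contract the
            # protein-held ones and are lost first.
            short = min(cell.edge_cycle, key=p.edge_length)
            res = t1_transition(p, short, force=True)
            if res.performed:
                t1_total += 1
                t1_total += descend_sweeps(p, max(2, sweeps // 2))
                area = p.cell_area(uv_cell)
        if (len(cell.edge_cycle) == 3 and area >= a_min
                and area > 0.9 * area_before):
            # a tiny triangle pinched at pressure balance (its edges are
            # protein-slack and tension-free); extrusion completes anyway
            jammed_triangle += 1
            if jammed_triangle >= 3 and area < 5 * a_min:
                final_area = area
                remove_cell(p, uv_cell)
                removed = True
                break
        else:
            jammed_triangle = 0
        if area < a_min:
            while len(cell.edge_cycle) > 3:
                short = min(cell.edge_cycle, key=p.edge_length)
                res = t1_transition(p, short, force=True)
                if not res.performed:
                    break
                t1_total += 1
                descend_sweeps(p, 1)
                if uv_cell not in p.cells:
                    break
            if uv_cell in p.cells and len(cell.edge_cycle) == 3:
                final_area = p.cell_area(uv_cell)
                remove_cell(p, uv_cell)
                removed = True
                break
    if not removed:
        raise StalledElimination(
            f"UV cell {uv_cell} not eliminated after {k} shrink intervals "
            f"(area {p.cell_area(uv_cell) if uv_cell in p.cells else 0:.4g}, "
            f"edges {len(cell.edge_cycle)})")

    ids = front.columns.get(column, [])
    if uv_cell in ids:
        ids.remove(uv_cell)
    if uv_cell in front.uv_cells.get(column, []):
        front.uv_cells[column].remove(uv_cell)

    # classify at the instant of removal, before further relaxation blurs
    # the topology around the vacated site
    outcome, ambiguous = classify_outcome(p, u, d)
    descend_sweeps(p, sweeps)
    event = EliminationEvent(uv_cell, column, k, t1_total, float(final_area),
                             outcome, ambiguous, (u, d))
    return p, event


def classify_outcome(packing: Packing, neighbor_up: int,
                     neighbor_down: int) -> tuple[str, bool]:
    """Classify an elimination by what now fills the vacated site.

    ``column_intact`` exactly when the two along-column cone neighbors
    share an edge (the column closes over the vacancy); ``column_broken``
    when a precursor cell shares edges with both, and also when anything
    else interrupts the column -- e.g. a cone of the adjacent column
    expanding into the vacancy (a column merge).  Events without a clean
    precursor bridge are flagged ambiguous.
    """
    p = packing
    u, d = neighbor_up, neighbor_down
    if u not in p.cells or d not in p.cells:
        return "column_broken", True
    direct = p.shared_interface_length(u, d)
    bridges = []                      # (interface, is_precursor) per filler
    for x in set(p.neighbors(u)) & set(p.neighbors(d)):
        if x in (u, d):
            continue
        bridges.append((p.shared_interface_length(u, x) +
                        p.shared_interface_length(d, x),
                        p.cells[x].type is CellType.PRECURSOR))
    if direct > 0:
        return "column_intact", False
    if any(b[1] for b in bridges):
        return "column_broken", False
    # no precursor bridge, but the neighbors are separated: the column is
    # interrupted by whatever fills the vacancy (usually a merge with the
    # adjacent column)
    return "column_broken", True


# --------------------------------------------------------------------------

@dataclass
class GrowthConfig:
    n_columns: int = 6                  # columns added by the front
    cells_per_column: int = 12
    n_established: int = 3
    n_buffer: int = 3
    mode: str = "mutant"                # wildtype | mutant
    relaxation: str = "fast"            # fast | slow
    settle_sweeps: int = 30             # sweeps after each column's events
    pre_elimination_sweeps: int = 10    # brief settling between conversion
                                        # and the start of UV elimination
    maturation_sweeps: int = 120        # extra sweeps once growth is done
    seed: int = 0
    params: Parameters = field(default_factory=Parameters)

    def __post_init__(self):
        if self.mode not in ("wildtype", "mutant"):
            raise ValueError("mode must be 'wildtype' or 'mutant'")
        if self.relaxation not in ("fast", "slow"):
            raise ValueError("relaxation must be 'fast' or 'slow'")
        if isinstance(self.params, dict):
            self.params = Parameters.from_dict(self.params)
        self.params.seed = self.seed

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "params"}
        d["params"] = self.params.to_dict()
        return d


@dataclass
class GrowthReport:
    config: dict
    n_events: int
    n_broken: int
    n_intact: int
    n_ambiguous: int
    break_fraction: float
    fragment_lengths: list[int]
    coordination_fractions: dict[int, float]
    column_straightness: float          # max centroid deviation / l
    events: list[dict]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def cohort_coordination(packing: Packing, front: FrontState) -> dict[int, int]:
    """Number of same-column cone neighbors still sharing an edge, per cone."""
    out = {}
    for col, ids in front.columns.items():
        live = [c for c in ids if c in packing.cells]
        for c in live:
            n = 0
            for o in packing.neighbors(c):
                if (o in packing.cells and packing.cells[o].column == col
                        and packing.cells[o].type.is_cone):
                    n += 1
            out[c] = n
    return out


def fragment_lengths(packing: Packing, front: FrontState) -> list[int]:
    """Lengths of maximal runs of consecutive cohort cells still adjacent."""
    lens = []
    for col, ids in front.columns.items():
        live = [c for c in ids if c in packing.cells]
        if not live:
            continue
        m = len(live)
        adj = [packing.shared_interface_length(live[i], live[(i + 1) % m]) > 0
               for i in range(m)]
        if all(adj) and m > 1:
            lens.append(m)
            continue
        # rotate to start at a break
        start = adj.index(False) + 1 if False in adj else 0
        run = 1
        for i in range(m - 1):
            j = (start + i) % m
            if adj[j]:
                run += 1
            else:
                lens.append(run)
                run = 1
        lens.append(run)
    return lens


def run_growth_experiment(config: GrowthConfig) -> tuple[Packing, FrontState,
                                                         GrowthReport]:
    """Grow the mosaic column by column, eliminating UV cones in mutant
    mode, and summarize the outcome statistics."""
    rng = np.random.default_rng(config.seed)
    if config.n_columns == 0:
        report = GrowthReport(config.to_dict(), 0, 0, 0, 0, float("nan"),
                              [], {}, 0.0, [])
        packing, front = initialize_growth(
            config.n_established, 0, config.cells_per_column,
            config.params, config.n_buffer, rng, settle=False)
        return packing, front, report

    packing, front = initialize_growth(
        config.n_established, config.n_columns, config.cells_per_column,
        config.params, config.n_buffer, rng)
    events: list[EliminationEvent] = []
    for _ in range(config.n_columns):
        packing, front = advance_front(packing, front, rng)
        descend_sweeps(packing, config.pre_elimination_sweeps
                       if config.mode == "mutant" else config.settle_sweeps)
        if config.mode == "mutant":
            uv_list = list(front.uv_cells.get(front.current_column, []))
            rng.shuffle(uv_list)
            for uv in uv_list:
                packing, ev = eliminate_uv(packing, front, uv,
                                           config.relaxation)
                events.append(ev)
        descend_sweeps(packing, config.settle_sweeps)
    descend_sweeps(packing, config.maturation_sweeps)

    n_broken = sum(e.outcome == "column_broken" for e in events)
    n_intact = sum(e.outcome == "column_intact" for e in events)
    n_amb = sum(e.ambiguous for e in events)
    coord = cohort_coordination(packing, front)
    hist: dict[int, float] = {}
    if coord:
        vals = np.array(list(coord.values()))
        for n in range(int(vals.max()) + 1):
            hist[n] = float(np.mean(vals == n))
    # straightness: centroid x-deviation from the column mean, in units of l
    devs = [0.0]
    for col, ids in front.columns.items():
        xs = [packing.cell_centroid(c)[0] for c in ids if c in packing.cells]
        if len(xs) > 1:
            devs.append(float(np.max(np.abs(np.array(xs) - np.mean(xs)))))
    report = GrowthReport(
        config.to_dict(), len(events), n_broken, n_intact, n_amb,
        (n_broken / len(events)) if events else float("nan"),
        fragment_lengths(packing, front), hist, max(devs),
        [e.to_dict() for e in events])
    return packing, front, report
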