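"""Initial packings: columnar cell lattices built from Voronoi diagrams.

Cell centers sit on a column/row grid (columns parallel to the retinal
margin, i.e. the y axis; alternate columns offset by half a row so the
relaxed packing is hexagonal).  The center grid is replicated across the
periodic y boundary and either mirrored (rigid walls) or replicated
(periodic) in x, and the Voronoi diagram of the extended point set is
stitched into a shared vertex/edge/cell complex.

The anisotropy parameter compresses the column spacing (perpendicular to
the margin) and dilates the row spacing so the mean cell area stays at
one model area unit.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Voronoi

from .geometry import Cell, CellType, Edge, Packing, Parameters, Vertex

__all__ = ["build_columnar_packing", "column_map"]

_HEX_RATIO = math.sqrt(3) / 2  # dx/dy of a hexagonal center grid


def _spacings(anisotropy: float) -> tuple[float, float]:
    # dx*dy = 1 (unit mean cell area), dx/dy = hex ratio * (1-anisotropy)^2
    r = _HEX_RATIO * (1.0 - anisotropy) ** 2
    dy = 1.0 / math.sqrt(r)
    return r * dy, dy


def build_columnar_packing(n_columns: int, n_rows: int,
                           params: Parameters | None = None,
                           periodic_x: bool = False,
                           jitter: float = 0.0,
                           rng: np.random.Generator | None = None) -> Packing:
    """Voronoi packing of ``n_columns`` x ``n_rows`` cells.

    Cells carry ``column``/``row`` attributes giving their grid position;
    all cells start as precursors with unit preferred area and no PCP
    protein.  ``jitter`` (in units of the reference length) perturbs the
    centers; the default regular grid relaxes to a hexagonal packing.
    """
    if n_columns < 1 or n_rows < 1:
        raise ValueError("need at least one column and one row")
    params = params or Parameters()
    dx, dy = _spacings(params.anisotropy)
    Lx, Ly = n_columns * dx, n_rows * dy

    idx = np.arange(n_columns * n_rows)
    ci, ri = idx // n_rows, idx % n_rows
    centers = np.empty((len(idx), 2))
    centers[:, 0] = (ci + 0.5) * dx
    centers[:, 1] = (ri + 0.5 * (ci % 2) + 0.25) * dy
    if jitter > 0:
        rng = rng or np.random.default_rng(params.seed)
        centers += rng.normal(scale=jitter, size=centers.shape)
        centers[:, 0] = np.clip(centers[:, 0], 0.05 * dx, Lx - 0.05 * dx)
    centers[:, 1] %= Ly

    # replicate across periodic/mirror boundaries
    tiles = []
    for sy in (0.0, -1.0, 1.0):
        shifted = centers + np.array([0.0, sy * Ly])
        tiles.append(shifted)
        if periodic_x:
            for sx in (-1.0, 1.0):
                tiles.append(shifted + np.array([sx * Lx, 0.0]))
        else:
            left = shifted * np.array([-1.0, 1.0])
            right = shifted * np.array([-1.0, 1.0]) + np.array([2 * Lx, 0.0])
            tiles.extend([left, right])
    allpts = np.vstack(tiles)
    vor = Voronoi(allpts)

    decimals = 7
    vkey_to_id: dict[tuple, int] = {}
    vertices: dict[int, Vertex] = {}
    edges: dict[int, Edge] = {}
    cells: dict[int, Cell] = {}
    ekey_to_id: dict[frozenset, int] = {}
    next_v, next_e = 0, 0

    def vertex_id(pt: np.ndarray) -> int:
        nonlocal next_v
        x, y = float(pt[0]), float(pt[1]) % Ly
        if abs(y - Ly) < 10 ** -decimals:
            y = 0.0
        wall = 0
        if not periodic_x:
            if abs(x) < 10 ** -decimals:
                x, wall = 0.0, -1
            elif abs(x - Lx) < 10 ** -decimals:
                x, wall = Lx, 1
        else:
            x %= Lx
            if abs(x - Lx) < 10 ** -decimals:
                x = 0.0
        key = (round(x, decimals), round(y, decimals))
        if key not in vkey_to_id:
            vkey_to_id[key] = next_v
            vertices[next_v] = Vertex(next_v, np.array([x, y]), wall)
            next_v += 1
        return vkey_to_id[key]

    cell_of_point = {}
    for k in range(len(centers)):
        cell_of_point[k] = k
    for k in range(len(centers)):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded Voronoi region in the core tile")
        poly = vor.vertices[region]
        # ensure counter-clockwise
        x, y = poly[:, 0], poly[:, 1]
        if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
            poly = poly[::-1]
        vids = [vertex_id(pt) for pt in poly]
        # drop consecutive duplicates from quantization
        vids = [v for i, v in enumerate(vids) if v != vids[(i + 1) % len(vids)]]
        ecycle = []
        for i in range(len(vids)):
            pair = frozenset((vids[i], vids[(i + 1) % len(vids)]))
            if len(pair) < 2:
                continue
            nonloc_e = ekey_to_id.get(pair)
            if nonloc_e is None:
                nonloc_e = next_e
                ekey_to_id[pair] = next_e
                edges[next_e] = Edge(next_e, tuple(sorted(pair)),
                                     (None, None), params.reference_tension)
                next_e += 1
            e = edges[nonloc_e]
            if e.cells[0] is None:
                e.cells = (k, e.cells[1])
            elif e.cells[1] is None and e.cells[0] != k:
                e.cells = (e.cells[0], k)
            ecycle.append(nonloc_e)
        cells[k] = Cell(k, ecycle, CellType.PRECURSOR, 1.0,
                        column=int(ci[k]), row=int(ri[k]))

    packing = Packing(vertices, edges, cells, (Lx, Ly), params,
                      periodic_x=periodic_x)
    packing.validate()
    return packing


def column_map(packing: Packing) -> dict[int, list[int]]:
    """Cells of each column, ordered by y position of the centroid."""
    cols: dict[int, list[int]] = {}
    for cid, cell in packing.cells.items():
        if cell.column is not None:
            cols.setdefault(cell.column, []).append(cid)
    for col, ids in cols.items():
        ids.sort(key=lambda c: packing.cells[c].row)
    return cols
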