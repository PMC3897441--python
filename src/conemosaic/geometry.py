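"""Two-dimensional vertex model of the retinal cone epithelium.

Cells are polygons whose vertices move to balance area elasticity, edge
line tension and perimeter contractility (the standard epithelial
vertex-model functional).  Each cell--cell interface additionally carries
planar-cell-polarity (PCP) protein *amounts*, one per flanking cell; the
local concentration (amount / edge length) lowers the effective line
tension, so protein-rich interfaces are mechanically favored.

Energy, at fixed protein amounts::

    E = sum_cells K/2 (A - A0)^2
      + sum_edges  Lambda * m * max(L - chi * (a_alpha + a_beta), 0)
      + sum_cells Gamma/2 P^2

where ``Lambda * m`` is the base tension times the (e.g. threefold UV)
multiplier and ``a`` are the protein amounts on the two sides.  The edge
term equals ``Lambda_eff * L`` with ``Lambda_eff = Lambda*m*max(0, 1 -
chi*(c_alpha + c_beta))`` and concentrations ``c = a/L``.

Forces treat the protein *concentration* as a frozen dynamical field:
the force an edge exerts on its vertices is ``Lambda_eff`` evaluated at
the current concentrations (protein-rich interfaces pull less), while
the amounts, not the concentrations, are what the PCP dynamics conserve.
Each relaxation step therefore does an exact line search on the
fixed-concentration energy surrogate and additionally requires the true
energy not to increase, so the recorded energy trace is non-increasing.

The box is periodic along y (parallel to the retinal margin).  Along x it
either has rigid walls (central retina at x=0, precursor reservoir at
x=Lx; wall vertices slide in y only) or is periodic as well, which is the
natural setting for ground-state tests.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "CellType",
    "Parameters",
    "Vertex",
    "Edge",
    "Cell",
    "Packing",
    "GeometryError",
    "RelaxationError",
    "RelaxResult",
    "T1Result",
    "energy",
    "relax",
    "t1_transition",
    "reallocate_pcp_t1",
    "remove_cell",
]


class GeometryError(ValueError):
    """Raised for inconsistent packings (non-simple polygons, bad ids...)."""


class RelaxationError(RuntimeError):
    """Raised when quasi-static relaxation diverges."""


class CellType(str, enum.Enum):
    PRECURSOR = "precursor"
    RED = "red"
    GREEN = "green"
    BLUE = "blue"
    UV = "uv"

    @property
    def is_cone(self) -> bool:
        return self is not CellType.PRECURSOR


#: the four spectral types, in within-column pentamer order g-r-b-r-g + uv
CONE_TYPES = (CellType.GREEN, CellType.RED, CellType.BLUE,
              CellType.RED, CellType.GREEN, CellType.UV)


@dataclass
class Parameters:
    """Model parameters, normalized by the reference tension and length.

    The reference length ``l`` is defined through ``l^2 = Lx*Ly/N`` so the
    mean cell area is one model area unit; all defaults are quoted in
    these units.
    """

    reference_tension: float = 0.12     # Lambda_ref, line tension per unit length
    area_stiffness: float = 1.0         # K
    contractility: float = 0.04         # Gamma
    pcp_tension_coupling: float = 0.5   # chi: concentration -> tension reduction
    pcp_mobility: float = 0.02          # intra-cell protein transfer rate
    pcp_total: float = 1.0              # per-cell protein budget P0 at initialization
    anisotropy: float = 0.15            # compression perpendicular to the margin
    t1_threshold: float = 0.17          # edge length triggering a T1
    sigma_blend: float = 0.5            # T1 protein reallocation blend weight
    shrink_factor: float = 0.4          # rho: preferred-area factor per interval
    shrink_interval: int = 5            # tau: relaxation sweeps between shrinks
    cutoff_area: float = 0.02           # A_min, in units of the mean preferred area
    uv_tension_factor: float = 3.0      # edge-tension multiplier of shrinking UV cells
    relax_tol: float = 1e-4             # max vertex force at convergence
    relax_step: float = 0.05            # initial gradient-descent step
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.shrink_factor < 1.0:
            raise ValueError("shrink_factor must lie in (0, 1)")
        for name in ("reference_tension", "area_stiffness", "t1_threshold",
                     "relax_tol", "uv_tension_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class Vertex:
    id: int
    pos: np.ndarray                      # shape (2,), model length units
    wall: int = 0                        # 0 free, -1 left wall (x=0), +1 right wall


@dataclass
class Edge:
    id: int
    vertices: tuple[int, int]
    cells: tuple[int | None, int | None] = (None, None)
    base_tension: float = 0.0
    tension_multiplier: float = 1.0
    pcp_amount: dict[int, float] = field(default_factory=dict)

    def other_cell(self, cid: int) -> int | None:
        a, b = self.cells
        return b if a == cid else a

    def other_vertex(self, vid: int) -> int:
        a, b = self.vertices
        return b if a == vid else a


@dataclass
class Cell:
    id: int
    edge_cycle: list[int]
    type: CellType = CellType.PRECURSOR
    preferred_area: float = 1.0
    tension_factor: float = 1.0          # 1, or 3 for UV cells being eliminated
    column: int | None = None            # cohort index (creation order), if any
    row: int | None = None


# --------------------------------------------------------------------------
# Packing
# --------------------------------------------------------------------------

class Packing:
    """A confluent 2-D cell packing with PCP amounts on edges."""

    def __init__(self, vertices: dict[int, Vertex], edges: dict[int, Edge],
                 cells: dict[int, Cell], box: tuple[float, float],
                 params: Parameters | None = None, periodic_x: bool = False):
        self.vertices = vertices
        self.edges = edges
        self.cells = cells
        self.Lx, self.Ly = float(box[0]), float(box[1])
        self.params = params or Parameters()
        self.periodic_x = periodic_x
        self._next_id = 1 + max(
            [0] + list(vertices) + list(edges) + list(cells))
        self._compiled: _Compiled | None = None
        for cid in list(cells):
            self._orient_ccw(cid)

    # -- ids ---------------------------------------------------------------
    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def invalidate(self) -> None:
        self._compiled = None

    # -- geometry helpers --------------------------------------------------
    def wrap_delta(self, d: np.ndarray) -> np.ndarray:
        """Minimal-image displacement."""
        d = np.asarray(d, dtype=float).copy()
        d[..., 1] -= self.Ly * np.round(d[..., 1] / self.Ly)
        if self.periodic_x:
            d[..., 0] -= self.Lx * np.round(d[..., 0] / self.Lx)
        return d

    def displacement(self, vid_from: int, vid_to: int) -> np.ndarray:
        return self.wrap_delta(self.vertices[vid_to].pos -
                               self.vertices[vid_from].pos)

    def edge_vector(self, eid: int) -> np.ndarray:
        v1, v2 = self.edges[eid].vertices
        return self.displacement(v1, v2)

    def edge_length(self, eid: int) -> float:
        return float(np.hypot(*self.edge_vector(eid)))

    def edges_at_vertex(self, vid: int) -> list[int]:
        return [e.id for e in self.edges.values() if vid in e.vertices]

    def cell_vertex_cycle(self, cid: int) -> list[int]:
        """Ordered vertex ids; vertex i joins edge_cycle[i-1] and [i]."""
        es = self.cells[cid].edge_cycle
        cyc = []
        for i in range(len(es)):
            prev = set(self.edges[es[i - 1]].vertices)
            cur = set(self.edges[es[i]].vertices)
            shared = prev & cur
            if not shared:
                raise GeometryError(
                    f"edge cycle of cell {cid} does not close")
            cyc.append(min(shared))
        return cyc

    def cell_polygon(self, cid: int) -> np.ndarray:
        """Unwrapped polygon coordinates, shape (n, 2)."""
        cyc = self.cell_vertex_cycle(cid)
        pts = [self.vertices[cyc[0]].pos.astype(float).copy()]
        for a, b in zip(cyc[:-1], cyc[1:]):
            pts.append(pts[-1] + self.displacement(a, b))
        return np.asarray(pts)

    def cell_area(self, cid: int) -> float:
        p = self.cell_polygon(cid)
        x, y = p[:, 0], p[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def cell_perimeter(self, cid: int) -> float:
        p = self.cell_polygon(cid)
        return float(np.sum(np.hypot(*((np.roll(p, -1, axis=0) - p).T))))

    def cell_centroid(self, cid: int) -> np.ndarray:
        p = self.cell_polygon(cid)
        x, y = p[:, 0], p[:, 1]
        cross = x * np.roll(y, -1) - np.roll(x, -1) * y
        a = 0.5 * cross.sum()
        if abs(a) < 1e-12:
            c = p.mean(axis=0)
        else:
            cx = np.sum((x + np.roll(x, -1)) * cross) / (6 * a)
            cy = np.sum((y + np.roll(y, -1)) * cross) / (6 * a)
            c = np.array([cx, cy])
        c[1] %= self.Ly
        if self.periodic_x:
            c[0] %= self.Lx
        return c

    def _orient_ccw(self, cid: int) -> None:
        if self.cell_area(cid) < 0:
            self.cells[cid].edge_cycle.reverse()

    def cell_pcp_total(self, cid: int) -> float:
        return sum(self.edges[e].pcp_amount.get(cid, 0.0)
                   for e in self.cells[cid].edge_cycle)

    def neighbors(self, cid: int) -> list[int]:
        out = []
        for e in self.cells[cid].edge_cycle:
            other = self.edges[e].other_cell(cid)
            if other is not None:
                out.append(other)
        return out

    def shared_edges(self, ca: int, cb: int) -> list[int]:
        return [e for e in self.cells[ca].edge_cycle
                if self.edges[e].other_cell(ca) == cb]

    def shared_interface_length(self, ca: int, cb: int) -> float:
        return sum(self.edge_length(e) for e in self.shared_edges(ca, cb))

    # -- invariants --------------------------------------------------------
    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells)

    def box_area(self) -> float:
        return self.Lx * self.Ly

    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges) + len(self.cells)

    def validate(self, atol_area: float = 1e-6) -> None:
        for cid in self.cells:
            a = self.cell_area(cid)
            if a < 0:
                raise GeometryError(f"cell {cid} has negative area")
            poly = self.cell_polygon(cid)
            if not np.all(np.isfinite(poly)):
                raise GeometryError(f"cell {cid} has non-finite vertices")
        rel = abs(self.total_area() - self.box_area()) / self.box_area()
        if rel > atol_area:
            raise GeometryError(
                f"packing is not confluent: area mismatch {rel:.2e}")
        for e in self.edges.values():
            for cid in e.pcp_amount:
                if cid not in e.cells:
                    raise GeometryError(
                        f"edge {e.id} carries protein for non-flanking cell {cid}")

    # -- compiled numerical view --------------------------------------------
    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._refresh_multipliers()
            self._compiled = _Compiled(self)
        return self._compiled

    def _refresh_multipliers(self) -> None:
        for e in self.edges.values():
            f = 1.0
            for cid in e.cells:
                if cid is not None:
                    f = max(f, self.cells[cid].tension_factor)
            e.tension_multiplier = f

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "box": [self.Lx, self.Ly],
            "periodic_x": self.periodic_x,
            "params": self.params.to_dict(),
            "vertices": [
                {"id": v.id, "pos": [float(v.pos[0]), float(v.pos[1])],
                 "wall": v.wall}
                for v in self.vertices.values()],
            "edges": [
                {"id": e.id, "vertices": list(e.vertices),
                 "cells": [c for c in e.cells],
                 "base_tension": e.base_tension,
                 "tension_multiplier": e.tension_multiplier,
                 "pcp_amount": {str(k): v for k, v in e.pcp_amount.items()}}
                for e in self.edges.values()],
            "cells": [
                {"id": c.id, "edge_cycle": list(c.edge_cycle),
                 "type": c.type.value, "preferred_area": c.preferred_area,
                 "tension_factor": c.tension_factor,
                 "column": c.column, "row": c.row}
                for c in self.cells.values()],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "Packing":
        vertices = {v["id"]: Vertex(v["id"], np.asarray(v["pos"], float),
                                    v.get("wall", 0))
                    for v in d["vertices"]}
        edges = {}
        for e in d["edges"]:
            edges[e["id"]] = Edge(
                e["id"], tuple(e["vertices"]),
                tuple(e["cells"]), e["base_tension"],
                e.get("tension_multiplier", 1.0),
                {int(k): v for k, v in e.get("pcp_amount", {}).items()})
        cells = {c["id"]: Cell(c["id"], list(c["edge_cycle"]),
                               CellType(c["type"]), c["preferred_area"],
                               c.get("tension_factor", 1.0),
                               c.get("column"), c.get("row"))
                 for c in d["cells"]}
        return cls(vertices, edges, cells, d["box"],
                   Parameters.from_dict(d.get("params", {})),
                   d.get("periodic_x", False))

    @classmethod
    def from_json(cls, path) -> "Packing":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# Compiled arrays: fast energy / force / PCP evaluation
# --------------------------------------------------------------------------

class _Compiled:
    """Flat-array view of a packing; topology-invariant hot loops run here."""

    def __init__(self, p: Packing):
        self.packing = p
        self.Lx, self.Ly = p.Lx, p.Ly
        self.periodic_x = p.periodic_x
        self.chi = p.params.pcp_tension_coupling

        self.vids = sorted(p.vertices)
        vrow = {v: i for i, v in enumerate(self.vids)}
        self.pos = np.array([p.vertices[v].pos for v in self.vids], float)
        self.wall = np.array([p.vertices[v].wall != 0 for v in self.vids])

        self.eids = sorted(p.edges)
        E = len(self.eids)
        self.ev = np.empty((E, 2), int)
        self.lam = np.empty(E)
        self.amt = np.zeros((E, 2))                # per-side protein amounts
        self.ecell = np.full((E, 2), -1, int)      # cell rows per side
        crow = {c: i for i, c in enumerate(sorted(p.cells))}
        for k, eid in enumerate(self.eids):
            e = p.edges[eid]
            self.ev[k] = (vrow[e.vertices[0]], vrow[e.vertices[1]])
            self.lam[k] = e.base_tension * e.tension_multiplier
            for s, cid in enumerate(e.cells):
                if cid is not None:
                    self.ecell[k, s] = crow[cid]
                    self.amt[k, s] = e.pcp_amount.get(cid, 0.0)

        self.cids = sorted(p.cells)
        C = len(self.cids)
        cycles = [p.cell_vertex_cycle(c) for c in self.cids]
        self.ncv = np.array([len(cy) for cy in cycles])
        Lmax = int(self.ncv.max()) if C else 3
        self.cv = np.empty((C, Lmax + 1), int)
        for i, cy in enumerate(cycles):
            rows = [vrow[v] for v in cy]
            rows = rows + [rows[0]] * (Lmax + 1 - len(rows))
            self.cv[i] = rows
        self.K = np.array([p.params.area_stiffness for _ in self.cids])
        self.A0 = np.array([p.cells[c].preferred_area for c in self.cids])
        self.G = np.array([p.params.contractility for _ in self.cids])

        # per-cell edge incidence (for PCP dynamics): edge row + side column
        erow = {e: i for i, e in enumerate(self.eids)}
        self.nce = np.array([len(p.cells[c].edge_cycle) for c in self.cids])
        Emax = int(self.nce.max()) if C else 3
        self.ce = np.full((C, Emax), -1, int)
        self.ce_side = np.zeros((C, Emax), int)
        for i, cid in enumerate(self.cids):
            for j, eid in enumerate(p.cells[cid].edge_cycle):
                self.ce[i, j] = erow[eid]
                self.ce_side[i, j] = 0 if p.edges[eid].cells[0] == cid else 1

    # -- primitives ---------------------------------------------------------
    def _wrap(self, d: np.ndarray) -> np.ndarray:
        d[..., 1] -= self.Ly * np.round(d[..., 1] / self.Ly)
        if self.periodic_x:
            d[..., 0] -= self.Lx * np.round(d[..., 0] / self.Lx)
        return d

    def _cell_geometry(self, pos: np.ndarray):
        P0 = pos[self.cv]                            # (C, L+1, 2)
        D = self._wrap(np.diff(P0, axis=1))          # (C, L, 2) segment vectors
        U = np.concatenate([P0[:, :1], P0[:, :1] + np.cumsum(D, axis=1)],
                           axis=1)                   # unwrapped coords
        seglen = np.hypot(D[..., 0], D[..., 1])
        area = 0.5 * np.sum(U[:, :-1, 0] * U[:, 1:, 1] -
                            U[:, 1:, 0] * U[:, :-1, 1], axis=1)
        perim = seglen.sum(axis=1)
        return D, U, seglen, area, perim

    def edge_lengths(self, pos: np.ndarray | None = None) -> np.ndarray:
        pos = self.pos if pos is None else pos
        d = self._wrap(pos[self.ev[:, 1]] - pos[self.ev[:, 0]])
        return np.hypot(d[:, 0], d[:, 1])

    def effective_tension(self, pos: np.ndarray | None = None) -> np.ndarray:
        """Lambda_eff per edge at the current protein concentrations."""
        L = self.edge_lengths(pos)
        csum = self.amt.sum(axis=1) / np.maximum(L, 1e-30)
        return self.lam * np.clip(1.0 - self.chi * csum, 0.0, None)

    def energy(self, pos: np.ndarray | None = None,
               tension: np.ndarray | None = None) -> float:
        """Total energy; with ``tension`` given, the fixed-concentration
        surrogate sum(T*L), otherwise the true functional Lambda_eff*L =
        lam*max(L - chi*a_sum, 0)."""
        pos = self.pos if pos is None else pos
        _, _, _, area, perim = self._cell_geometry(pos)
        L = self.edge_lengths(pos)
        if tension is None:
            slack = self.chi * self.amt.sum(axis=1)
            e_edge = np.sum(self.lam * np.maximum(L - slack, 0.0))
        else:
            e_edge = np.sum(tension * L)
        e_area = 0.5 * np.sum(self.K * (area - self.A0) ** 2)
        e_perim = 0.5 * np.sum(self.G * perim ** 2)
        return float(e_edge + e_area + e_perim)

    def forces(self, pos: np.ndarray | None = None,
               tension: np.ndarray | None = None) -> np.ndarray:
        pos = self.pos if pos is None else pos
        F = np.zeros_like(pos)

        # edge line tension at frozen concentrations
        d = self._wrap(pos[self.ev[:, 1]] - pos[self.ev[:, 0]])
        L = np.hypot(d[:, 0], d[:, 1])
        if tension is None:
            csum = self.amt.sum(axis=1) / np.maximum(L, 1e-30)
            T = self.lam * np.clip(1.0 - self.chi * csum, 0.0, None)
        else:
            T = tension
        safe = np.maximum(L, 1e-30)
        u = d / safe[:, None]
        np.add.at(F, self.ev[:, 0], T[:, None] * u)
        np.add.at(F, self.ev[:, 1], -T[:, None] * u)

        # cell terms
        D, U, seglen, area, perim = self._cell_geometry(pos)
        ka = self.K * (area - self.A0)               # dE/dA
        gp = self.G * perim                          # dE/dP
        uhat = D / np.maximum(seglen, 1e-30)[..., None]

        # area gradient: segment (k, k+1): d(cross)/d endpoints
        gxk = U[:, 1:, 1] * 0.5
        gyk = -U[:, 1:, 0] * 0.5
        gxk1 = -U[:, :-1, 1] * 0.5
        gyk1 = U[:, :-1, 0] * 0.5
        # force = -(dE/dA) * dA/dr - (dE/dP) * dP/dr
        fk = np.empty_like(D)
        fk[..., 0] = -ka[:, None] * gxk
        fk[..., 1] = -ka[:, None] * gyk
        fk += gp[:, None, None] * uhat               # dP/d r_k = -uhat
        fk1 = np.empty_like(D)
        fk1[..., 0] = -ka[:, None] * gxk1
        fk1[..., 1] = -ka[:, None] * gyk1
        fk1 -= gp[:, None, None] * uhat
        rows_k = self.cv[:, :-1].ravel()
        rows_k1 = self.cv[:, 1:].ravel()
        np.add.at(F, rows_k, fk.reshape(-1, 2))
        np.add.at(F, rows_k1, fk1.reshape(-1, 2))

        if not self.periodic_x:
            F[self.wall, 0] = 0.0
        return F

    def max_force(self, pos: np.ndarray | None = None) -> float:
        F = self.forces(pos)
        return float(np.sqrt((F ** 2).sum(axis=1)).max()) if len(F) else 0.0

    def canonicalize(self, pos: np.ndarray) -> np.ndarray:
        pos = pos.copy()
        pos[:, 1] %= self.Ly
        if self.periodic_x:
            pos[:, 0] %= self.Lx
        else:
            np.clip(pos[:, 0], 0.0, self.Lx, out=pos[:, 0])
        return pos

    # -- PCP dynamics (intra-cell redistribution toward shorter edges) -----
    def pcp_step(self, dt: float, mobility: float) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        L = self.edge_lengths()
        valid = self.ce >= 0
        Lce = np.where(valid, L[np.maximum(self.ce, 0)], 0.0)
        n = np.maximum(self.nce, 1)
        Lmean = Lce.sum(axis=1) / n
        a = np.where(valid,
                     self.amt[np.maximum(self.ce, 0), self.ce_side], 0.0)
        total = a.sum(axis=1)
        perim = np.maximum(Lce.sum(axis=1), 1e-30)
        scale = total / perim
        rate = -mobility * (Lce - Lmean[:, None]) * scale[:, None]
        # flux-limited Euler step: donors cannot give more than they hold;
        # recipients are scaled down to match the realized outflow so each
        # cell's total is conserved exactly and amounts stay nonnegative
        flux = rate * dt * valid
        out = np.maximum(flux * (flux < 0), -a)          # realized outflow
        inflow_want = flux * (flux > 0)
        sum_out = -out.sum(axis=1)
        sum_in = inflow_want.sum(axis=1)
        fac = np.where(sum_in > 0, sum_out / np.maximum(sum_in, 1e-30), 0.0)
        trial = a + out + inflow_want * fac[:, None]
        if not np.all(np.isfinite(trial)):
            raise RelaxationError("PCP update produced non-finite amounts")
        trial = np.maximum(trial, 0.0)
        self.amt[:] = 0.0
        np.add.at(self.amt, (self.ce[valid], self.ce_side[valid]),
                  trial[valid])

    # -- write back to the object layer -------------------------------------
    def sync_back(self) -> None:
        p = self.packing
        pos = self.canonicalize(self.pos)
        for row, vid in enumerate(self.vids):
            p.vertices[vid].pos = pos[row].copy()
        for k, eid in enumerate(self.eids):
            e = p.edges[eid]
            e.pcp_amount = {
                cid: float(self.amt[k, s])
                for s, cid in enumerate(e.cells)
                if cid is not None and self.amt[k, s] != 0.0}


# --------------------------------------------------------------------------
# Relaxation
# --------------------------------------------------------------------------

@dataclass
class RelaxResult:
    converged: bool
    steps: int
    max_force: float
    energy_trace: list[float]


def energy(packing: Packing) -> float:
    """Total mechanical energy of the packing (see module docstring)."""
    for cid in packing.cells:
        poly = packing.cell_polygon(cid)
        if _self_intersects(poly):
            raise GeometryError(f"cell {cid} polygon is not simple")
    return packing.compiled().energy()


def _self_intersects(poly: np.ndarray) -> bool:
    n = len(poly)
    if n < 4:
        return False
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _seg_cross(*segs[i], *segs[j]):
                return True
    return False


def _seg_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def relax(packing: Packing, tol: float | None = None,
          max_steps: int = 5000) -> RelaxResult:
    """Quasi-static force balance by damped gradient descent.

    Backtracking line search guarantees the energy is non-increasing
    across accepted steps; terminates when the largest vertex force drops
    below ``tol`` or after ``max_steps`` steps.
    """
    if tol is None:
        tol = packing.params.relax_tol
    if tol <= 0:
        raise ValueError("tol must be positive")
    comp = packing.compiled()
    res = _relax_compiled(comp, tol, max_steps, packing.params.relax_step)
    comp.sync_back()
    return res


def _relax_compiled(comp: _Compiled, tol: float, max_steps: int,
                    step0: float) -> RelaxResult:
    pos = comp.pos
    E = comp.energy(pos)
    trace = [E]
    alpha = step0
    fmax = comp.max_force(pos)
    steps = 0
    for steps in range(1, max_steps + 1):
        T = comp.effective_tension(pos)
        F = comp.forces(pos, tension=T)
        fmax = float(np.sqrt((F ** 2).sum(axis=1)).max()) if len(F) else 0.0
        if fmax <= tol:
            steps -= 1
            break
        Es = comp.energy(pos, tension=T)
        g2 = float((F ** 2).sum())
        accepted = False
        for _ in range(60):
            trial = pos + alpha * F
            # Armijo decrease on the frozen-concentration surrogate, and
            # no increase of the true functional
            if (comp.energy(trial, tension=T) <= Es - 1e-4 * alpha * g2
                    and (Et := comp.energy(trial)) <= E):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            raise RelaxationError(
                f"relaxation stalled at step {steps}: energy {E:.6g}, "
                f"max force {fmax:.3g}, step size underflow")
        pos, E = trial, Et
        trace.append(E)
        alpha = min(alpha * 1.5, 1.0)
    comp.pos = pos
    return RelaxResult(fmax <= tol, steps, fmax, trace)


def descend_sweeps(packing: Packing, sweeps: int, dt: float = 1.0,
                   t1_refractory: set[int] | None = None) -> int:
    """Run ``sweeps`` single descent steps interleaved with PCP updates and
    T1 scans; the unit of simulated relaxation used by the growth protocol.

    Returns the number of T1 transitions performed.
    """
    n_t1 = 0
    refractory: set[int] = set()
    for _ in range(sweeps):
        comp = packing.compiled()
        try:
            _relax_compiled(comp, tol=packing.params.relax_tol, max_steps=1,
                            step0=packing.params.relax_step)
        except RelaxationError:
            pass  # pinned at a tension kink; PCP/T1 may unstick it
        comp.pcp_step(dt, packing.params.pcp_mobility)
        comp.sync_back()
        flipped = scan_t1(packing, skip=refractory)
        refractory = set(flipped)
        n_t1 += len(flipped)
    return n_t1


def scan_t1(packing: Packing, skip: Iterable[int] = ()) -> list[int]:
    """Attempt a T1 on every edge shorter than the threshold."""
    thr = packing.params.t1_threshold
    skip = set(skip)
    flipped = []
    short = [eid for eid in list(packing.edges)
             if eid not in skip and packing.edge_length(eid) <= thr]
    for eid in short:
        if eid not in packing.edges:
            continue
        res = t1_transition(packing, eid)
        if res.performed:
            flipped.append(eid)
    return flipped


# --------------------------------------------------------------------------
# T1 topological transitions
# --------------------------------------------------------------------------

@dataclass
class T1Result:
    performed: bool
    edge_id: int
    reason: str = ""
    new_cells: tuple[int, int] | None = None


def _marginal_tension(packing: Packing, eid: int) -> float:
    """Effective tension Lambda_eff of an edge at current concentrations."""
    e = packing.edges[eid]
    chi = packing.params.pcp_tension_coupling
    L = packing.edge_length(eid)
    csum = sum(e.pcp_amount.values()) / max(L, 1e-30)
    lam = e.base_tension * e.tension_multiplier
    return lam * max(1.0 - chi * csum, 0.0)


def t1_transition(packing: Packing, edge_id: int,
                  force: bool = False) -> T1Result:
    """Collapse a short edge to a 4-fold vertex and resolve it.

    Both candidate topologies (the original pairing of the four outer
    edges and the neighbor-exchanged one) are scored by the net opening
    force the paired edges exert on the prospective new vertices; the
    larger positive score wins and the new edge opens parallel to the
    difference of the two pair forces, at length ``t1_threshold * 1.01``.
    ``force=True`` performs the neighbor exchange even when the opening
    criterion would reject it (used by the elimination protocol).
    """
    p = packing
    if edge_id not in p.edges:
        raise GeometryError(f"no edge {edge_id}")
    e0 = p.edges[edge_id]
    if not force and p.edge_length(edge_id) > p.params.t1_threshold * 1.0001:
        return T1Result(False, edge_id, "edge above threshold")
    W, E_ = e0.cells
    if W is None or E_ is None:
        return T1Result(False, edge_id, "boundary edge")
    a, b = e0.vertices
    ea = [i for i in p.edges_at_vertex(a) if i != edge_id]
    eb = [i for i in p.edges_at_vertex(b) if i != edge_id]
    if len(ea) != 2 or len(eb) != 2:
        return T1Result(False, edge_id, "endpoint not 3-fold")
    if len(p.cells[W].edge_cycle) <= 3 or len(p.cells[E_].edge_cycle) <= 3:
        return T1Result(False, edge_id, "side cell is a triangle")

    def side_edge(cands, cid):
        hits = [i for i in cands if cid in p.edges[i].cells]
        return hits[0] if len(hits) == 1 else None

    ea1, ea2 = side_edge(ea, W), side_edge(ea, E_)   # at a: W-side, E-side
    eb1, eb2 = side_edge(eb, W), side_edge(eb, E_)   # at b
    if None in (ea1, ea2, eb1, eb2):
        return T1Result(False, edge_id, "ambiguous outer edges")
    N = p.edges[ea1].other_cell(W)
    if N != p.edges[ea2].other_cell(E_):
        return T1Result(False, edge_id, "inconsistent apex cell at a")
    S = p.edges[eb1].other_cell(W)
    if S != p.edges[eb2].other_cell(E_):
        return T1Result(False, edge_id, "inconsistent apex cell at b")
    if N is None or S is None or N == S or N in (W, E_) or S in (W, E_):
        return T1Result(False, edge_id, "degenerate neighborhood")

    # midpoint of the collapsing edge (4-fold vertex position)
    pa = p.vertices[a].pos
    m = pa + 0.5 * p.displacement(a, b)

    def unit_from_m(eid_outer, vid_near):
        far = p.edges[eid_outer].other_vertex(vid_near)
        d = p.wrap_delta(p.vertices[far].pos - m)
        n = np.hypot(*d)
        return d / n if n > 0 else np.zeros(2)

    T = {i: _marginal_tension(p, i) for i in (ea1, ea2, eb1, eb2)}
    u = {ea1: unit_from_m(ea1, a), ea2: unit_from_m(ea2, a),
         eb1: unit_from_m(eb1, b), eb2: unit_from_m(eb2, b)}

    lam_ref = p.params.reference_tension
    mult_orig = e0.tension_multiplier
    mult_flip = max(p.cells[N].tension_factor, p.cells[S].tension_factor)

    # original pairing: {ea1, ea2} at one vertex, {eb1, eb2} at the other
    F_a = T[ea1] * u[ea1] + T[ea2] * u[ea2]
    F_b = T[eb1] * u[eb1] + T[eb2] * u[eb2]
    d_orig = F_a - F_b
    open_orig = float(np.hypot(*d_orig)) - 2 * e0.base_tension * mult_orig
    # flipped pairing: {ea1, eb1} (cell-W side) and {ea2, eb2} (cell-E side)
    F_w = T[ea1] * u[ea1] + T[eb1] * u[eb1]
    F_e = T[ea2] * u[ea2] + T[eb2] * u[eb2]
    d_flip = F_w - F_e
    open_flip = float(np.hypot(*d_flip)) - 2 * lam_ref * mult_flip

    Lnew = p.params.t1_threshold * 1.01

    if not force and open_orig <= 0 and open_flip <= 0:
        return T1Result(False, edge_id, "no positive opening force")

    if not force and open_orig >= open_flip:
        # keep the original topology, re-open along the favored direction
        n = np.hypot(*d_orig)
        dhat = d_orig / n if n > 0 else _perp_unit(p, a, b)
        p.vertices[a].pos = _canon(p, m + 0.5 * Lnew * dhat)
        p.vertices[b].pos = _canon(p, m - 0.5 * Lnew * dhat)
        _pin_walls(p, a, b)
        p.invalidate()
        return T1Result(False, edge_id, "original topology favored")

    # ---- perform the neighbor exchange -----------------------------------
    totals_before = {cid: p.cell_pcp_total(cid) for cid in (W, E_, N, S)}
    # flanking concentrations of the gaining cells, at the pre-flip state
    conc_before = {}
    for cid, (f1, f2) in ((N, (ea1, ea2)), (S, (eb1, eb2))):
        for f in (f1, f2):
            Lf = p.edge_length(f)
            conc_before[(cid, f)] = (
                p.edges[f].pcp_amount.get(cid, 0.0) / Lf if Lf > 0 else 0.0,
                Lf)

    n = np.hypot(*d_flip)
    dhat = d_flip / n if n > 0 else _perp_unit(p, a, b)
    # vertex a keeps the W-side pair {ea1, eb1}; b keeps {ea2, eb2}
    p.vertices[a].pos = _canon(p, m + 0.5 * Lnew * dhat)
    p.vertices[b].pos = _canon(p, m - 0.5 * Lnew * dhat)
    _pin_walls(p, a, b)

    # rewire endpoints: eb1 moves b->a, ea2 moves a->b
    _swap_endpoint(p.edges[eb1], b, a)
    _swap_endpoint(p.edges[ea2], a, b)

    # cells: W and E lose e0; N and S gain it
    p.cells[W].edge_cycle.remove(edge_id)
    p.cells[E_].edge_cycle.remove(edge_id)
    _insert_between(p.cells[N].edge_cycle, ea1, ea2, edge_id)
    _insert_between(p.cells[S].edge_cycle, eb1, eb2, edge_id)
    e0.cells = (N, S)

    reallocate_pcp_t1(p, edge_id, lost_cells=(W, E_),
                      gained={N: (ea1, ea2), S: (eb1, eb2)},
                      totals_before=totals_before,
                      conc_before=conc_before)

    for cid in (W, E_, N, S):
        p._orient_ccw(cid)
    p.invalidate()
    return T1Result(True, edge_id, "neighbor exchange", (N, S))


def _canon(p: Packing, pos: np.ndarray) -> np.ndarray:
    pos = pos.copy()
    pos[1] %= p.Ly
    if p.periodic_x:
        pos[0] %= p.Lx
    else:
        pos[0] = min(max(pos[0], 0.0), p.Lx)
    return pos


def _pin_walls(p: Packing, *vids: int) -> None:
    for vid in vids:
        v = p.vertices[vid]
        if v.wall == -1:
            v.pos[0] = 0.0
        elif v.wall == 1:
            v.pos[0] = p.Lx


def _perp_unit(p: Packing, a: int, b: int) -> np.ndarray:
    d = p.displacement(a, b)
    n = np.hypot(*d)
    if n == 0:
        return np.array([1.0, 0.0])
    return np.array([-d[1], d[0]]) / n


def _swap_endpoint(e: Edge, old: int, new: int) -> None:
    v1, v2 = e.vertices
    e.vertices = (new if v1 == old else v1, new if v2 == old else v2)


def _insert_between(cycle: list[int], e1: int, e2: int, new: int) -> None:
    i1, i2 = cycle.index(e1), cycle.index(e2)
    n = len(cycle)
    if (i1 + 1) % n == i2:
        cycle.insert(i2, new)
    elif (i2 + 1) % n == i1:
        cycle.insert(i1, new)
    else:
        raise GeometryError("edges not adjacent in cell cycle")


def reallocate_pcp_t1(packing: Packing, new_edge: int,
                      lost_cells: tuple[int, int],
                      gained: dict[int, tuple[int, int]],
                      totals_before: dict[int, float],
                      conc_before: dict | None = None) -> None:
    """Allot PCP protein after a T1, conserving every cell's total.

    For each cell now flanking the new edge, the new-edge concentration is
    a blend of that cell's concentrations on its two edges meeting the new
    vertices (evaluated at the pre-transition state): ``(1-sigma)`` times
    the length-weighted mean plus ``sigma`` times the plain mean.  Amounts
    on the cell's surviving edges are then rescaled so its total is
    conserved exactly; the two cells that lost the edge redistribute the
    lost amount over their remaining edges.
    """
    p = packing
    sigma = p.params.sigma_blend
    e_new = p.edges[new_edge]
    Lnew = p.edge_length(new_edge)

    for cid, (f1, f2) in gained.items():
        if conc_before is not None:
            c1, L1 = conc_before[(cid, f1)]
            c2, L2 = conc_before[(cid, f2)]
        else:
            L1, L2 = p.edge_length(f1), p.edge_length(f2)
            c1 = p.edges[f1].pcp_amount.get(cid, 0.0) / max(L1, 1e-30)
            c2 = p.edges[f2].pcp_amount.get(cid, 0.0) / max(L2, 1e-30)
        if L1 <= 0 or L2 <= 0:
            raise GeometryError("zero-length edge flanking a new T1 edge")
        c_lw = (L1 * c1 + L2 * c2) / (L1 + L2)
        c_new = (1.0 - sigma) * c_lw + sigma * 0.5 * (c1 + c2)
        a_new = min(c_new * Lnew, totals_before[cid])
        others = [i for i in p.cells[cid].edge_cycle if i != new_edge]
        t_others = sum(p.edges[i].pcp_amount.get(cid, 0.0) for i in others)
        target_others = totals_before[cid] - a_new
        if t_others > 0:
            fac = target_others / t_others
            for i in others:
                if cid in p.edges[i].pcp_amount:
                    p.edges[i].pcp_amount[cid] *= fac
        elif target_others > 0:
            lens = np.array([p.edge_length(i) for i in others])
            for i, w in zip(others, lens / lens.sum()):
                p.edges[i].pcp_amount[cid] = target_others * w
        e_new.pcp_amount[cid] = a_new

    for cid in lost_cells:
        e_new.pcp_amount.pop(cid, None)
        total = totals_before[cid]
        es = p.cells[cid].edge_cycle
        t_now = sum(p.edges[i].pcp_amount.get(cid, 0.0) for i in es)
        if t_now > 0:
            fac = total / t_now
            for i in es:
                if cid in p.edges[i].pcp_amount:
                    p.edges[i].pcp_amount[cid] *= fac
        elif total > 0:
            lens = np.array([p.edge_length(i) for i in es])
            for i, w in zip(es, lens / lens.sum()):
                p.edges[i].pcp_amount[cid] = total * w


# --------------------------------------------------------------------------
# Cell removal (extrusion endpoint)
# --------------------------------------------------------------------------

def remove_cell(packing: Packing, cid: int) -> int:
    """Delete a (three-sided) cell, collapsing it to a single vertex.

    The cell's own protein is discarded; each neighbor's amount on the
    shared interface is redistributed over the neighbor's remaining edges
    so neighbor totals are conserved.  Returns the id of the new vertex.
    """
    p = packing
    cell = p.cells[cid]
    if len(cell.edge_cycle) != 3:
        raise GeometryError(
            f"can only remove three-sided cells (cell {cid} has "
            f"{len(cell.edge_cycle)} edges)")
    cyc = p.cell_vertex_cycle(cid)
    centroid = p.cell_centroid(cid)
    boundary = list(cell.edge_cycle)
    neighbor_of = {e: p.edges[e].other_cell(cid) for e in boundary}

    v_new = p.new_id()
    wall = 0
    for vid in cyc:
        if p.vertices[vid].wall:
            wall = p.vertices[vid].wall
    pos = centroid.copy()
    if wall == -1:
        pos[0] = 0.0
    elif wall == 1:
        pos[0] = p.Lx
    p.vertices[v_new] = Vertex(v_new, pos, wall)

    # neighbors lose their shared edge; conserve their protein totals
    for e in boundary:
        nb = neighbor_of[e]
        if nb is not None:
            lost = p.edges[e].pcp_amount.get(nb, 0.0)
            cyc_nb = p.cells[nb].edge_cycle
            cyc_nb.remove(e)
            if lost > 0:
                others = cyc_nb
                t_now = sum(p.edges[i].pcp_amount.get(nb, 0.0)
                            for i in others)
                if t_now > 0:
                    fac = (t_now + lost) / t_now
                    for i in others:
                        if nb in p.edges[i].pcp_amount:
                            p.edges[i].pcp_amount[nb] *= fac
                else:
                    lens = np.array([p.edge_length(i) for i in others])
                    for i, w in zip(others, lens / lens.sum()):
                        p.edges[i].pcp_amount[nb] = lost * w
        del p.edges[e]

    # outer edges reconnect to the new vertex
    for vid in cyc:
        for e in p.edges_at_vertex(vid):
            _swap_endpoint(p.edges[e], vid, v_new)
        del p.vertices[vid]

    del p.cells[cid]
    for nb in set(neighbor_of.values()):
        if nb is not None:
            p._orient_ccw(nb)
    p.invalidate()
    return v_new
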