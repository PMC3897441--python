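"""Planar-cell-polarity protein dynamics on cell edges.

Between mechanical events, protein redistributes *within* each cell from
longer toward shorter edges (the adhesion complexes accumulate on short,
compressed interfaces), at a rate linear in the deviation of the edge
length from the cell's mean edge length.  The per-cell total is conserved
exactly; there is no intercellular transport and no cytoplasmic pool.

Because the law is intracellular, a cell's polarity direction is defined
only up to sign (protein piles symmetrically onto opposite short edges),
so the tissue order parameter is the *nematic* mean resultant of the
per-cell polarity axes: Phi = |< exp(2 i theta) >| over cone cells,
which is 1 for a perfectly aligned axis field and 0 for random axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Packing

__all__ = [
    "PolarityState",
    "update_pcp",
    "polarity_vector",
    "tissue_order",
    "polarity_state",
    "initialize_random_pcp",
    "initialize_polarized_pcp",
    "polarity_overlay_png",
]


@dataclass
class PolarityState:
    """Per-cell polarity vectors and the tissue nematic order parameter."""

    cell_ids: list[int]
    vectors: np.ndarray          # (n, 2), amount * length units
    magnitudes: np.ndarray       # |p| per cell
    order_parameter: float       # Phi in [0, 1]
    mean_axis: np.ndarray        # unit vector of the mean polarity axis


def update_pcp(packing: Packing, dt: float) -> Packing:
    """Advance the intracellular redistribution law by one step of ``dt``.

    Amounts flow from edges longer than the cell mean to shorter ones with
    rate ``mobility * (L_e - <L>) * total/perimeter``; the step is halved
    on negativity and per-cell totals are conserved to machine precision.
    """
    comp = packing.compiled()
    comp.pcp_step(dt, packing.params.pcp_mobility)
    comp.sync_back()
    return packing


def polarity_vector(packing: Packing, cid: int) -> np.ndarray:
    """p = sum_e a_e * n_e with n_e the outward unit normal of edge e."""
    cell = packing.cells[cid]
    if len(cell.edge_cycle) < 3:
        raise ValueError(f"cell {cid} has fewer than 3 edges")
    cyc = packing.cell_vertex_cycle(cid)
    p = np.zeros(2)
    n = len(cyc)
    for i, eid in enumerate(cell.edge_cycle):
        t = packing.displacement(cyc[i], cyc[(i + 1) % n])
        norm = np.hypot(*t)
        if norm == 0:
            continue
        outward = np.array([t[1], -t[0]]) / norm   # CCW cycle -> right normal
        p += packing.edges[eid].pcp_amount.get(cid, 0.0) * outward
    return p


def tissue_order(packing: Packing, cell_ids=None) -> tuple[float, np.ndarray]:
    """Nematic order parameter Phi and mean axis over the given cells
    (default: all cone cells with nonzero polarity)."""
    if cell_ids is None:
        cell_ids = [c for c in packing.cells
                    if packing.cells[c].type.is_cone]
    zs = []
    for cid in cell_ids:
        p = polarity_vector(packing, cid)
        m = np.hypot(*p)
        if m > 1e-12:
            th = np.arctan2(p[1], p[0])
            zs.append(np.exp(2j * th))
    if not zs:
        return 0.0, np.array([1.0, 0.0])
    z = np.mean(zs)
    phi = float(abs(z))
    ax = 0.5 * np.angle(z)
    return phi, np.array([np.cos(ax), np.sin(ax)])


def polarity_state(packing: Packing, cell_ids=None) -> PolarityState:
    if cell_ids is None:
        cell_ids = [c for c in packing.cells
                    if packing.cells[c].type.is_cone]
    vecs = np.array([polarity_vector(packing, c) for c in cell_ids]
                    ).reshape(-1, 2)
    phi, ax = tissue_order(packing, cell_ids)
    return PolarityState(list(cell_ids), vecs,
                         np.hypot(vecs[:, 0], vecs[:, 1]), phi, ax)


def polarity_overlay_png(packing: Packing, path, bar_scale: float = 1.0,
                         dpi: int = 150) -> None:
    """Render the packing with a polarity bar per cone cell.

    Each bar is centered on the cell centroid, oriented along the cell's
    polarity vector; its length scales with the polarization strength.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(6, 6 * packing.Ly / max(packing.Lx, 1e-9)))
    for cid, cell in packing.cells.items():
        poly = packing.cell_polygon(cid)
        color = "0.85" if not cell.type.is_cone else {
            "red": "#d08080", "green": "#80c080", "blue": "#8080d0",
            "uv": "#c080c0"}.get(cell.type.value, "0.7")
        ax.fill(poly[:, 0], poly[:, 1], facecolor=color,
                edgecolor="k", linewidth=0.5)
        if cell.type.is_cone and len(cell.edge_cycle) >= 3:
            p = polarity_vector(packing, cid)
            m = np.hypot(*p)
            if m > 1e-9:
                c = packing.cell_centroid(cid)
                d = 0.5 * bar_scale * p / max(m, 1e-12) * min(m, 1.0)
                ax.plot([c[0] - d[0], c[0] + d[0]],
                        [c[1] - d[1], c[1] + d[1]],
                        color="navy", linewidth=2.0,
                        solid_capstyle="round")
    ax.set_xlim(0, packing.Lx)
    ax.set_ylim(0, packing.Ly)
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def initialize_random_pcp(packing: Packing, cell_ids,
                          rng: np.random.Generator,
                          total: float | None = None) -> None:
    """Random initial protein of a newborn column: per-edge concentrations
    i.i.d. uniform(0,1), amounts = concentration * length, normalized to
    the per-cell budget.  Sampling concentrations (not amounts) keeps the
    initial tension modulation unbiased with respect to edge length, so
    under fast elimination the order of edge loss is arbitrary."""
    if total is None:
        total = packing.params.pcp_total
    for cid in cell_ids:
        es = packing.cells[cid].edge_cycle
        lens = np.array([packing.edge_length(e) for e in es])
        w = rng.uniform(0.0, 1.0, size=len(es)) * lens
        s = w.sum()
        w = w / s if s > 0 else np.full(len(es), 1.0 / len(es))
        for eid, wi in zip(es, w):
            packing.edges[eid].pcp_amount[cid] = float(total * wi)
    packing.invalidate()


def initialize_polarized_pcp(packing: Packing, cell_ids,
                             column_of: dict[int, int | None] | None = None,
                             frac: float = 0.8,
                             total: float | None = None) -> None:
    """Polarized initial condition of established cone columns: ``frac`` of
    the budget on within-column interfaces, the rest spread uniformly."""
    if total is None:
        total = packing.params.pcp_total

    def col(cid):
        if column_of is not None:
            return column_of.get(cid)
        return packing.cells[cid].column

    for cid in cell_ids:
        es = packing.cells[cid].edge_cycle
        incol = [e for e in es
                 if (other := packing.edges[e].other_cell(cid)) is not None
                 and col(other) == col(cid)]
        rest = [e for e in es if e not in incol]
        for eid in es:
            packing.edges[eid].pcp_amount[cid] = 0.0
        if incol:
            for eid in incol:
                packing.edges[eid].pcp_amount[cid] = total * frac / len(incol)
            for eid in rest:
                packing.edges[eid].pcp_amount[cid] = (
                    total * (1 - frac) / len(rest)) if rest else 0.0
        else:
            for eid in es:
                packing.edges[eid].pcp_amount[cid] = total / len(es)
    packing.invalidate()
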