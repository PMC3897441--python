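"""Synthetic cone-mosaic lattices and rendered two-channel z-stacks.

Retinal flat-mount micrographs (ZO-1-outlined apical profiles plus a
rod reporter channel) are emulated here with full ground truth: an idealized
wild-type lattice built from the 12-cone motif, fragmented mutant-like
mosaics of curved single-cell-wide chains, and a renderer that turns
either lattice (or a simulated packing) into a multi-channel z-stack at
0.1 um/pixel with a bright junction-marker outline, a reporter channel
filling non-cone cells, per-cell z (OLM) profiles, and optional
Poisson + Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk
from skimage.segmentation import find_boundaries

from .geometry import Packing

__all__ = [
    "MosaicLattice",
    "SyntheticStack",
    "generate_ideal_mosaic",
    "generate_fragmented_mosaic",
    "render_stack",
    "render_packing",
    "PIXEL_SIZE_UM",
]

PIXEL_SIZE_UM = 0.1          # standard magnification, um per pixel
ROD_RADIUS_FACTOR = 0.55     # rod profile diameter relative to cones

#: within-column motif, phase 0 at the UV cone: uv, g, r, b, r, g
_MOTIF = ("uv", "green", "red", "blue", "red", "green")


@dataclass
class MosaicLattice:
    """Planar arrangement of cone/rod slots with ground-truth adjacency."""

    ids: list[int]
    types: list[str]                     # red green blue uv rod
    centers_um: np.ndarray               # (n, 2), x/y in micrometers
    groups: list[int | None]             # column / fragment index (rods: None)
    adjacency: list[tuple[int, int]]     # within-column neighbor pairs
    spacing_um: float
    seed: int
    meta: dict = field(default_factory=dict)

    def count(self, *types: str) -> int:
        return sum(t in types for t in self.types)

    def cone_ratio(self) -> float:
        """(red + green) / blue count."""
        blue = self.count("blue")
        if blue == 0:
            raise ValueError("no blue cones in lattice")
        return self.count("red", "green") / blue


def generate_ideal_mosaic(n_columns: int, n_rows: int,
                          spacing_um: float = 5.0,
                          seed: int = 0,
                          column_gap_factor: float = 1.5,
                          phase_offset: int = 0) -> MosaicLattice:
    """The crystalline wild-type lattice.

    Columns repeat the pentamer green-red-blue-red-green separated by
    single UV cones; adjacent columns are offset by half a motif (three
    slots) so cones of the same type are never lateral neighbors, which
    makes rows of blue and UV cones alternate with rows of red/green
    cones.  Rod slots sit at the interfaces between columns.  The
    (red+green)/blue ratio is exactly 4 whenever ``n_rows`` is a
    multiple of six.
    """
    if n_columns < 1 or n_rows < 1:
        raise ValueError("n_columns and n_rows must be >= 1")
    dy = spacing_um
    dx = spacing_um * column_gap_factor
    ids, types, centers, groups, adjacency = [], [], [], [], []
    nid = 0
    index = {}
    for c in range(n_columns):
        for r in range(n_rows):
            phase = (r + 1 + 3 * c + phase_offset) % 6
            ids.append(nid)
            types.append(_MOTIF[phase])
            centers.append(((c + 0.5) * dx, (r + 0.5) * dy))
            groups.append(c)
            index[(c, r)] = nid
            nid += 1
    for c in range(n_columns):
        for r in range(n_rows - 1):
            adjacency.append((index[(c, r)], index[(c, r + 1)]))
    # rods at the column interfaces (including the outer ones)
    for c in range(n_columns + 1):
        for r in range(n_rows):
            ids.append(nid)
            types.append("rod")
            centers.append((c * dx, r * dy))
            groups.append(None)
            nid += 1
    return MosaicLattice(ids, types, np.asarray(centers, float), groups,
                         adjacency, spacing_um, seed,
                         {"kind": "ideal", "n_columns": n_columns,
                          "n_rows": n_rows,
                          "column_gap_factor": column_gap_factor})


def generate_fragmented_mosaic(n_fragments: int = 60,
                               mean_length: float = 4.0,
                               length_dist: str = "geometric",
                               curvature: float = 0.5,
                               rod_density: float = 0.012,
                               spacing_um: float = 5.0,
                               seed: int = 0,
                               field_um: tuple[float, float] | None = None,
                               max_attempts: int = 400) -> MosaicLattice:
    """Mutant-like mosaic: curved, single-cell-wide cone chains (column
    fragments) surrounded by rods.

    Fragment lengths are geometric with the requested mean (or fixed);
    each fragment is a random walk with turn angles bounded by
    ``curvature`` (radians per step).  Raises on infeasible density.
    """
    if mean_length < 1:
        raise ValueError("mean_length must be >= 1")
    if length_dist not in ("geometric", "fixed"):
        raise ValueError("length_dist must be 'geometric' or 'fixed'")
    rng = np.random.default_rng(seed)
    if field_um is None:
        area_per_cone = (1.6 * spacing_um) ** 2
        side = float(np.sqrt(max(n_fragments, 1) * mean_length *
                             area_per_cone / 0.35))
        field_um = (side, side)
    W, H = field_um
    margin = spacing_um
    min_sep = 1.05 * spacing_um

    ids, types, centers, groups, adjacency = [], [], [], [], []
    placed: list[np.ndarray] = []
    nid = 0
    motif = ["green", "red", "blue", "red", "green"]

    def sample_length() -> int:
        if length_dist == "fixed":
            return int(round(mean_length))
        return int(rng.geometric(1.0 / mean_length))

    for fi in range(n_fragments):
        length = sample_length()
        for attempt in range(max_attempts):
            tree = cKDTree(np.array(placed)) if placed else None
            start = np.array([rng.uniform(margin, W - margin),
                              rng.uniform(margin, H - margin)])
            if tree is not None and tree.query(start)[0] < min_sep:
                continue
            bearing = rng.uniform(0, 2 * np.pi)
            chain = [start]
            ok = True
            for _ in range(length - 1):
                bearing += rng.uniform(-curvature, curvature)
                nxt = chain[-1] + spacing_um * np.array(
                    [np.cos(bearing), np.sin(bearing)])
                if not (margin <= nxt[0] <= W - margin
                        and margin <= nxt[1] <= H - margin):
                    ok = False
                    break
                if tree is not None and tree.query(nxt)[0] < min_sep:
                    ok = False
                    break
                if any(np.hypot(*(nxt - q)) < 0.95 * spacing_um
                       for q in chain[:-1]):
                    ok = False
                    break
                chain.append(nxt)
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place fragment {fi}: density infeasible "
                f"for field {field_um} at spacing {spacing_um}")
        phase = int(rng.integers(len(motif)))
        first = nid
        for j, ptn in enumerate(chain):
            ids.append(nid)
            types.append(motif[(phase + j) % len(motif)])
            centers.append(ptn)
            groups.append(fi)
            placed.append(ptn)
            if j > 0:
                adjacency.append((nid - 1, nid))
            nid += 1

    # rods fill the interstitium
    n_rods = int(rod_density * W * H)
    tree = cKDTree(np.array(placed)) if placed else None
    rod_pts: list[np.ndarray] = []
    attempts = 0
    while len(rod_pts) < n_rods and attempts < 60 * max(n_rods, 1):
        attempts += 1
        ptn = np.array([rng.uniform(margin / 2, W - margin / 2),
                        rng.uniform(margin / 2, H - margin / 2)])
        if tree is not None and tree.query(ptn)[0] < 0.85 * spacing_um:
            continue
        if rod_pts and cKDTree(np.array(rod_pts)).query(ptn)[0] < \
                0.7 * spacing_um:
            continue
        rod_pts.append(ptn)
    for ptn in rod_pts:
        ids.append(nid)
        types.append("rod")
        centers.append(ptn)
        groups.append(None)
        nid += 1

    return MosaicLattice(ids, types, np.asarray(centers, float), groups,
                         adjacency, spacing_um, seed,
                         {"kind": "fragmented", "n_fragments": n_fragments,
                          "mean_length": mean_length,
                          "length_dist": length_dist,
                          "curvature": curvature,
                          "rod_density": rod_density,
                          "field_um": list(field_um)})


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

@dataclass
class SyntheticStack:
    """Rendered two-channel z-stack with full ground truth."""

    zo1: np.ndarray                      # (z, y, x) float32 in [0, 1+]
    reporter: np.ndarray                 # same shape
    label_map: np.ndarray                # (y, x) int32; 0 = background
    types: dict[int, str]                # label -> cell type
    centers_px: dict[int, tuple[float, float]]   # label -> (x, y)
    olm_slice: dict[int, int]            # label -> ground-truth OLM z index
    adjacency: list[tuple[int, int]]     # ground-truth adjacent cone labels
    pixel_size_um: float
    noise: float
    seed: int

    @property
    def n_slices(self) -> int:
        return self.zo1.shape[0]

    def save(self, path) -> None:
        """Write a (z, 2, y, x) multi-channel TIFF plus ground-truth JSON."""
        path = str(path)
        stack = np.stack([self.zo1, self.reporter], axis=1).astype("float32")
        tifffile.imwrite(path, stack, metadata={
            "axes": "ZCYX", "pixel_size_um": self.pixel_size_um})
        gt = {
            "types": {str(k): v for k, v in self.types.items()},
            "centers_px": {str(k): list(v)
                           for k, v in self.centers_px.items()},
            "olm_slice": {str(k): int(v)
                          for k, v in self.olm_slice.items()},
            "adjacency": [list(p) for p in self.adjacency],
            "pixel_size_um": self.pixel_size_um,
            "noise": self.noise,
            "seed": self.seed,
        }
        with open(path.rsplit(".", 1)[0] + "_truth.json", "w") as fh:
            json.dump(gt, fh)


def _compose_stack(label_map: np.ndarray, types: dict[int, str],
                   centers_px: dict[int, tuple[float, float]],
                   z_slices: int, olm_slice: dict[int, int],
                   adjacency, noise: float, seed: int,
                   boundary_peak: float = 1.0, interior_level: float = 0.12,
                   background_level: float = 0.55,
                   reporter_contrast: float = 10.0,
                   z_sigma: float = 1.0) -> SyntheticStack:
    rng = np.random.default_rng(seed)
    H, W = label_map.shape
    # junction lines are ~0.3 um thick at 0.1 um/px
    from scipy import ndimage
    boundary = find_boundaries(label_map, mode="thick", background=0)
    boundary = ndimage.binary_dilation(boundary, disk(1))
    # per-pixel OLM slice from the owning cell
    max_label = int(label_map.max())
    olm_of = np.zeros(max_label + 1, dtype=float)
    for lbl, z in olm_slice.items():
        olm_of[lbl] = z
    olm_px = olm_of[label_map]

    filled = np.zeros(max_label + 1, dtype=bool)
    for lbl, t in types.items():
        if t in ("rod", "precursor"):
            filled[lbl] = True
    fill_px = filled[label_map]

    zo1 = np.empty((z_slices, H, W), dtype="float32")
    rep = np.empty_like(zo1)
    inside = label_map > 0
    for z in range(z_slices):
        zprof = np.exp(-0.5 * ((z - olm_px) / z_sigma) ** 2)
        plane = np.full((H, W), background_level, dtype="float32")
        plane[inside] = interior_level
        plane[boundary] = (background_level +
                           (boundary_peak - background_level) *
                           zprof[boundary])
        zo1[z] = plane
        rplane = np.full((H, W), background_level / reporter_contrast,
                         dtype="float32")
        mask = fill_px & inside
        rplane[mask] = (background_level +
                        boundary_peak * zprof[mask]) * \
            reporter_contrast / 10.0
        rep[z] = rplane
    if noise > 0:
        photons = 400.0
        zo1 = rng.poisson(np.clip(zo1, 0, None) * photons) / photons
        rep = rng.poisson(np.clip(rep, 0, None) * photons) / photons
        zo1 = zo1 + rng.normal(0.0, noise, zo1.shape)
        rep = rep + rng.normal(0.0, noise, rep.shape)
    return SyntheticStack(zo1.astype("float32"), rep.astype("float32"),
                          label_map.astype("int32"), dict(types),
                          dict(centers_px), dict(olm_slice),
                          list(adjacency), PIXEL_SIZE_UM, noise, seed)


def render_stack(lattice: MosaicLattice, z_slices: int = 1,
                 noise: float = 0.0, jitter_um: float = 0.0,
                 seed: int | None = None,
                 vary_olm: bool = False,
                 pixel_size_um: float = PIXEL_SIZE_UM) -> SyntheticStack:
    """Render a lattice into a two-channel z-stack at 0.1 um/pixel.

    Cell profiles are discs capped by the weighted Voronoi partition of
    the (optionally jittered) centers; rods are drawn at ``0.55`` times
    the cone diameter and filled in the reporter channel.  Raises if the
    pixel scale would make cells fewer than 3 px across.
    """
    if z_slices < 1:
        raise ValueError("need at least one z slice")
    seed = lattice.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    scale = 1.0 / pixel_size_um
    r_cone_um = 0.5 * lattice.spacing_um
    if 2 * r_cone_um * scale < 3:
        raise ValueError("cells are fewer than 3 pixels across at this "
                         "pixel size; increase spacing or resolution")
    centers = lattice.centers_um.copy()
    if jitter_um > 0:
        centers = centers + rng.normal(scale=jitter_um, size=centers.shape)
    margin_um = 1.2 * lattice.spacing_um
    offset = centers.min(axis=0) - margin_um
    centers_px = (centers - offset) * scale
    size = (centers.max(axis=0) - offset + margin_um) * scale
    W, H = int(np.ceil(size[0])), int(np.ceil(size[1]))

    radii = np.array([(ROD_RADIUS_FACTOR if t == "rod" else 1.0) *
                      r_cone_um * scale for t in lattice.types])
    labels = _weighted_disc_labels(centers_px, radii, (H, W))

    types = {i + 1: t for i, t in enumerate(lattice.types)}
    cmap = {i + 1: (float(centers_px[i][0]), float(centers_px[i][1]))
            for i in range(len(lattice.ids))}
    mid = z_slices // 2
    if vary_olm and z_slices > 1:
        olm = {i + 1: int(rng.integers(z_slices))
               for i in range(len(lattice.ids))}
    else:
        olm = {i + 1: mid for i in range(len(lattice.ids))}
    adjacency = [(a + 1, b + 1) for a, b in lattice.adjacency]
    return _compose_stack(labels, types, cmap, z_slices, olm, adjacency,
                          noise, seed)


def _weighted_disc_labels(centers_px: np.ndarray, radii: np.ndarray,
                          shape: tuple[int, int]) -> np.ndarray:
    """Assign pixels to the nearest center in radius-weighted metric,
    capped at each center's radius; 0 elsewhere."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(centers_px)
    k = min(8, len(centers_px))
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    wdist = dist / radii[idx]
    best = np.argmin(wdist, axis=1)
    rows = np.arange(len(pts))
    chosen = idx[rows, best]
    chosen_dist = dist[rows, best]
    labels = np.where(chosen_dist <= radii[chosen], chosen + 1, 0)
    return labels.reshape(H, W).astype("int32")


# --------------------------------------------------------------------------
# Rendering a simulated packing
# --------------------------------------------------------------------------

def render_packing(packing: Packing, scale_px_per_unit: float = 80.0,
                   z_slices: int = 1, noise: float = 0.0,
                   rod_conc_threshold: float = 0.6,
                   rod_radius_px: float | None = None,
                   seed: int = 0) -> SyntheticStack:
    """Render a vertex-model packing as a ZO-1/reporter stack.

    Cone cells are rasterized from their polygons; precursor cells are
    filled in the reporter channel (non-cone class).  Rod profiles are
    inserted along cone-cone interfaces whose total PCP concentration
    falls below ``rod_conc_threshold`` — rods populate exactly the
    interfaces that lack planar-polarized adhesion.  The neighboring
    cones are pushed back along the whole rod-bearing interface, as the
    inserted rods do in the tissue, so non-column neighbors are
    physically separated.
    """
    p = packing
    s = scale_px_per_unit
    H = int(round(p.Ly * s))
    W = int(round(p.Lx * s))
    labels = np.zeros((H, W), dtype="int32")
    types: dict[int, str] = {}
    centers: dict[int, tuple[float, float]] = {}

    for cid, cell in p.cells.items():
        poly = p.cell_polygon(cid) * s
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=None)
        rr = np.mod(rr, H)
        cc = np.clip(cc, 0, W - 1)
        labels[rr, cc] = cid + 1
        c = p.cell_centroid(cid) * s
        centers[cid + 1] = (float(c[0]), float(c[1]))
        types[cid + 1] = cell.type.value

    # rods along weak (adhesion-free) cone-cone interfaces: carve a
    # capsule along the interface (the displaced membrane) and place the
    # rod profile at its center
    if rod_radius_px is None:
        rod_radius_px = 0.11 * s
    carve_r = int(round(rod_radius_px)) + 3
    rod_disk = disk(int(round(rod_radius_px)))
    carve_disk = disk(carve_r)
    next_label = int(labels.max()) + 1
    for e in p.edges.values():
        a, b = e.cells
        if a is None or b is None:
            continue
        if not (p.cells[a].type.is_cone and p.cells[b].type.is_cone):
            continue
        L = p.edge_length(e.id)
        if L <= 0:
            continue
        conc = sum(e.pcp_amount.values()) / L
        if conc >= rod_conc_threshold:
            continue
        v1, v2 = e.vertices
        p1 = p.vertices[v1].pos * s
        dvec = p.displacement(v1, v2) * s
        seglen = float(np.hypot(*dvec))
        nstep = max(2, int(seglen / max(carve_r, 1)) * 2 + 1)
        for t in np.linspace(0.0, 1.0, nstep):
            pt = p1 + t * dvec
            _stamp(labels, carve_disk, int(round(pt[1])),
                   int(round(pt[0])), H, W, value=0)
        mid = p1 + 0.5 * dvec
        cx, cy = int(round(mid[0])), int(round(mid[1]))
        _stamp(labels, rod_disk, cy, cx, H, W, value=next_label)
        types[next_label] = "rod"
        centers[next_label] = (float(mid[0]), float(mid[1] % H))
        next_label += 1

    # thin separation between flush cells so each profile is outlined
    mid = z_slices // 2
    olm = {lbl: mid for lbl in types}
    adjacency = []
    for e in p.edges.values():
        a, b = e.cells
        if a is None or b is None:
            continue
        ca, cb = p.cells[a], p.cells[b]
        if (ca.type.is_cone and cb.type.is_cone
                and ca.column is not None and ca.column == cb.column):
            adjacency.append((a + 1, b + 1))
    return _compose_stack(labels, types, centers, z_slices, olm,
                          adjacency, noise, seed)


def _stamp(canvas: np.ndarray, footprint: np.ndarray, cy: int, cx: int,
           H: int, W: int, value: int) -> None:
    fh, fw = footprint.shape
    ys = np.arange(cy - fh // 2, cy - fh // 2 + fh)
    xs = np.arange(cx - fw // 2, cx - fw // 2 + fw)
    ys = np.mod(ys, H)
    keep = (xs >= 0) & (xs < W)
    sub = footprint[:, keep].astype(bool)
    canvas[np.ix_(ys, xs[keep])] = np.where(
        sub, value, canvas[np.ix_(ys, xs[keep])])
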