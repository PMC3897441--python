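"""Quantitative cone-adjacency analysis of ZO-1 / reporter z-stacks.

The measurement chain: maximum projection
of the junction-marker channel, threshold segmentation into cell
profiles, rod/cone classification by k-means on the reporter intensity
at each cell's own OLM slice, pairwise morphological closing (circular
structuring element, radius 10 px) to define the between-region of every
nearby cone pair, inertia-tensor thickness/elongation measures on that
region, and the two-threshold adjacency criteria (low: thickness <= 10
px and elongation ratio >= 2.0; high: 10 px and 2.5).  Coordination
histograms, planimetric densities with the two-of-four-sides edge rule,
and the (red+green)/blue cone ratio complete the outputs.

Thickness is reported as the principal radius of gyration
``sqrt(I_min / area)`` of the between-region, in pixels, so that the
10-pixel threshold is a geometrically meaningful length; the raw second
moments are recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from sklearn.cluster import KMeans

__all__ = [
    "SegmentedField",
    "PairMeasure",
    "AdjacencyResult",
    "PipelineError",
    "segment_cells",
    "classify_rods",
    "pair_measure",
    "adjacency_graphs",
    "coordination_histogram",
    "planimetric_density",
    "cone_type_ratio",
    "LOW_THRESHOLD",
    "HIGH_THRESHOLD",
    "CLOSING_RADIUS_PX",
]

CLOSING_RADIUS_PX = 10
LOW_THRESHOLD = {"max_thickness": 10.0, "min_ratio": 2.0}
HIGH_THRESHOLD = {"max_thickness": 10.0, "min_ratio": 2.5}
MIN_CELL_AREA_PX = 20
GLIA_ROUNDNESS = 0.45


class PipelineError(RuntimeError):
    pass


@dataclass
class SegmentedField:
    label_map: np.ndarray                 # (y, x) int; 0 = boundary/bg
    pixel_size_um: float
    centroids: dict[int, tuple[float, float]]      # label -> (x, y) px
    areas_px: dict[int, int]
    roundness: dict[int, float]
    touches_border: dict[int, bool]
    cell_class: dict[int, str] = field(default_factory=dict)
    olm_slice: dict[int, int] = field(default_factory=dict)
    reporter_mean: dict[int, float] = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return sorted(self.centroids)

    def cones(self) -> list[int]:
        return [k for k in self.labels
                if self.cell_class.get(k, "cone") == "cone"]

    def mask(self, lbl: int) -> np.ndarray:
        return self.label_map == lbl


@dataclass
class PairMeasure:
    pair: tuple[int, int]
    touching: bool
    region_area_px: int
    thickness_px: float                   # sqrt(I_min / area)
    elongation_ratio: float               # I_max / I_min
    raw_moments: tuple[float, float]      # (I_max, I_min), raw second moments

    def passes(self, max_thickness: float, min_ratio: float) -> bool:
        if self.region_area_px == 0:
            # nothing between them: adjacent iff directly abutting
            return self.touching
        return (self.thickness_px <= max_thickness
                and self.elongation_ratio >= min_ratio)


@dataclass
class AdjacencyResult:
    low: "nx.Graph"
    high: "nx.Graph"
    measures: dict[tuple[int, int], PairMeasure]
    low_histogram: dict[int, float]
    high_histogram: dict[int, float]

    def table(self) -> pd.DataFrame:
        """Coordination fractions in the printed-table layout: one row per
        threshold, columns n = 0..4 (percent)."""
        ns = [0, 1, 2, 3, 4]
        rows = []
        for name, h in (("low", self.low_histogram),
                        ("high", self.high_histogram)):
            row = {"threshold": name}
            for n in ns:
                key = f"n={n}" if n < 4 else "n=4+"
                val = h.get(n, 0.0)
                if n == 4:
                    val = sum(v for k, v in h.items() if k >= 4)
                row[key] = 100.0 * val
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------

def segment_cells(zo1_stack: np.ndarray, threshold_method: str = "otsu",
                  pixel_size_um: float = 0.1,
                  min_area_px: int = MIN_CELL_AREA_PX) -> SegmentedField:
    """Segment cell profiles from the junction-marker channel.

    Maximum projection -> global threshold (Otsu by default) -> bright
    boundary mask -> 8-connected components of its complement are the
    cell profiles.  Components smaller than ``min_area_px`` or equal to
    the outer background are dropped; border-touching cells are flagged.
    """
    zo1_stack = np.asarray(zo1_stack, dtype=float)
    if zo1_stack.ndim == 2:
        zo1_stack = zo1_stack[None]
    if not np.all(np.isfinite(zo1_stack)):
        raise PipelineError("non-finite intensities in the ZO-1 stack")
    proj = zo1_stack.max(axis=0)
    if threshold_method == "otsu":
        if np.allclose(proj.max(), proj.min()):
            raise PipelineError("no cells: blank image")
        thr = threshold_otsu(proj)
    else:
        thr = float(threshold_method)
    boundary = proj > thr
    if not boundary.any() or boundary.all():
        raise PipelineError("no cells: degenerate threshold")
    interior = ~boundary
    labels = cc_label(interior, connectivity=2)
    # the outer background is usually the largest border-spanning region
    # with very low mean intensity; drop components that are background:
    # everything else between boundaries is a cell profile
    out = np.zeros_like(labels)
    centroids, areas, roundness, touches = {}, {}, {}, {}
    H, W = labels.shape
    props = [rp for rp in regionprops(labels) if rp.area >= min_area_px]
    if not props:
        raise PipelineError("no cells found after filtering")
    # cell interiors are the dimmest component population; interstitial
    # regions (unresolved junction mesh between profiles) sit between the
    # interior level and the threshold and are not cells
    comp_mean = {rp.label: float(proj[labels == rp.label].mean())
                 for rp in props}
    dimmest = min(comp_mean.values())
    intensity_cut = 0.5 * (dimmest + thr)
    props = [rp for rp in props if comp_mean[rp.label] <= intensity_cut]
    if not props:
        raise PipelineError("no cells found after filtering")
    # the interstitial background is one sprawling border-touching
    # component much larger than any cell profile
    med_area = float(np.median([rp.area for rp in props]))
    nid = 0
    for rp in props:
        minr, minc, maxr, maxc = rp.bbox
        on_border = minr == 0 or minc == 0 or maxr == H or maxc == W
        if on_border and rp.area > 5 * med_area:
            continue
        nid += 1
        mask = labels == rp.label
        out[mask] = nid
        cy, cx = rp.centroid
        centroids[nid] = (cx, cy)
        areas[nid] = int(rp.area)
        per = max(rp.perimeter, 1.0)
        roundness[nid] = float(4 * np.pi * rp.area / per ** 2)
        touches[nid] = on_border
    if not centroids:
        raise PipelineError("no cells found after filtering")
    return SegmentedField(out.astype("int32"), pixel_size_um, centroids,
                          areas, roundness, touches)


def classify_rods(field: SegmentedField, zo1_stack: np.ndarray,
                  reporter_stack: np.ndarray, seed: int = 0,
                  n_restarts: int = 10) -> SegmentedField:
    """Split profiles into cones and rods by reporter intensity.

    For each cell the OLM slice is the z with the highest mean ZO-1 in a
    2-px annulus around the cell; the feature is the mean reporter
    intensity inside the cell at that slice.  Two-cluster k-means on the
    1-D features assigns the higher-intensity cluster to rods.  Cells
    failing the roundness filter are excluded as glia before clustering.
    """
    zo1_stack = np.asarray(zo1_stack, dtype=float)
    rep_stack = np.asarray(reporter_stack, dtype=float)
    if zo1_stack.ndim == 2:
        zo1_stack = zo1_stack[None]
    if rep_stack.ndim == 2:
        rep_stack = rep_stack[None]
    labels = field.label_map
    feats = {}
    for lbl in field.labels:
        mask = labels == lbl
        annulus = ndimage.binary_dilation(mask, disk(2)) & ~mask
        if not annulus.any():
            annulus = mask
        zmeans = zo1_stack[:, annulus].mean(axis=1)
        z = int(np.argmax(zmeans))
        field.olm_slice[lbl] = z
        feats[lbl] = float(rep_stack[z][mask].mean())
        field.reporter_mean[lbl] = feats[lbl]

    for lbl in field.labels:
        if field.roundness.get(lbl, 1.0) < GLIA_ROUNDNESS:
            field.cell_class[lbl] = "excluded_glia"
    candidates = [lbl for lbl in field.labels
                  if field.cell_class.get(lbl) != "excluded_glia"]
    if len(candidates) < 2:
        for lbl in candidates:
            field.cell_class[lbl] = "cone"
        return field
    X = np.array([[feats[lbl]] for lbl in candidates])
    if np.allclose(X.max(), X.min()):
        # degenerate: indistinguishable intensities; call everything cone
        for lbl in candidates:
            field.cell_class[lbl] = "cone"
        return field
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    rod_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    for lbl, a in zip(candidates, assign):
        field.cell_class[lbl] = "rod" if a == rod_cluster else "cone"
    return field


# --------------------------------------------------------------------------

def pair_measure(field: SegmentedField, cell_a: int, cell_b: int,
                 closing_radius: int = CLOSING_RADIUS_PX) -> PairMeasure:
    """Measure the between-region of one cell pair.

    Morphological closing (disc structuring element) of the pair's union
    mask; the between-region is the closed set minus the union.  An
    empty between-region with directly abutting cells marks the pair as
    touching (adjacent by definition); an empty region with separated
    cells means the closing could not bridge them.
    """
    for c in (cell_a, cell_b):
        if c not in field.centroids:
            raise PipelineError(f"cell {c} not in segmented field")
    if cell_a == cell_b:
        raise PipelineError("pair must be two distinct cells")
    lm = field.label_map
    mask = (lm == cell_a) | (lm == cell_b)
    # crop to the pair's bounding box plus closing reach
    ys, xs = np.nonzero(mask)
    pad = closing_radius + 2
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, lm.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, lm.shape[1])
    sub = mask[y0:y1, x0:x1]
    suba = (lm[y0:y1, x0:x1] == cell_a)
    subb = (lm[y0:y1, x0:x1] == cell_b)
    closed = ndimage.binary_closing(sub, structure=disk(closing_radius))
    between = closed & ~sub
    # pieces of the closed set must actually connect the two cells: keep
    # only between-pixels whose component touches both cells
    if between.any():
        comp = cc_label(closed, connectivity=2)
        keep = np.zeros_like(between)
        for cid in np.unique(comp[between]):
            if cid == 0:
                continue
            m = comp == cid
            if (m & suba).any() and (m & subb).any():
                keep |= m & between
        between = keep
    area = int(between.sum())
    touching = bool((ndimage.binary_dilation(suba, disk(1)) & subb).any())
    if area == 0:
        return PairMeasure((cell_a, cell_b), touching, 0, 0.0, 1.0,
                           (0.0, 0.0))
    ys, xs = np.nonzero(between)
    pts = np.column_stack([xs, ys]).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)          # second moments about centroid
    evals = np.linalg.eigvalsh(cov)
    i_min, i_max = float(max(evals[0], 0.0)), float(max(evals[1], 1e-12))
    thickness = float(np.sqrt(max(i_min, 1e-12)))
    ratio = float(i_max / max(i_min, 1e-12))
    return PairMeasure((cell_a, cell_b), touching, area, thickness, ratio,
                       (i_max, i_min))


def adjacency_graphs(field: SegmentedField,
                     low: dict = None, high: dict = None,
                     closing_radius: int = CLOSING_RADIUS_PX,
                     max_centroid_dist: float | None = 40.0,
                     cells: list[int] | None = None) -> AdjacencyResult:
    """Two-threshold adjacency over cone cells.

    A pair is adjacent at a threshold iff its between-region thickness is
    at most ``max_thickness`` and its elongation ratio at least
    ``min_ratio`` (or the cells are directly touching).  The high graph
    is a subgraph of the low graph by construction.  ``max_centroid_dist``
    (px) is a candidate-pair prefilter; pass None to test all pairs.
    """
    low = dict(LOW_THRESHOLD if low is None else low)
    high = dict(HIGH_THRESHOLD if high is None else high)
    cones = field.cones() if cells is None else list(cells)
    glow, ghigh = nx.Graph(), nx.Graph()
    glow.add_nodes_from(cones)
    ghigh.add_nodes_from(cones)
    measures: dict[tuple[int, int], PairMeasure] = {}
    if len(cones) >= 2:
        cents = np.array([field.centroids[c] for c in cones])
        if max_centroid_dist is None:
            pairs = [(i, j) for i in range(len(cones))
                     for j in range(i + 1, len(cones))]
        else:
            from scipy.spatial import cKDTree
            tree = cKDTree(cents)
            pairs = sorted(tree.query_pairs(max_centroid_dist))
        for i, j in pairs:
            a, b = cones[i], cones[j]
            m = pair_measure(field, a, b, closing_radius)
            measures[(a, b)] = m
            if m.passes(**{"max_thickness": low["max_thickness"],
                           "min_ratio": low["min_ratio"]}):
                glow.add_edge(a, b)
            if m.passes(**{"max_thickness": high["max_thickness"],
                           "min_ratio": high["min_ratio"]}):
                ghigh.add_edge(a, b)
    return AdjacencyResult(glow, ghigh, measures,
                           coordination_histogram(glow),
                           coordination_histogram(ghigh))


def coordination_histogram(graph: "nx.Graph") -> dict[int, float]:
    """Fraction of cones with n = 0, 1, 2, ... identified neighbors."""
    nodes = list(graph.nodes)
    if not nodes:
        raise PipelineError("empty graph: no cones to histogram")
    degs = np.array([graph.degree(n) for n in nodes])
    return {int(n): float(np.mean(degs == n))
            for n in range(int(degs.max()) + 1)}


# --------------------------------------------------------------------------

def planimetric_density(field: SegmentedField,
                        window_px: tuple[int, int, int, int] | None = None,
                        include_sides: tuple[str, str] = ("left", "top"),
                        classes: tuple[str, ...] = ("cone", "rod"),
                        ) -> dict[str, float]:
    """Cell density (#/10^3 um^2) inside a counting window.

    Cells wholly inside the window count; cells crossing the window
    boundary count only if every side they touch is one of the two
    designated inclusion sides (avoiding double counting when tiling).
    ``window_px`` is (x0, y0, x1, y1); default is the full field.
    """
    lm = field.label_map
    H, W = lm.shape
    if window_px is None:
        window_px = (0, 0, W, H)
    x0, y0, x1, y1 = window_px
    if x1 - x0 > W or y1 - y0 > H or x1 <= x0 or y1 <= y0:
        raise PipelineError("window larger than field or empty")
    counts = {c: 0 for c in classes}
    for lbl in field.labels:
        cls = field.cell_class.get(lbl, "cone")
        if cls not in counts:
            continue
        ys, xs = np.nonzero(lm == lbl)
        inside = (xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)
        if not inside.any():
            continue
        sides = set()
        if (xs < x0).any():
            sides.add("left")
        if (xs >= x1).any():
            sides.add("right")
        if (ys < y0).any():
            sides.add("top")
        if (ys >= y1).any():
            sides.add("bottom")
        if sides and not sides.issubset(set(include_sides)):
            continue
        counts[cls] += 1
    area_um2 = ((x1 - x0) * (y1 - y0)) * field.pixel_size_um ** 2
    return {cls: 1000.0 * n / area_um2 for cls, n in counts.items()}


def cone_type_ratio(types: dict[int, str]) -> tuple[float, dict[str, int]]:
    """(red+green)/blue ratio from per-cell type labels."""
    counts = {"red": 0, "green": 0, "blue": 0, "uv": 0}
    for t in types.values():
        if t in counts:
            counts[t] += 1
    if counts["blue"] == 0:
        raise PipelineError("undefined ratio: no blue cones in sample")
    ratio = (counts["red"] + counts["green"]) / counts["blue"]
    return ratio, counts
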