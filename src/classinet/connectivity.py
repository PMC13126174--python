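"""Network reconstruction and connectivity classification.

Two reconstruction strategies turn a set of cluster centroids into a
node-link graph:

* **range**: every centroid pair within a biologically constrained
  distance window (160-220 nm for node-labeled images, 40-220 nm for
  link-midpoint images, 120-220 nm for EM) is connected; planarity is then
  enforced by randomly deleting one link of each crossing pair.
* **delaunay**: a Delaunay triangulation is built and edges outside the
  distance window are removed, *except* when an edge is the sole
  out-of-range edge of a triangle whose other two edges are in range —
  preserving characteristic triangular motifs.

Connectivity per 1024 nm analysis window is quantified by link count,
triangle count and triangle area sum (triangles being the smallest closed
three-link cycles).  Thresholds separating genuine network domains from
density-driven artifacts are the 95th percentile of the same scores on
density-matched completely-spatially-random (CSR) null fields, i.e. a 5%
per-window false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .structures import (
    ClusterSet,
    CellMask,
    NetworkGraph,
    WindowGrid,
    accumulate_window_means,
)

METRICS = ("link_count", "triangle_count", "triangle_area_sum")

NODE_LINK_RANGE = (160.0, 220.0)
MIDPOINT_LINK_RANGE = (40.0, 220.0)
EM_LINK_RANGE = (120.0, 220.0)


def link_range_for_role(role: str) -> tuple[float, float]:
    return MIDPOINT_LINK_RANGE if role == "midpoint" else NODE_LINK_RANGE


# ---------------------------------------------------------------- geometry


def _three_cycles(n_nodes: int, links: np.ndarray) -> np.ndarray:
    """All 3-cycles of an undirected graph (small n; windows hold tens of
    nodes so cubic worst case never bites)."""
    if len(links) == 0:
        return np.zeros((0, 3), dtype=int)
    adj = [set() for _ in range(n_nodes)]
    for a, b in links:
        adj[a].add(b)
        adj[b].add(a)
    tris = set()
    for a, b in links:
        for c in adj[a] & adj[b]:
            tris.add(tuple(sorted((int(a), int(b), int(c)))))
    return np.asarray(sorted(tris), dtype=int).reshape(-1, 3)


# ----------------------------------------------------------- reconstruction


def _range_links(points: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if len(points) < 2:
        return np.zeros((0, 2), dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(hi, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
    pairs = pairs[(d >= lo) & (d <= hi)]
    return np.sort(pairs, axis=1)


def _crossing_pairs(points: np.ndarray, links: np.ndarray) -> np.ndarray:
    """Index pairs (i, j) of links that properly intersect (shared
    endpoints excluded).  Vectorized orientation tests."""
    L = len(links)
    if L < 2:
        return np.zeros((0, 2), dtype=int)
    ii, jj = np.triu_indices(L, k=1)
    a, b = links[ii, 0], links[ii, 1]
    c, d = links[jj, 0], links[jj, 1]
    share = (a == c) | (a == d) | (b == c) | (b == d)
    ii, jj, a, b, c, d = ii[~share], jj[~share], a[~share], b[~share], c[~share], d[~share]
    if len(ii) == 0:
        return np.zeros((0, 2), dtype=int)
    P = points

    def orient(p, q, r):
        v = (P[q, 0] - P[p, 0]) * (P[r, 1] - P[p, 1]) - (
            P[q, 1] - P[p, 1]
        ) * (P[r, 0] - P[p, 0])
        return np.sign(np.where(np.abs(v) < 1e-12, 0.0, v))

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    cross = (o1 != o2) & (o3 != o4) & (o1 != 0) & (o2 != 0) & (o3 != 0) & (o4 != 0)
    return np.column_stack([ii[cross], jj[cross]])


def _remove_crossings(
    points: np.ndarray, links: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Randomly delete one link of every crossing pair (seeded order)."""
    pairs = _crossing_pairs(points, links)
    alive = np.ones(len(links), dtype=bool)
    for k in rng.permutation(len(pairs)):
        i, j = pairs[k]
        if alive[i] and alive[j]:
            alive[i if rng.random() < 0.5 else j] = False
    return links[alive]


def _delaunay_edges(points: np.ndarray):
    """Delaunay simplices and the unique edge set."""
    tri = Delaunay(points)
    simplices = np.sort(tri.simplices, axis=1)
    edges = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [0, 2]], simplices[:, [1, 2]]]
    )
    return simplices, np.unique(edges, axis=0)


def reconstruct_network(
    centroids: ClusterSet | np.ndarray,
    method: str = "delaunay",
    link_range: tuple[float, float] = NODE_LINK_RANGE,
    seed: int = 0,
) -> NetworkGraph:
    """Reconstruct a node-link network from cluster centroids.

    With fewer than 3 nodes (or a degenerate point set) the Delaunay method
    falls back to plain range links — never an exception.
    """
    points = (
        centroids.centroids if isinstance(centroids, ClusterSet) else
        np.asarray(centroids, dtype=float).reshape(-1, 2)
    )
    lo, hi = link_range
    if not lo < hi:
        raise ValueError("link_range must satisfy lo < hi")

    if method == "range":
        links = _range_links(points, lo, hi)
        if len(links):
            links = _remove_crossings(points, links, np.random.default_rng(seed))
        tris = _three_cycles(len(points), links)
        return NetworkGraph(points, links, tris, "range", link_range)

    if method != "delaunay":
        raise ValueError(f"unknown reconstruction method {method!r}")

    if len(points) < 3:
        links = _range_links(points, lo, hi)
        return NetworkGraph(
            points, links, np.zeros((0, 3), int), "delaunay", link_range
        )
    try:
        simplices, edges = _delaunay_edges(points)
    except Exception:  # collinear / duplicate degeneracies
        links = _range_links(points, lo, hi)
        return NetworkGraph(
            points, links, np.zeros((0, 3), int), "delaunay", link_range
        )

    def in_range(e0, e1):
        d = np.linalg.norm(points[e0] - points[e1], axis=-1)
        return (d >= lo) & (d <= hi)

    edge_ok = {tuple(e): bool(in_range(e[0], e[1])) for e in edges}
    kept = {e for e, ok in edge_ok.items() if ok}
    # preservation rule: the sole out-of-range edge of a triangle whose
    # other two edges are in range is retained
    for s in simplices:
        tri_edges = [
            tuple(sorted((int(s[0]), int(s[1])))),
            tuple(sorted((int(s[0]), int(s[2])))),
            tuple(sorted((int(s[1]), int(s[2])))),
        ]
        status = [edge_ok[e] for e in tri_edges]
        if sum(status) == 2:
            kept.add(tri_edges[status.index(False)])
    links = np.asarray(sorted(kept), dtype=int).reshape(-1, 2)
    kept_set = set(map(tuple, links))
    tris = []
    for s in simplices:
        tri_edges = (
            tuple(sorted((int(s[0]), int(s[1])))),
            tuple(sorted((int(s[0]), int(s[2])))),
            tuple(sorted((int(s[1]), int(s[2])))),
        )
        if all(e in kept_set for e in tri_edges):
            tris.append(tuple(s))
    tris_arr = np.asarray(sorted(set(tris)), dtype=int).reshape(-1, 3)
    return NetworkGraph(points, links, tris_arr, "delaunay", link_range)


# ----------------------------------------------------------------- scoring


@dataclass
class ConnectivityScores:
    link_count: float
    triangle_count: float
    triangle_area_sum: float      # nm² per window

    def as_dict(self) -> dict:
        return {
            "link_count": self.link_count,
            "triangle_count": self.triangle_count,
            "triangle_area_sum": self.triangle_area_sum,
        }


def connectivity_scores(
    net: NetworkGraph, window: tuple[float, float, float, float]
) -> ConnectivityScores:
    """Score one (x0, y0, x1, y1) window.  Links and triangles are counted
    if their centroid (link midpoint / triangle centroid) lies in the
    half-open window, avoiding double counting across adjacent windows."""
    x0, y0, x1, y1 = window

    def inside(pts):
        if len(pts) == 0:
            return np.zeros(0, dtype=bool)
        return (
            (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
        )

    link_in = inside(net.link_midpoints)
    tri_in = inside(net.triangle_centroids())
    areas = net.triangle_areas()
    return ConnectivityScores(
        link_count=float(link_in.sum()),
        triangle_count=float(tri_in.sum()),
        triangle_area_sum=float(areas[tri_in].sum()) if len(areas) else 0.0,
    )


@dataclass
class ScoreMaps:
    """Per-grid-pixel heatmaps plus the raw per-window scores."""

    pixel_maps: dict                  # metric -> 2D array (NaN outside mask)
    window_scores: dict               # metric -> 1D array over windows
    window_origins: np.ndarray        # (W, 2) grid (row, col) of each window
    grid: WindowGrid
    window_density: np.ndarray | None = None   # clusters/µm² per window


def connectivity_heatmap(
    centroids: ClusterSet | np.ndarray,
    mask: CellMask,
    grid: WindowGrid | None = None,
    method: str = "delaunay",
    link_range: tuple[float, float] = NODE_LINK_RANGE,
    seed: int = 0,
) -> ScoreMaps:
    """Slide the 1024 nm window (step 256 nm) over the field; each window is
    independently reconstructed and scored.  Per-pixel heatmap values are
    the mean over all complete windows covering the pixel; pixels outside
    the cellular mask are NaN."""
    grid = grid or WindowGrid()
    points = (
        centroids.centroids if isinstance(centroids, ClusterSet) else
        np.asarray(centroids, dtype=float).reshape(-1, 2)
    )
    shape = mask.grid.shape
    tree = cKDTree(points) if len(points) else None
    half = grid.window_nm / 2.0

    origins = list(grid.window_origins(shape))
    scores = {m: np.zeros(len(origins)) for m in METRICS}
    win_density = np.zeros(len(origins))
    win_area_um2 = (grid.window_nm / 1000.0) ** 2
    for w_idx, (i, j) in enumerate(origins):
        x0, y0, x1, y1 = grid.window_bounds(i, j)
        if tree is None:
            continue
        idx = tree.query_ball_point(
            [(x0 + x1) / 2.0, (y0 + y1) / 2.0], half * np.sqrt(2.0) + 1e-9
        )
        pts = points[idx]
        sel = (
            (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
        )
        pts = pts[sel]
        win_density[w_idx] = len(pts) / win_area_um2
        net = reconstruct_network(pts, method, link_range, seed=seed + 7919 * w_idx)
        s = connectivity_scores(net, (x0, y0, x1, y1))
        for m in METRICS:
            scores[m][w_idx] = getattr(s, m)

    pixel_maps = {}
    for m in METRICS:
        pm = accumulate_window_means(scores[m], shape, grid)
        pm[~mask.grid] = np.nan
        pixel_maps[m] = pm
    return ScoreMaps(
        pixel_maps=pixel_maps,
        window_scores=scores,
        window_origins=np.asarray(origins, dtype=int).reshape(-1, 2),
        grid=grid,
        window_density=win_density,
    )


# -------------------------------------------------------------- null model


@dataclass
class NullModel:
    """Density-matched CSR null thresholds (per-metric 95th percentiles)."""

    density: float                     # clusters / µm²
    thresholds: dict                   # metric -> scalar
    n_reps: int = 100
    percentile: float = 95.0
    seed: int = 0
    samples: dict = field(default_factory=dict, repr=False)


def null_threshold(
    density: float,
    grid: WindowGrid | None = None,
    n_reps: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
    method: str = "delaunay",
    link_range: tuple[float, float] = NODE_LINK_RANGE,
    windows_per_rep: int = 16,
) -> NullModel:
    """Per-metric null thresholds from ``n_reps`` CSR replicate fields at
    the given density.

    Each replicate field is scanned into ``windows_per_rep`` disjoint
    analysis windows, each independently reconstructed and scored; the
    threshold is the stated percentile of the pooled window-score
    distribution (n_reps x windows_per_rep samples, so the tail estimate
    is stable)."""
    grid = grid or WindowGrid()
    if density < 0:
        raise ValueError("density must be >= 0")
    w = grid.window_nm
    side = int(np.ceil(np.sqrt(windows_per_rep)))
    area_um2 = (w / 1000.0) ** 2
    if density == 0:
        return NullModel(0.0, {m: 0.0 for m in METRICS}, n_reps, percentile, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC5A]))
    n_samples = n_reps * side * side
    samples = {m: np.zeros(n_samples) for m in METRICS}
    idx = 0
    for r in range(n_reps):
        n = rng.poisson(density * area_um2 * side * side)
        pts = rng.uniform(0.0, w * side, (n, 2))
        for wi in range(side):
            for wj in range(side):
                x0, y0 = wj * w, wi * w
                sel = (
                    (pts[:, 0] >= x0) & (pts[:, 0] < x0 + w)
                    & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + w)
                )
                net = reconstruct_network(
                    pts[sel] - [x0, y0], method, link_range, seed=seed + idx
                )
                s = connectivity_scores(net, (0.0, 0.0, w, w))
                for m in METRICS:
                    samples[m][idx] = getattr(s, m)
                idx += 1
    thresholds = {m: float(np.percentile(samples[m], percentile)) for m in METRICS}
    return NullModel(density, thresholds, n_reps, percentile, seed, samples)


def quantize_density(density: float, rel_step: float = 0.05) -> float:
    """Quantize a density to 5% multiplicative bins for threshold caching."""
    if density <= 0:
        return 0.0
    k = round(np.log(density) / np.log1p(rel_step))
    return float(np.exp(k * np.log1p(rel_step)))


def measured_density(points: np.ndarray, mask: CellMask) -> float:
    """Clusters per µm² inside the cellular mask."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if mask.area_um2 == 0:
        return 0.0
    ri = np.clip((pts[:, 1] / mask.pitch).astype(int), 0, mask.grid.shape[0] - 1)
    ci = np.clip((pts[:, 0] / mask.pitch).astype(int), 0, mask.grid.shape[1] - 1)
    n_in = int(mask.grid[ri, ci].sum()) if len(pts) else 0
    return n_in / mask.area_um2


def segment_network(
    conn_map: np.ndarray, null: NullModel, metric: str = "triangle_area_sum"
) -> np.ndarray:
    """Binary network mask: pixel is network iff its connectivity value
    exceeds the density-matched threshold.  NaN pixels are non-network."""
    thr = null.thresholds[metric]
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(conn_map), conn_map > thr, False)


def segment_network_local(
    maps: ScoreMaps,
    mask: CellMask,
    metric: str = "triangle_area_sum",
    n_reps: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
    method: str = "delaunay",
    link_range: tuple[float, float] = NODE_LINK_RANGE,
    cache: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Window-local density-matched segmentation.

    Every window's score is compared against the null threshold at that
    window's own centroid density (quantized to 5% bins; thresholds are
    cached per bin).  A pixel is network iff more than half of the
    complete windows covering it exceed their density-matched threshold.
    Returns the binary mask and the per-bin threshold dictionary.
    """
    if maps.window_density is None:
        raise ValueError("score maps lack per-window densities")
    cache = {} if cache is None else cache
    grid = maps.grid
    shape = mask.grid.shape
    exceed = np.zeros(len(maps.window_density))
    thresholds_used: dict[float, float] = {}
    for w_idx, dens in enumerate(maps.window_density):
        dbin = quantize_density(float(dens))
        key = (dbin, metric, link_range, n_reps, percentile, seed)
        if key not in cache:
            cache[key] = null_threshold(
                dbin, grid, n_reps, percentile, seed, method, link_range
            ).thresholds
        thr = cache[key][metric]
        thresholds_used[dbin] = thr
        exceed[w_idx] = 1.0 if maps.window_scores[metric][w_idx] > thr else 0.0
    frac = accumulate_window_means(exceed, shape, grid)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isfinite(frac), frac > 0.5, False)
    out &= mask.grid
    return out, thresholds_used
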