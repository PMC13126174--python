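"""Synthetic SMLM data generation with ground truth.

The generator emulates SMLM images of node-link networks at the level of
molecular localization clusters.  Ideal lattices are built first — parallel
lines with equal spacing for 1D periodic networks (190 nm default, the
spectrin-lattice period) and honeycomb (degree-3 hexagonal) lattices for
2D polygonal networks — then perturbed by experimentally motivated noise:
missed detections (Bernoulli deletion), false-positive clusters (a CSR
overlay), and lateral Gaussian jitter of cluster centroids.  Localization
clusters are expanded into individual localizations with log-normal
per-cluster localization counts and log-normal per-localization precision.
Non-network fields are homogeneous Poisson (CSR) draws.

Composite fields place one pattern inside an irregular island mask (white
noise -> Gaussian blur -> median threshold -> morphological refinement)
and a second pattern outside, at matched cluster densities, with the mask
retained as the pixelwise ground-truth label grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import closing, disk, opening

from .structures import (
    LABEL_1D,
    LABEL_2D,
    LABEL_NON_NETWORK,
    ClusterSet,
    LocalizationTable,
    NetworkGraph,
    WindowGrid,
)

PATTERNS = ("1d_periodic", "2d_hex", "csr")

PATTERN_LABELS = {
    "1d_periodic": LABEL_1D,
    "2d_hex": LABEL_2D,
    "csr": LABEL_NON_NETWORK,
}


@dataclass
class SimConfig:
    """Parameters of one simulated field.

    Geometry defaults follow the spectrin skeleton: 190 nm line spacing for
    the 1D lattice, 190 nm side for the 2D honeycomb lattice, and a 100 nm
    spacing of clusters along each 1D line (a placeholder calibration
    constant for the across-axis cluster spacing).  ``density`` (clusters
    per µm²) applies to CSR draws.  Log-normal parameters are (mu, sigma)
    of the underlying normal.
    """

    pattern: str = "csr"
    extent: tuple[float, float] = (6144.0, 6144.0)      # nm (24 x 24 grid px)
    line_spacing: float = 190.0                          # nm, 1D period
    within_line_spacing: float = 100.0                   # nm along each line
    hex_side: float = 190.0                              # nm honeycomb edge
    density: float | None = None                         # clusters / µm² (csr)
    miss_rate: float = 0.2                               # ~80% labeling efficiency
    fp_rate: float = 0.0                                 # clusters / µm²
    jitter_sigma: float = 10.0                           # nm, precision-scale
    locs_per_cluster: tuple[float, float] = (math.log(30.0), 0.5)
    precision: tuple[float, float] = (math.log(12.0), 0.3)
    fp_single_localization: bool = False                 # FPs emit 1 loc each
    rotation_deg: float | None = None                    # None -> seeded draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; one of {PATTERNS}")
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if self.locs_per_cluster[1] < 0 or self.precision[1] < 0:
            raise ValueError("log-normal sigma must be >= 0")


@dataclass
class GroundTruth:
    """Per-field truth: label grid (256 nm pixels), ideal centroids and the
    ideal lattice network (pre-perturbation)."""

    label_grid: np.ndarray
    true_centroids: np.ndarray
    true_network: NetworkGraph | None = None
    island_mask: np.ndarray | None = None


def pattern_density(cfg: SimConfig) -> float:
    """Analytic expected cluster density (clusters per µm²) of a pattern."""
    if cfg.pattern == "csr":
        if cfg.density is None:
            raise ValueError("csr pattern requires density")
        return float(cfg.density)
    if cfg.pattern == "1d_periodic":
        return 1e6 / (cfg.line_spacing * cfg.within_line_spacing)
    # honeycomb: 4 nodes per 3*sqrt(3)*s^2 unit area
    return 1e6 * 4.0 / (3.0 * math.sqrt(3.0) * cfg.hex_side**2)


def _rotate(points: np.ndarray, deg: float, center: np.ndarray) -> np.ndarray:
    t = math.radians(deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    return (points - center) @ rot.T + center


def _ideal_1d(cfg: SimConfig, rng: np.random.Generator):
    w, h = cfg.extent
    center = np.array([w / 2.0, h / 2.0])
    # generate with margin so rotation still fills the extent
    half = math.hypot(w, h) / 2.0 + cfg.line_spacing
    ys = np.arange(-half, half, cfg.line_spacing)
    xs = np.arange(-half, half, cfg.within_line_spacing)
    nodes = []
    links = []
    nx = len(xs)
    for li, y in enumerate(ys):
        base = len(nodes)
        for xi, x in enumerate(xs):
            nodes.append((center[0] + x, center[1] + y))
        if li > 0:
            # molecular links are the cross-line tetramers (length = period);
            # adjacency of clusters along one line reflects labeling
            # granularity of a ring, not a link, so it carries no midpoint
            prev = base - nx
            for xi in range(nx):
                links.append((prev + xi, base + xi))
    return np.asarray(nodes), np.asarray(links, dtype=int)


def _ideal_hex(cfg: SimConfig, rng: np.random.Generator):
    """Honeycomb lattice with edge length ``hex_side`` (interior degree 3)."""
    s = cfg.hex_side
    w, h = cfg.extent
    half = math.hypot(w, h) / 2.0 + 3 * s
    a1 = np.array([math.sqrt(3.0) * s, 0.0])
    a2 = np.array([math.sqrt(3.0) * s / 2.0, 1.5 * s])
    basis = [np.array([0.0, 0.0]), np.array([0.0, s])]
    n1 = int(half / a1[0]) + 2
    n2 = int(half / a2[1]) + 2
    center = np.array([w / 2.0, h / 2.0])
    nodes = []
    for i in range(-n1 - n2, n1 + n2 + 1):
        for j in range(-n2, n2 + 1):
            cell = i * a1 + j * a2
            for off in basis:
                nodes.append(center + cell + off)
    nodes_arr = np.asarray(nodes)
    # lattice edges are exactly the nearest-neighbor pairs at distance s
    from scipy.spatial import cKDTree

    tree = cKDTree(nodes_arr)
    pairs = tree.query_pairs(s * 1.001, output_type="ndarray")
    good = (
        np.abs(
            np.linalg.norm(nodes_arr[pairs[:, 0]] - nodes_arr[pairs[:, 1]], axis=1) - s
        )
        < 1e-6
    )
    links_arr = np.unique(np.sort(pairs[good], axis=1), axis=0)
    return nodes_arr, links_arr


def _clip_network(nodes: np.ndarray, links: np.ndarray, extent) -> tuple[np.ndarray, np.ndarray]:
    w, h = extent
    keep = (
        (nodes[:, 0] >= 0) & (nodes[:, 0] < w) & (nodes[:, 1] >= 0) & (nodes[:, 1] < h)
    )
    remap = -np.ones(len(nodes), dtype=int)
    remap[keep] = np.arange(keep.sum())
    nodes2 = nodes[keep]
    if len(links):
        lk = links[keep[links[:, 0]] & keep[links[:, 1]]]
        links2 = remap[lk]
    else:
        links2 = np.zeros((0, 2), dtype=int)
    return nodes2, links2


def label_grid_for(extent, pattern: str, grid: WindowGrid | None = None) -> np.ndarray:
    grid = grid or WindowGrid()
    return np.full(grid.n_pixels(extent), PATTERN_LABELS[pattern], dtype=np.uint8)


def simulate_pattern(cfg: SimConfig) -> tuple[ClusterSet, GroundTruth]:
    """Generate one perturbed field plus its ground truth.

    The ideal lattice (or CSR draw) is built, each cluster is independently
    deleted with probability ``miss_rate``, false positives are added as a
    CSR overlay at ``fp_rate``, and surviving centroids are displaced by
    isotropic Gaussian jitter.
    """
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.extent
    area_um2 = (w / 1000.0) * (h / 1000.0)
    true_net = None
    if cfg.pattern == "csr":
        if cfg.density is None:
            raise ValueError("csr pattern requires density")
        n = rng.poisson(cfg.density * area_um2)
        ideal = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    else:
        if cfg.pattern == "1d_periodic":
            nodes, links = _ideal_1d(cfg, rng)
        else:
            nodes, links = _ideal_hex(cfg, rng)
        rot = (
            cfg.rotation_deg
            if cfg.rotation_deg is not None
            else float(rng.uniform(0.0, 180.0))
        )
        nodes = _rotate(nodes, rot, np.array([w / 2.0, h / 2.0]))
        nodes, links = _clip_network(nodes, links, cfg.extent)
        ideal = nodes
        true_net = NetworkGraph(
            nodes=nodes,
            links=links,
            triangles=np.zeros((0, 3), dtype=int),
            method="ideal",
            link_range=(0.0, np.inf),
        )

    truth = GroundTruth(
        label_grid=label_grid_for(cfg.extent, cfg.pattern),
        true_centroids=ideal.copy(),
        true_network=true_net,
    )

    centroids = ideal
    if cfg.miss_rate > 0 and len(centroids):
        keep = rng.random(len(centroids)) >= cfg.miss_rate
        centroids = centroids[keep]
    n_fp = rng.poisson(cfg.fp_rate * area_um2) if cfg.fp_rate > 0 else 0
    is_fp = np.zeros(len(centroids), dtype=bool)
    if n_fp:
        fps = np.column_stack([rng.uniform(0, w, n_fp), rng.uniform(0, h, n_fp)])
        centroids = np.vstack([centroids, fps]) if len(centroids) else fps
        is_fp = np.concatenate([is_fp, np.ones(n_fp, dtype=bool)])
    if cfg.jitter_sigma > 0 and len(centroids):
        centroids = centroids + rng.normal(0.0, cfg.jitter_sigma, centroids.shape)
        centroids = np.clip(centroids, [0, 0], [w - 1e-9, h - 1e-9])
    clusters = ClusterSet(centroids=centroids, role="node")
    clusters.is_false_positive = is_fp  # type: ignore[attr-defined]
    return clusters, truth


def emit_localizations(clusters: ClusterSet, cfg: SimConfig) -> LocalizationTable:
    """Expand cluster centroids into individual localizations.

    Per-cluster localization counts are log-normal draws rounded to >= 1;
    each localization is scattered isotropically around its centroid with a
    per-localization precision drawn from the precision log-normal.  False
    positives optionally emit a single localization each
    (``fp_single_localization``), modeling nonclustered background noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = len(clusters)
    if n == 0:
        return LocalizationTable(x=np.zeros(0), y=np.zeros(0))
    mu, sigma = cfg.locs_per_cluster
    counts = np.maximum(1, np.round(rng.lognormal(mu, sigma, n))).astype(int)
    is_fp = getattr(clusters, "is_false_positive", None)
    if cfg.fp_single_localization and is_fp is not None and is_fp.any():
        counts[is_fp] = 1
    total = int(counts.sum())
    pmu, psigma = cfg.precision
    prec = rng.lognormal(pmu, psigma, total)
    centers = np.repeat(clusters.centroids, counts, axis=0)
    xy = centers + rng.normal(0.0, 1.0, (total, 2)) * prec[:, None]
    xy = np.clip(xy, 0.0, None)
    return LocalizationTable(x=xy[:, 0], y=xy[:, 1], precision=prec)


def _boundary_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    blur_sigma_px: float,
    morph_radius_px: int,
) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, shape)
    smooth = gaussian_filter(noise, blur_sigma_px)
    mask = smooth > np.median(smooth)
    se = disk(morph_radius_px)
    mask = closing(opening(mask, se), se)
    return mask.astype(bool)


def make_composite(
    island_cfg: SimConfig,
    background_cfg: SimConfig,
    boundary_seed: int = 0,
    island_fraction: tuple[float, float] = (0.2, 0.6),
    max_retries: int = 25,
    grid: WindowGrid | None = None,
) -> tuple[ClusterSet, GroundTruth]:
    """Composite field: island pattern inside an irregular mask, background
    pattern outside, at matched cluster densities.

    The mask is built on the 256 nm grid from white noise blurred with a
    1 µm Gaussian, thresholded at its median and refined by morphological
    opening/closing with a 0.5 µm disk.  Masks whose island fraction falls
    outside ``island_fraction`` are regenerated with the next sub-seed.
    If the background is CSR with no density set, its density is matched
    to the island pattern's analytic density.
    """
    grid = grid or WindowGrid()
    if island_cfg.extent != background_cfg.extent:
        raise ValueError("island and background extents must match")
    shape = grid.n_pixels(island_cfg.extent)
    blur_px = 1000.0 / grid.pitch
    morph_px = max(1, int(round(500.0 / grid.pitch)))

    mask = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([boundary_seed, attempt]))
        cand = _boundary_mask(shape, rng, blur_px, morph_px)
        frac = cand.mean()
        if island_fraction[0] <= frac <= island_fraction[1]:
            mask = cand
            break
        if island_fraction[0] <= 1.0 - frac <= island_fraction[1]:
            mask = ~cand
            break
    if mask is None:
        raise RuntimeError("could not generate a usable island mask")

    if background_cfg.pattern == "csr" and background_cfg.density is None:
        background_cfg = replace(background_cfg, density=pattern_density(island_cfg))

    def _grid_idx(points: np.ndarray):
        ci = np.floor(points[:, 0] / grid.pitch).astype(int)
        ri = np.floor(points[:, 1] / grid.pitch).astype(int)
        ri = np.clip(ri, 0, shape[0] - 1)
        ci = np.clip(ci, 0, shape[1] - 1)
        return ri, ci

    island_clusters, island_truth = simulate_pattern(island_cfg)
    bg_clusters, bg_truth = simulate_pattern(background_cfg)

    ri, ci = _grid_idx(island_clusters.centroids)
    inside = mask[ri, ci] if len(island_clusters) else np.zeros(0, dtype=bool)
    ri, ci = _grid_idx(bg_clusters.centroids)
    outside = ~mask[ri, ci] if len(bg_clusters) else np.zeros(0, dtype=bool)

    centroids = np.vstack(
        [island_clusters.centroids[inside], bg_clusters.centroids[outside]]
    )
    clusters = ClusterSet(centroids=centroids, role="node")

    label_grid = np.where(
        mask,
        PATTERN_LABELS[island_cfg.pattern],
        PATTERN_LABELS[background_cfg.pattern],
    ).astype(np.uint8)
    # truth centroids restricted the same way
    ri, ci = _grid_idx(island_truth.true_centroids)
    t_in = mask[ri, ci] if len(island_truth.true_centroids) else np.zeros(0, bool)
    truth = GroundTruth(
        label_grid=label_grid,
        true_centroids=island_truth.true_centroids[t_in],
        true_network=island_truth.true_network,
        island_mask=mask,
    )
    return clusters, truth


def network_to_midpoints(net: NetworkGraph) -> ClusterSet:
    """One midpoint centroid per link (the link-midpoint labeling mode)."""
    return ClusterSet(centroids=net.link_midpoints, role="midpoint")
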