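"""Benchmark protocols on simulated ground truth.

Each function re-runs one of the package's validation experiments from
scratch: composite fields are generated by the simulator, the classifier
under test is applied with density-matched null thresholds, and pixelwise
F1 against the known island mask is reported.  These protocols back both
the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import connectivity as co
from . import locio, periodic1d as p1, regular2d as r2
from .midpoints import infer_nodes
from .pipeline_eval import f1_metric
from .simgen import SimConfig, make_composite, pattern_density, simulate_pattern
from .structures import (
    GRID_PITCH,
    LABEL_1D,
    LABEL_2D,
    LABEL_DISORDERED,
    LABEL_NON_NETWORK,
    ClusterSet,
    WindowGrid,
    accumulate_window_means,
)

EXTENT = (6144.0, 6144.0)        # 6.1 µm fields, 24 x 24 grid pixels

ONED_SCORES = ("a_fft", "r_global", "r_proj", "r_local", "s_integrated")
TWOD_SCORES = ("s_count", "s_length", "s_angle", "s_integrated")


# ------------------------------------------------ connectivity benchmarks


def connectivity_f1_missed_detections(
    n_seeds: int = 10,
    miss_rate: float = 0.4,
    seed: int = 0,
    extent: tuple[float, float] = EXTENT,
    method: str = "delaunay",
    metric: str = "triangle_area_sum",
) -> np.ndarray:
    """Pixelwise F1 of network-vs-background segmentation on 1D-periodic
    islands in a density-matched CSR background with a missed-detection
    perturbation, one value per seed."""
    mask = locio.full_mask(extent)
    f1s = np.zeros(n_seeds)
    null_cache: dict[float, co.NullModel] = {}
    for k in range(n_seeds):
        island = SimConfig(pattern="1d_periodic", miss_rate=miss_rate,
                           extent=extent, seed=seed * 1000 + 2 * k)
        background = SimConfig(pattern="csr", miss_rate=miss_rate,
                               extent=extent, seed=seed * 1000 + 2 * k + 1)
        clusters, truth = make_composite(island, background, boundary_seed=seed * 97 + k)
        dens = co.quantize_density(co.measured_density(clusters.centroids, mask))
        if dens not in null_cache:
            null_cache[dens] = co.null_threshold(dens, seed=seed + 13)
        maps = co.connectivity_heatmap(clusters, mask, method=method, seed=seed)
        pred = co.segment_network(maps.pixel_maps[metric], null_cache[dens], metric)
        f1s[k], _, _ = f1_metric(pred, truth.island_mask)
    return f1s


def null_false_positive_rate(
    density: float | None = None,
    n_fields: int = 15,
    seed: int = 0,
    extent: tuple[float, float] = EXTENT,
    metric: str = "triangle_area_sum",
) -> tuple[float, int]:
    """Fraction of fresh CSR analysis windows exceeding the 95th-percentile
    null threshold built from 100 CSR replicates at the same density.

    Evaluation windows are disjoint (step = window), so the count is a
    genuine binomial sample.  Returns (empirical rate, number of windows).
    """
    if density is None:
        density = pattern_density(SimConfig(pattern="1d_periodic"))
    null = co.null_threshold(density, seed=seed + 101)
    thr = null.thresholds[metric]
    grid = WindowGrid(step_px=WindowGrid().window_px)
    mask = locio.full_mask(extent, grid)
    n_exceed = n_total = 0
    for k in range(n_fields):
        # plain CSR at the stated observed density: no perturbations
        clusters, _ = simulate_pattern(
            SimConfig(pattern="csr", density=density, extent=extent,
                      miss_rate=0.0, jitter_sigma=0.0,
                      seed=seed * 500 + 77 + k)
        )
        maps = co.connectivity_heatmap(clusters, mask, grid)
        ws = maps.window_scores[metric]
        n_exceed += int((ws > thr).sum())
        n_total += len(ws)
    return n_exceed / n_total, n_total


def connectivity_pipeline_comparison(
    island_pattern: str = "1d_periodic",
    n_seeds: int = 4,
    seed: int = 0,
    extent: tuple[float, float] = EXTENT,
) -> dict[str, float]:
    """Mean F1 of all six reconstruction x metric pipelines on island
    composites (island pattern vs density-matched CSR background)."""
    mask = locio.full_mask(extent)
    sums: dict[str, list[float]] = {
        f"{m}+{s}": [] for m in ("delaunay", "range") for s in co.METRICS
    }
    null_cache: dict[tuple, co.NullModel] = {}
    for k in range(n_seeds):
        island = SimConfig(pattern=island_pattern, extent=extent, seed=seed * 300 + k)
        background = SimConfig(pattern="csr", extent=extent, seed=seed * 300 + 150 + k)
        clusters, truth = make_composite(island, background, boundary_seed=seed * 31 + k)
        dens = co.quantize_density(co.measured_density(clusters.centroids, mask))
        for method in ("delaunay", "range"):
            key = (dens, method)
            if key not in null_cache:
                null_cache[key] = co.null_threshold(dens, method=method, seed=seed + 7)
            maps = co.connectivity_heatmap(clusters, mask, method=method, seed=seed)
            for metric in co.METRICS:
                pred = co.segment_network(
                    maps.pixel_maps[metric], null_cache[key], metric
                )
                f1, _, _ = f1_metric(pred, truth.island_mask)
                sums[f"{method}+{metric}"].append(f1)
    return {k: float(np.mean(v)) for k, v in sums.items()}


# ------------------------------------------------------- 1D benchmarks


def _window_scores_1d(pixels: np.ndarray, grid: WindowGrid, shape) -> dict[str, np.ndarray]:
    """Per-window candidate 1D scores over a rendered field."""
    factor = int(round(grid.pitch / 16.0))
    wpx = grid.window_px * factor
    origins = list(grid.window_origins(shape))
    out = {s: np.zeros(len(origins)) for s in ONED_SCORES}
    for w_idx, (i, j) in enumerate(origins):
        sub = pixels[i * factor : i * factor + wpx, j * factor : j * factor + wpx]
        _, sc = p1.analyze_window_1d(sub)
        for s in ONED_SCORES:
            out[s][w_idx] = getattr(sc, s)
    return out


def _score_nulls_1d(density: float, seed: int, n_fields: int = 2,
                    extent=(4096.0, 4096.0)) -> dict[str, tuple[float, float]]:
    """(99th, 95th) percentile of each candidate score over CSR windows —
    the seed and growth thresholds of the region-growing segmentation."""
    grid = WindowGrid()
    shape = grid.n_pixels(extent)
    pooled: dict[str, list] = {s: [] for s in ONED_SCORES}
    for k in range(n_fields):
        clusters, _ = simulate_pattern(
            SimConfig(pattern="csr", density=density, extent=extent,
                      miss_rate=0.0, jitter_sigma=0.0,
                      seed=seed * 900 + 55 + k)
        )
        img = locio.render_clusters(clusters, 16.0, extent)
        ws = _window_scores_1d(img.pixels, grid, shape)
        for s in ONED_SCORES:
            pooled[s].extend(ws[s])
    return {
        s: (float(np.percentile(pooled[s], 99.0)),
            float(np.percentile(pooled[s], 95.0)))
        for s in ONED_SCORES
    }


def oned_score_comparison(
    background_pattern: str = "csr",
    n_seeds: int = 4,
    seed: int = 0,
    extent: tuple[float, float] = EXTENT,
) -> dict[str, float]:
    """Mean F1 of each candidate 1D regularity score on 1D-island
    composites.  Every score's heatmap is segmented with the same refined
    seed-region-growing machinery, seeded at that score's CSR-null 99th
    percentile (1% FPR) and grown at its 95th percentile (5% FPR) under
    the orientation/period consistency constraints."""
    grid = WindowGrid()
    island0 = SimConfig(pattern="1d_periodic", extent=extent, seed=0)
    # null at the composite's observed (post-miss) density
    dens = pattern_density(island0) * (1.0 - island0.miss_rate)
    thresholds = _score_nulls_1d(dens, seed)
    sums: dict[str, list[float]] = {s: [] for s in ONED_SCORES}
    mask = locio.full_mask(extent, grid)
    for k in range(n_seeds):
        island = SimConfig(pattern="1d_periodic", extent=extent, seed=seed * 400 + k)
        # CSR background density auto-matches the island's analytic density
        # and is thinned by the same default miss rate
        background = SimConfig(pattern=background_pattern, extent=extent,
                               seed=seed * 400 + 200 + k)
        clusters, truth = make_composite(island, background, boundary_seed=seed * 41 + k)
        img = locio.render_clusters(clusters, 16.0, extent)
        maps = p1.periodicity_maps(img, mask, grid, keep_candidate_scores=True)
        for s in ONED_SCORES:
            pm = maps.score_grid if s == "s_integrated" else maps.per_score_grids[s]
            score_map = p1.OrientationPeriodMap(pm, maps.theta_grid, maps.d_grid, grid)
            seed_thr, grow_thr = thresholds[s]
            pred = p1.segment_1d(score_map, seed_thr=seed_thr, grow_thr=grow_thr)
            f1, _, _ = f1_metric(pred, truth.island_mask)
            sums[s].append(f1)
    return {s: float(np.mean(v)) for s, v in sums.items()}


def period_orientation_recovery(
    n_seeds: int = 3, seed: int = 0, extent=(4096.0, 4096.0)
) -> tuple[float, float]:
    """(period-mode error nm, median orientation error deg) on perturbed
    1D lattices with known rotation."""
    grid = WindowGrid()
    mask = locio.full_mask(extent, grid)
    d_err, t_err = [], []
    for k in range(n_seeds):
        rot = 20.0 + 37.0 * k
        cfg = SimConfig(pattern="1d_periodic", extent=extent,
                        rotation_deg=rot, seed=seed * 600 + k)
        clusters, _ = simulate_pattern(cfg)
        img = locio.render_clusters(clusters, 16.0, extent)
        maps = p1.periodicity_maps(img, mask, grid)
        seg = p1.segment_1d(maps)
        dist = p1.period_histogram(seg, maps)
        if dist.mode is not None:
            d_err.append(abs(dist.mode - 190.0))
        th = maps.theta_grid[seg & np.isfinite(maps.theta_grid)]
        expected = (rot + 90.0) % 180.0   # periodicity axis is normal to lines
        diff = np.abs(th - expected) % 180.0
        t_err.append(float(np.median(np.minimum(diff, 180.0 - diff))))
    return float(np.max(d_err)), float(np.max(t_err))


# ------------------------------------------------------- 2D benchmarks


def twod_score_comparison(
    background_pattern: str = "csr",
    n_seeds: int = 4,
    seed: int = 0,
    extent: tuple[float, float] = EXTENT,
) -> dict[str, float]:
    """Mean F1 of the three single-feature 2D regularity scores and the
    LDA-integrated score on 2D-hex-island composites."""
    grid = WindowGrid()
    mask = locio.full_mask(extent, grid)
    weights = r2.default_lda_weights(seed)
    island0 = SimConfig(pattern="2d_hex", extent=extent, seed=0)
    dens = pattern_density(island0) * (1.0 - island0.miss_rate)

    def field_window_means(net):
        feats, valid = r2.regularity_features(net)
        values = {
            "s_count": feats[:, 0], "s_length": feats[:, 1],
            "s_angle": feats[:, 2], "s_integrated": weights.project(feats),
        }
        return {
            s: r2.window_mean_scores(net, values[s], valid, mask, grid)[0]
            for s in TWOD_SCORES
        }

    # null thresholds from full CSR fields scanned with the same windows
    null_vals: dict[str, list] = {s: [] for s in TWOD_SCORES}
    for k in range(5):
        clusters, _ = simulate_pattern(
            SimConfig(pattern="csr", density=dens, miss_rate=0.0,
                      jitter_sigma=0.0, extent=extent, seed=seed * 880 + 21 + k)
        )
        net = co.reconstruct_network(clusters, "delaunay", co.NODE_LINK_RANGE)
        for s, wm in field_window_means(net).items():
            null_vals[s].extend(wm[np.isfinite(wm)])
    thresholds = {
        s: float(np.percentile(v, 95.0)) if v else np.inf
        for s, v in null_vals.items()
    }

    sums: dict[str, list[float]] = {s: [] for s in TWOD_SCORES}
    for k in range(n_seeds):
        island = SimConfig(pattern="2d_hex", extent=extent, seed=seed * 700 + k)
        background = SimConfig(pattern=background_pattern, extent=extent,
                               seed=seed * 700 + 350 + k)
        clusters, truth = make_composite(island, background, boundary_seed=seed * 17 + k)
        net = co.reconstruct_network(clusters, "delaunay", co.NODE_LINK_RANGE)
        for s, win in field_window_means(net).items():
            pm = accumulate_window_means(win, mask.grid.shape, grid)
            pred = np.where(np.isfinite(pm), pm > thresholds[s], False)
            f1, _, _ = f1_metric(pred, truth.island_mask)
            sums[s].append(f1)
    return {s: float(np.mean(v)) for s, v in sums.items()}


# -------------------------------------------------- midpoint benchmarks


def _hex_island_sets(seed: int, extent):
    """Node (Set 1), link-midpoint (Set 2) and inferred-node (Set 3)
    versions of one hex-island-on-CSR composite, plus the island mask."""
    grid = WindowGrid()
    shape = grid.n_pixels(extent)
    _, truth0 = simulate_pattern(
        SimConfig(pattern="2d_hex", extent=extent, seed=seed, jitter_sigma=0.0)
    )
    net = truth0.true_network
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))

    from .simgen import _boundary_mask

    mask = _boundary_mask(shape, np.random.default_rng(seed + 2000), 1000.0 / 256.0, 2)
    if not 0.2 <= mask.mean() <= 0.8:
        mask = ~mask

    def clip(points):
        ri = np.clip((points[:, 1] / GRID_PITCH).astype(int), 0, shape[0] - 1)
        ci = np.clip((points[:, 0] / GRID_PITCH).astype(int), 0, shape[1] - 1)
        return points[mask[ri, ci]]

    def with_background(points, role):
        area = (extent[0] / 1000.0) * (extent[1] / 1000.0)
        dens = len(points) / (mask.mean() * area)
        n_bg = rng.poisson(dens * (1 - mask.mean()) * area)
        bg = np.column_stack(
            [rng.uniform(0, extent[0], n_bg), rng.uniform(0, extent[1], n_bg)]
        )
        ri = np.clip((bg[:, 1] / GRID_PITCH).astype(int), 0, shape[0] - 1)
        ci = np.clip((bg[:, 0] / GRID_PITCH).astype(int), 0, shape[1] - 1)
        bg = bg[~mask[ri, ci]]
        return ClusterSet(np.vstack([points, bg]), role=role)

    jitter = lambda pts: pts + rng.normal(0, 10.0, pts.shape)
    nodes = clip(jitter(net.nodes.copy()))
    mids = clip(jitter(net.link_midpoints.copy()))
    set1 = with_background(nodes, "node")
    set2 = with_background(mids, "midpoint")
    set3 = ClusterSet(infer_nodes(set2).predicted_nodes, role="node")
    return set1, set2, set3, mask


def midpoint_pipeline_comparison(
    n_seeds: int = 3, seed: int = 0, extent=(4096.0, 4096.0)
) -> dict[str, float]:
    """Connectivity-module F1 on node-labeled (Set 1), midpoint-labeled
    (Set 2) and inferred-node (Set 3) hex-island composites."""
    mask_full = locio.full_mask(extent)
    sums = {"set1_nodes": [], "set2_midpoints": [], "set3_inferred": []}
    for k in range(n_seeds):
        s1, s2, s3, island = _hex_island_sets(seed * 800 + k, extent)
        for name, cs in (("set1_nodes", s1), ("set2_midpoints", s2), ("set3_inferred", s3)):
            link_range = co.link_range_for_role(cs.role)
            dens = co.quantize_density(co.measured_density(cs.centroids, mask_full))
            null = co.null_threshold(dens, link_range=link_range, seed=seed + 3)
            maps = co.connectivity_heatmap(cs, mask_full, link_range=link_range)
            pred = co.segment_network(
                maps.pixel_maps["triangle_area_sum"], null
            )
            f1, _, _ = f1_metric(pred, island)
            sums[name].append(f1)
    return {k: float(np.mean(v)) for k, v in sums.items()}


def midpoint_node_recovery(seed: int = 2, extent=(4000.0, 4000.0)) -> float:
    """Fraction of interior lattice nodes recovered within the merge radius
    from unperturbed link midpoints."""
    from scipy.spatial import cKDTree

    _, truth = simulate_pattern(
        SimConfig(pattern="2d_hex", jitter_sigma=0.0, rotation_deg=0.0,
                  seed=seed, extent=extent)
    )
    net = truth.true_network
    asm = infer_nodes(ClusterSet(net.link_midpoints, role="midpoint"))
    deg = np.bincount(net.links.ravel(), minlength=net.n_nodes)
    interior = net.nodes[deg == 3]
    dist, _ = cKDTree(asm.predicted_nodes).query(interior)
    return float((dist <= 50.0).mean())


# ------------------------------------------------- four-state benchmark


def quadrant_composite(seed: int, extent_nm: float = 8192.0):
    """Four-quadrant field covering all four organizational states.

    The disordered quadrant is a heavily jittered honeycomb (20 nm
    centroid jitter, so the link-length spread is comparable to the
    link-range half-width) with full labeling: a disordered *network*
    must remain connective — spacings stay mostly physical while lattice
    regularity is destroyed.  A thinned jittered lattice would instead be
    a borderline non-network region and make the truth label itself
    ambiguous."""
    half = extent_nm / 2
    n_half = int(half / GRID_PITCH)
    labels = np.zeros((2 * n_half, 2 * n_half), dtype=np.uint8)
    specs = [
        ("1d_periodic", {}, (0, 0), LABEL_1D),
        ("2d_hex", {}, (0, 1), LABEL_2D),
        ("2d_hex", {"jitter_sigma": 20.0, "miss_rate": 0.0}, (1, 0), LABEL_DISORDERED),
        ("csr", {"density": pattern_density(SimConfig(pattern="2d_hex"))},
         (1, 1), LABEL_NON_NETWORK),
    ]
    pts = []
    for k, (pat, kw, (qi, qj), lab) in enumerate(specs):
        cfg = SimConfig(pattern=pat, extent=(half, half), seed=seed * 10 + k, **kw)
        clusters, _ = simulate_pattern(cfg)
        pts.append(clusters.centroids + np.array([qj * half, qi * half]))
        labels[qi * n_half:(qi + 1) * n_half, qj * n_half:(qj + 1) * n_half] = lab
    return ClusterSet(np.vstack(pts)), labels


def four_state_f1(n_seeds: int = 5, seed: int = 0) -> dict[str, float]:
    """Mean per-state F1 of the full pipeline on quadrant composites."""
    from .pipeline_eval import PipelineConfig, run_classinet

    names = {
        LABEL_1D: "oned_periodic", LABEL_2D: "twod_ordered",
        LABEL_DISORDERED: "disordered", LABEL_NON_NETWORK: "non_network",
    }
    sums: dict[str, list[float]] = {v: [] for v in names.values()}
    for k in range(n_seeds):
        clusters, truth = quadrant_composite(seed * 50 + k + 1)
        res = run_classinet(clusters, PipelineConfig(seed=seed))
        for code, name in names.items():
            f1, _, _ = f1_metric(res.label_grid == code, truth == code)
            sums[name].append(f1)
    return {k: float(np.mean(v)) for k, v in sums.items()}
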