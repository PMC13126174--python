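"""Four-state segmentation pipeline and evaluation utilities.

The pipeline applies the three classifiers sequentially: (1) the
connectivity classifier separates network from non-network pixels against
a density-matched CSR null; (2) the 1D classifier segments 1D periodic
domains inside the network mask; (3) the 2D classifier scores the
remaining network pixels; (4) residual network pixels are labeled
disordered.  The result is a per-256-nm-pixel label map over the cellular
area, a partition by construction.

Evaluation helpers: pixelwise F1 (harmonic mean of precision and recall),
k-nearest-neighbor distances, actin stress-fiber detection in conventional
fluorescence images, and spatial statistics of segmentation states
relative to the nearest fiber (state fraction vs distance, relative
orientation of the 1D periodicity axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from . import connectivity as conn
from . import locio, periodic1d, regular2d
from .regular2d import LDAWeights
from .structures import (
    LABEL_1D,
    LABEL_2D,
    LABEL_DISORDERED,
    LABEL_NON_NETWORK,
    LABEL_OUTSIDE,
    CellMask,
    ClusterSet,
    LocalizationTable,
    WindowGrid,
)


@dataclass
class PipelineConfig:
    """All thresholds and ranges of one pipeline run (defaults are the
    standard spectrin-lattice operating point)."""

    role: str = "node"                                  # node | midpoint
    link_range: tuple[float, float] | None = None       # None -> by role
    metric: str = "triangle_area_sum"
    band_nm: tuple[float, float] = (160.0, 220.0)
    seed_thr: float = 0.6
    grow_thr: float = 0.45
    dtheta_max_deg: float = 15.0
    dd_max_nm: float = 10.0
    min_region_px: int = 4
    null_reps: int = 100
    null_percentile: float = 95.0
    render_pixel_nm: float = 16.0
    extent: tuple[float, float] | None = None           # None -> from data
    seed: int = 0

    def resolved_link_range(self) -> tuple[float, float]:
        if self.link_range is not None:
            return tuple(self.link_range)
        return conn.link_range_for_role(self.role)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg


@dataclass
class SegmentationResult:
    label_grid: np.ndarray                  # per-256-nm-pixel label code
    mask: CellMask
    conn_maps: conn.ScoreMaps
    null: conn.NullModel
    network_mask: np.ndarray
    oned_maps: periodic1d.OrientationPeriodMap
    oned_mask: np.ndarray
    twod_map: np.ndarray
    twod_threshold: float
    twod_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


_NULL_CACHE: dict[tuple, conn.NullModel] = {}
_LOCAL_NULL_CACHE: dict[tuple, dict] = {}


def _cached_null(density_bin, grid, cfg: PipelineConfig) -> conn.NullModel:
    key = (
        round(density_bin, 6),
        grid.window_px,
        cfg.resolved_link_range(),
        cfg.null_reps,
        cfg.null_percentile,
        cfg.seed,
    )
    if key not in _NULL_CACHE:
        _NULL_CACHE[key] = conn.null_threshold(
            density_bin,
            grid,
            n_reps=cfg.null_reps,
            percentile=cfg.null_percentile,
            seed=cfg.seed,
            link_range=cfg.resolved_link_range(),
        )
    return _NULL_CACHE[key]


def run_classinet(
    data: ClusterSet | LocalizationTable,
    config: PipelineConfig | None = None,
    mask: CellMask | None = None,
    lda_weights: LDAWeights | None = None,
    grid: WindowGrid | None = None,
) -> SegmentationResult:
    """Run the full four-state segmentation.

    ``data`` is either a cluster set (centroids are analyzed directly) or
    a localization table (rendered, cluster-detected, and the cellular
    area determined from the rendering).  For cluster input the cellular
    mask defaults to the full extent unless supplied.
    """
    cfg = config or PipelineConfig()
    grid = grid or WindowGrid()

    if isinstance(data, LocalizationTable):
        img = locio.render_image(data, cfg.render_pixel_nm, cfg.extent)
        clusters = locio.detect_clusters(img, data)
        if mask is None:
            mask = locio.cellular_area(img, grid=grid)
    else:
        clusters = data
        extent = cfg.extent
        if extent is None:
            if len(clusters) == 0:
                extent = (grid.pitch, grid.pitch)
            else:
                extent = (
                    float(clusters.centroids[:, 0].max()) + 1e-9,
                    float(clusters.centroids[:, 1].max()) + 1e-9,
                )
        img = locio.render_clusters(clusters, cfg.render_pixel_nm, extent)
        if mask is None:
            mask = locio.full_mask(extent, grid)

    role = cfg.role if cfg.role else clusters.role
    link_range = cfg.resolved_link_range()
    shape = mask.grid.shape
    empty = np.zeros(shape, dtype=bool)

    if not mask.grid.any():
        label = np.full(shape, LABEL_OUTSIDE, dtype=np.uint8)
        null = conn.NullModel(0.0, {m: 0.0 for m in conn.METRICS})
        return SegmentationResult(
            label, mask,
            conn.ScoreMaps({}, {}, np.zeros((0, 2), int), grid), null,
            empty,
            periodic1d.OrientationPeriodMap(
                np.full(shape, np.nan), np.full(shape, np.nan),
                np.full(shape, np.nan), grid),
            empty, np.full(shape, np.nan), 0.0, empty,
            provenance={"warning": "empty cellular mask"},
        )

    # (1) connectivity: window-local density-matched nulls + binary mask
    density = conn.measured_density(clusters.centroids, mask)
    density_bin = conn.quantize_density(density)
    null = _cached_null(density_bin, grid, cfg)
    maps = conn.connectivity_heatmap(
        clusters, mask, grid, "delaunay", link_range, seed=cfg.seed
    )
    network_mask, local_thresholds = conn.segment_network_local(
        maps, mask, cfg.metric,
        n_reps=cfg.null_reps, percentile=cfg.null_percentile,
        seed=cfg.seed, link_range=link_range, cache=_LOCAL_NULL_CACHE,
    )

    # (2) 1D periodicity inside the network mask
    oned_maps = periodic1d.periodicity_maps(img, mask, grid, cfg.band_nm)
    oned_mask = periodic1d.segment_1d(
        oned_maps,
        mask=network_mask,
        seed_thr=cfg.seed_thr,
        grow_thr=cfg.grow_thr,
        dtheta_max=cfg.dtheta_max_deg,
        dd_max=cfg.dd_max_nm,
        min_region_px=cfg.min_region_px,
    )

    # (3) 2D regularity on network minus 1D
    weights = lda_weights or regular2d.default_lda_weights(cfg.seed)
    net = conn.reconstruct_network(clusters, "delaunay", link_range, seed=cfg.seed)
    twod_map = regular2d.regularity2d_heatmap(net, mask, grid, weights)
    twod_thr = regular2d.regularity2d_null_threshold(
        density_bin, grid, weights, link_range,
        n_reps=cfg.null_reps, percentile=cfg.null_percentile, seed=cfg.seed,
    )
    remaining = network_mask & ~oned_mask
    twod_mask = regular2d.segment_2d(twod_map, twod_thr) & remaining

    # (4) residual network -> disordered; assemble the partition
    label = np.full(shape, LABEL_OUTSIDE, dtype=np.uint8)
    label[mask.grid] = LABEL_NON_NETWORK
    label[network_mask & mask.grid] = LABEL_DISORDERED
    label[twod_mask & mask.grid] = LABEL_2D
    label[oned_mask & mask.grid] = LABEL_1D

    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "role": role,
        "link_range": list(link_range),
        "density_per_um2": density,
        "density_bin": density_bin,
        "connectivity_threshold_global": null.thresholds[cfg.metric],
        "connectivity_thresholds_by_density": {
            str(k): v for k, v in sorted(local_thresholds.items())
        },
        "twod_threshold": twod_thr,
        "n_clusters": len(clusters),
    }
    return SegmentationResult(
        label, mask, maps, null, network_mask,
        oned_maps, oned_mask, twod_map, twod_thr, twod_mask, provenance,
    )


# ------------------------------------------------------------- evaluation


def f1_metric(pred: np.ndarray, truth: np.ndarray):
    """Pixelwise F1 = 2PR/(P+R) with precision and recall; 0 when P+R=0."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth grids must share a shape")
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return f1, precision, recall


def knn_nnd(points: ClusterSet | np.ndarray, k: int = 3) -> np.ndarray:
    """Exact first..k-th nearest-neighbor Euclidean distances per point,
    shape (N, k)."""
    pts = (
        points.centroids if isinstance(points, ClusterSet) else
        np.asarray(points, dtype=float).reshape(-1, 2)
    )
    if len(pts) < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k}")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k + 1)
    return d[:, 1:]


# ---------------------------------------------------------- stress fibers


@dataclass
class FiberSet:
    masks: np.ndarray               # (F, rows, cols) boolean
    orientation: np.ndarray         # degrees in [0, 180), per fiber
    area_um2: np.ndarray
    eccentricity: np.ndarray
    major_axis_um: np.ndarray
    pixel_size: float               # nm

    def __len__(self) -> int:
        return len(self.orientation)

    def combined_mask(self) -> np.ndarray:
        if len(self) == 0:
            return np.zeros(self.masks.shape[1:] if self.masks.ndim == 3 else (0, 0), bool)
        return self.masks.any(axis=0)


def detect_fibers(
    img: np.ndarray,
    pixel_size: float,
    global_threshold: float = 20.0,
    adaptive_block: int = 111,
    adaptive_offset: float = 2.0,
    min_eccentricity: float = 0.8,
    min_area_px: float = 250.0,
    min_major_axis_um: float = 2.0,
) -> FiberSet:
    """Dual-threshold stress-fiber segmentation of a conventional
    fluorescence image.

    Normalize to 0-255, blur with a 5x5 Gaussian, combine a global
    intensity threshold (>20) with local adaptive thresholding (111-pixel
    Gaussian window, offset 2), close (3x3) then open (7x7), and keep
    elongated components (eccentricity > 0.8, area and major-axis floors).
    Fiber orientation comes from the component's second moments.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.filters import threshold_local
    from skimage.measure import label as cc_label, regionprops
    from skimage.morphology import closing, footprint_rectangle, opening

    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if img.max() > img.min():
        norm = 255.0 * (img - img.min()) / (img.max() - img.min())
    else:
        return FiberSet(
            np.zeros((0,) + img.shape, bool), np.zeros(0), np.zeros(0),
            np.zeros(0), np.zeros(0), pixel_size,
        )
    blurred = gaussian_filter(norm, sigma=5.0 / 4.0)   # 5x5 kernel ~ sigma 1.25
    block = min(adaptive_block, (min(img.shape) // 2) * 2 - 1)
    block = max(block, 3)
    local_thr = threshold_local(blurred, block_size=block, method="gaussian")
    binary = (blurred > global_threshold) & (blurred > local_thr - adaptive_offset)
    binary = closing(binary, footprint_rectangle((3, 3)))
    binary = opening(binary, footprint_rectangle((7, 7)))

    labels = cc_label(binary, connectivity=2)
    px_um = pixel_size / 1000.0
    masks, oris, areas, eccs, majors = [], [], [], [], []
    for prop in regionprops(labels):
        area_um2 = prop.area * px_um**2
        major_um = prop.axis_major_length * px_um
        if (
            prop.eccentricity > min_eccentricity
            and prop.area > min_area_px
            and major_um >= min_major_axis_um
        ):
            # regionprops orientation: angle of the major axis from the row
            # (y) axis, counterclockwise; convert to angle from +x in image
            # coordinates (y down), folded to [0, 180)
            theta = (90.0 - np.degrees(prop.orientation)) % 180.0
            masks.append(labels == prop.label)
            oris.append(theta)
            areas.append(area_um2)
            eccs.append(prop.eccentricity)
            majors.append(major_um)
    if masks:
        masks_arr = np.stack(masks)
    else:
        masks_arr = np.zeros((0,) + img.shape, bool)
    return FiberSet(
        masks_arr,
        np.asarray(oris), np.asarray(areas), np.asarray(eccs),
        np.asarray(majors), pixel_size,
    )


# -------------------------------------------------------- fiber proximity


def fiber_context(
    label_grid: np.ndarray,
    fibers: FiberSet,
    theta_grid: np.ndarray,
    grid: WindowGrid | None = None,
    bin_nm: float = 256.0,
):
    """State fractions vs distance to the nearest stress fiber, and the
    distribution of |theta_pixel - theta_fiber| for 1D pixels.

    ``label_grid`` and ``theta_grid`` live on the 256 nm grid; fiber masks
    are resampled onto it (registration is assumed: both modalities share
    the coordinate frame).  Distances are measured between pixel centers;
    relative angles are folded to [0, 90] since both axes are undirected.
    Returns (curves DataFrame, relative-angle array in degrees).
    """
    grid = grid or WindowGrid()
    if len(fibers) == 0:
        raise ValueError("fiber context requires at least one detected fiber")
    shape = label_grid.shape

    # resample fiber masks to the classification grid
    factor = fibers.pixel_size / grid.pitch
    fiber_grid = np.zeros(shape, dtype=int)   # 0 = none, else fiber idx + 1
    for f_idx in range(len(fibers)):
        rows, cols = np.nonzero(fibers.masks[f_idx])
        ri = np.clip((rows * factor).astype(int), 0, shape[0] - 1)
        ci = np.clip((cols * factor).astype(int), 0, shape[1] - 1)
        fiber_grid[ri, ci] = f_idx + 1
    if not (fiber_grid > 0).any():
        raise ValueError("fiber masks do not overlap the analysis grid")

    dist_px, (ir, ic) = distance_transform_edt(
        fiber_grid == 0, return_indices=True
    )
    dist_nm = dist_px * grid.pitch
    nearest_fiber = fiber_grid[ir, ic] - 1

    cellular = label_grid != LABEL_OUTSIDE
    states = {
        "non_network": LABEL_NON_NETWORK,
        "oned_periodic": LABEL_1D,
        "twod_ordered": LABEL_2D,
        "disordered": LABEL_DISORDERED,
    }
    max_d = dist_nm[cellular].max() if cellular.any() else 0.0
    edges = np.arange(0.0, max_d + bin_nm, bin_nm)
    rows_out = []
    for k in range(len(edges) - 1):
        sel = cellular & (dist_nm >= edges[k]) & (dist_nm < edges[k + 1])
        n = int(sel.sum())
        if n == 0:
            continue
        row = {"distance_nm": 0.5 * (edges[k] + edges[k + 1]), "n_pixels": n}
        for name, code in states.items():
            row[f"frac_{name}"] = float((label_grid[sel] == code).sum()) / n
        rows_out.append(row)
    curves = pd.DataFrame(rows_out)

    oned = (label_grid == LABEL_1D) & np.isfinite(theta_grid)
    rel = np.zeros(int(oned.sum()))
    for i, (ri, ci) in enumerate(np.argwhere(oned)):
        th_f = fibers.orientation[nearest_fiber[ri, ci]]
        diff = abs(theta_grid[ri, ci] - th_f) % 180.0
        rel[i] = min(diff, 180.0 - diff)
    return curves, rel
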