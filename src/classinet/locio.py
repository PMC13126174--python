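"""Localization-table I/O, image rendering, cluster detection and cellular
area determination.

Rendering bins localizations into a 2D histogram at 16 nm/pixel — on the
order of the localization precision (~10-20 nm) and well below the Nyquist
limit (~47.5 nm) for the finest periodic feature of interest (~95 nm).
Cluster detection is a two-pass, coarse-to-fine strategy: fast multiscale
blob detection on the rendered image proposes candidate regions, then
density-based clustering of the raw localizations inside each candidate
defines final cluster membership and centroids at point-cloud accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile
from skimage.feature import blob_log
from skimage.measure import label as cc_label
from sklearn.cluster import HDBSCAN

from .structures import (
    CellMask,
    ClusterSet,
    LocalizationTable,
    RenderedImage,
    WindowGrid,
)

DEFAULT_DIALECT = {
    "x": "x_nm",
    "y": "y_nm",
    "frame": "frame",
    "precision": "precision_nm",
    "photons": "photons",
}


class FormatError(ValueError):
    """Raised when an input table cannot be interpreted."""


def read_localizations(path, dialect: dict | None = None) -> LocalizationTable:
    """Read a delimited localization table (CSV/TSV with header).

    ``dialect`` maps canonical field names (x, y, frame, precision, photons)
    to the column names used in the file; defaults to x_nm/y_nm/frame/
    precision_nm/photons.  Rows with non-finite coordinates are dropped and
    counted in ``n_dropped``.  An empty file yields an empty table.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        return LocalizationTable(x=np.zeros(0), y=np.zeros(0))
    except Exception:
        # delimiter sniffing fails on degenerate single-column content
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return LocalizationTable(x=np.zeros(0), y=np.zeros(0))
    if len(df) == 0:
        return LocalizationTable(x=np.zeros(0), y=np.zeros(0))
    for key in ("x", "y"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"required column {cols[key]!r} ({key}) not found in {path}"
            )
    x = pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())

    def _opt(key, dtype=float):
        name = cols.get(key)
        if name and name in df.columns:
            return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=dtype)[keep]
        return None

    return LocalizationTable(
        x=x[keep],
        y=y[keep],
        frame=_opt("frame"),
        precision=_opt("precision"),
        photons=_opt("photons"),
        n_dropped=n_dropped,
    )


def write_localizations(path, locs: LocalizationTable) -> None:
    data = {"x_nm": locs.x, "y_nm": locs.y}
    if locs.frame is not None:
        data["frame"] = locs.frame
    if locs.precision is not None:
        data["precision_nm"] = locs.precision
    if locs.photons is not None:
        data["photons"] = locs.photons
    pd.DataFrame(data).to_csv(path, index=False)


def read_clusters(path) -> ClusterSet:
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} not found in {path}")
    role = "node"
    if "role" in df.columns and len(df):
        role = str(df["role"].iloc[0])
    loc_count = (
        df["loc_count"].to_numpy(dtype=int) if "loc_count" in df.columns else None
    )
    return ClusterSet(
        centroids=df[["x_nm", "y_nm"]].to_numpy(dtype=float),
        loc_count=loc_count,
        role=role,
    )


def write_clusters(path, clusters: ClusterSet) -> None:
    pd.DataFrame(
        {
            "x_nm": clusters.centroids[:, 0],
            "y_nm": clusters.centroids[:, 1],
            "loc_count": clusters.loc_count,
            "role": clusters.role,
        }
    ).to_csv(path, index=False)


def write_image(path, img: RenderedImage) -> None:
    tifffile.imwrite(path, img.pixels.astype(np.float32))


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8))


def render_image(
    locs: LocalizationTable,
    pixel_size: float = 16.0,
    extent: tuple[float, float] | None = None,
) -> RenderedImage:
    """Bin localizations into a 2D histogram (half-open bins).

    ``extent`` is the (width, height) of the field in nm; by default it is
    the smallest extent containing every localization.  Total intensity
    equals the number of binned localizations.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if extent is None:
        if len(locs) == 0:
            extent = (pixel_size, pixel_size)
        else:
            extent = (float(locs.x.max()) + 1e-9, float(locs.y.max()) + 1e-9)
    cols = max(1, int(np.ceil(extent[0] / pixel_size)))
    rows = max(1, int(np.ceil(extent[1] / pixel_size)))
    if len(locs) == 0:
        return RenderedImage(np.zeros((rows, cols)), pixel_size)
    ci = np.floor(locs.x / pixel_size).astype(int)
    ri = np.floor(locs.y / pixel_size).astype(int)
    keep = (ci >= 0) & (ci < cols) & (ri >= 0) & (ri < rows)
    img = np.zeros((rows, cols))
    np.add.at(img, (ri[keep], ci[keep]), 1.0)
    return RenderedImage(img, pixel_size)


def render_points(
    points: np.ndarray,
    pixel_size: float = 16.0,
    extent: tuple[float, float] | None = None,
) -> RenderedImage:
    """Render bare (x, y) points (e.g. cluster centroids) as unit counts."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return render_image(
        LocalizationTable(x=pts[:, 0], y=pts[:, 1]), pixel_size, extent
    )


def render_clusters(
    clusters: ClusterSet,
    pixel_size: float = 16.0,
    extent: tuple[float, float] | None = None,
    kernel_sigma: float = 12.0,
) -> RenderedImage:
    """Render cluster centroids as 2D Gaussian peaks.

    This is the expectation of a STORM rendering of the cluster set: each
    molecular cluster appears as an isotropic Gaussian of width
    ``kernel_sigma`` (default 12 nm, the typical localization precision).
    Used when the pipeline receives centroids rather than localizations,
    so that the spectral scores see the same image statistics as on
    localization-rendered data.
    """
    from scipy.ndimage import gaussian_filter

    img = render_points(clusters.centroids, pixel_size, extent)
    img.pixels = gaussian_filter(img.pixels, kernel_sigma / pixel_size)
    return img


def enhance_contrast(pixels: np.ndarray, clip_percentile: float = 99.9) -> np.ndarray:
    """Percentile normalization to [0, 1], clipping at the given percentile."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0 or pixels.max() <= 0:
        return np.zeros_like(pixels)
    hi = np.percentile(pixels[pixels > 0], clip_percentile)
    if hi <= 0:
        hi = pixels.max()
    return np.clip(pixels / hi, 0.0, 1.0)


def detect_clusters(
    img: RenderedImage,
    locs: LocalizationTable,
    search_radius: float = 50.0,
    min_cluster_size: int = 10,
    min_samples: int = 5,
    num_sigma: int = 20,
    blob_threshold: float = 0.1,
) -> ClusterSet:
    """Two-pass cluster detection.

    Pass 1: Laplacian-of-Gaussian blob detection on the contrast-enhanced
    rendering, scanning 20 logarithmically spaced scales at threshold 0.1.
    Pass 2: for each candidate, the raw localizations within a 50 nm search
    radius are clustered with HDBSCAN (min_cluster_size=10, min_samples=5);
    cluster centers are the mean of member localizations and outliers are
    discarded.  Duplicate detections of the same cluster (blobs whose point
    clouds resolve to the same center) are merged.
    """
    if len(locs) == 0:
        return ClusterSet(np.zeros((0, 2)))
    w, h = img.extent
    if locs.x.max() > w + img.pixel_size or locs.y.max() > h + img.pixel_size:
        raise ValueError("rendered image geometry does not cover the localizations")

    enhanced = enhance_contrast(img.pixels)
    blobs = blob_log(
        enhanced,
        min_sigma=1.0,
        max_sigma=4.0,
        num_sigma=num_sigma,
        threshold=blob_threshold,
        log_scale=True,
    )
    if len(blobs) == 0:
        return ClusterSet(np.zeros((0, 2)))

    from scipy.spatial import cKDTree

    tree = cKDTree(locs.xy)
    centers: list[np.ndarray] = []
    ps = img.pixel_size
    for row, col, _sigma in blobs:
        cx = (col + 0.5) * ps
        cy = (row + 0.5) * ps
        idx = tree.query_ball_point([cx, cy], search_radius)
        if len(idx) < min_cluster_size:
            continue
        pts = np.ascontiguousarray(locs.xy[idx])
        # a candidate region usually holds a single cluster; the root of the
        # condensed tree must therefore be selectable
        labels = HDBSCAN(
            min_cluster_size=min_cluster_size,
            min_samples=min_samples,
            allow_single_cluster=True,
            copy=True,
        ).fit_predict(pts)
        for lab in np.unique(labels):
            if lab < 0:
                continue
            c = pts[labels == lab].mean(axis=0)
            # one re-centering pass: the first ball is centered on the
            # pixel-quantized blob and truncates the cluster asymmetrically
            idx2 = tree.query_ball_point(c, search_radius)
            if len(idx2) >= min_cluster_size:
                c = locs.xy[idx2].mean(axis=0)
            centers.append(c)
    if not centers:
        return ClusterSet(np.zeros((0, 2)))
    centers_arr = np.asarray(centers)
    # merge duplicates from overlapping candidate regions
    ctree = cKDTree(centers_arr)
    merged: list[np.ndarray] = []
    used = np.zeros(len(centers_arr), dtype=bool)
    for i in range(len(centers_arr)):
        if used[i]:
            continue
        group = ctree.query_ball_point(centers_arr[i], 20.0)
        group = [g for g in group if not used[g]]
        for g in group:
            used[g] = True
        merged.append(centers_arr[group].mean(axis=0))
    merged_arr = np.asarray(merged)
    counts = np.array(
        [len(tree.query_ball_point(c, search_radius)) for c in merged_arr], dtype=int
    )
    return ClusterSet(centroids=merged_arr, loc_count=counts, role="node")


def cellular_area(
    img: RenderedImage,
    intensity_threshold: float = 10.0,
    min_area_nm2: float = 5000.0,
    grid: WindowGrid | None = None,
) -> CellMask:
    """Determine the high-confidence cellular analysis area.

    The rendering is first cleaned at its native pixel size by removing
    connected intensity-support components smaller than ``min_area_nm2``
    (spurious isolated detections).  The cleaned intensity is then summed
    onto the 256 nm grid, a 4x4-pixel sliding window (step 1) computes
    total intensity per window, and a grid pixel belongs to the cell if at
    least one complete window covering it reaches ``intensity_threshold``.
    """
    grid = grid or WindowGrid()
    pixels = img.pixels.copy()
    # fine-scale contour filter on the rendering
    support = pixels > 0
    if support.any():
        labels = cc_label(support, connectivity=2)
        areas = np.bincount(labels.ravel())
        px_area = img.pixel_size**2
        small = np.flatnonzero(areas * px_area < min_area_nm2)
        if small.size:
            pixels[np.isin(labels, small[small > 0])] = 0.0

    # bin onto the classification grid
    factor = int(round(grid.pitch / img.pixel_size))
    rows, cols = pixels.shape
    grows = int(np.ceil(rows / factor))
    gcols = int(np.ceil(cols / factor))
    padded = np.zeros((grows * factor, gcols * factor))
    padded[:rows, :cols] = pixels
    coarse = padded.reshape(grows, factor, gcols, factor).sum(axis=(1, 3))

    w = grid.window_px
    if grows < w or gcols < w:
        # field smaller than one window: single all-or-nothing decision
        ok = coarse.sum() >= intensity_threshold
        return CellMask(np.full((grows, gcols), ok, dtype=bool), pitch=grid.pitch)
    # exact window sums (window w, step 1) via a summed-area table
    cs = np.cumsum(np.cumsum(np.pad(coarse, ((1, 0), (1, 0))), axis=0), axis=1)
    win = (
        cs[w:, w:] - cs[:-w, w:] - cs[w:, :-w] + cs[:-w, :-w]
    )  # (grows-w+1, gcols-w+1) window totals
    keep = win >= intensity_threshold
    mask = np.zeros((grows, gcols), dtype=bool)
    for i in range(keep.shape[0]):
        for j in range(keep.shape[1]):
            if keep[i, j]:
                mask[i : i + w, j : j + w] = True
    return CellMask(mask, pitch=grid.pitch)


def full_mask(extent: tuple[float, float], grid: WindowGrid | None = None) -> CellMask:
    """Mask covering the whole extent (used for simulated fields)."""
    grid = grid or WindowGrid()
    return CellMask(np.ones(grid.n_pixels(extent), dtype=bool), pitch=grid.pitch)
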