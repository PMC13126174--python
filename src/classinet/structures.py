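"""Core in-memory containers shared across the analysis modules.

All coordinates are in nanometres with the origin at the top-left of the
field of view; x increases to the right (image columns), y increases
downward (image rows).  Pixel indices are 0-based and bins are half-open,
``i*ps <= x < (i+1)*ps``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: classification-grid pitch in nm (the native resolution of all label maps)
GRID_PITCH = 256.0
#: analysis window, in grid pixels (4 px -> 1024 nm)
WINDOW_PX = 4
#: default rendering pixel size in nm
RENDER_PX = 16.0

# label codes used by segmentation maps
LABEL_OUTSIDE = 0
LABEL_NON_NETWORK = 1
LABEL_1D = 2
LABEL_2D = 3
LABEL_DISORDERED = 4

LABEL_NAMES = {
    LABEL_OUTSIDE: "outside",
    LABEL_NON_NETWORK: "non_network",
    LABEL_1D: "oned_periodic",
    LABEL_2D: "twod_ordered",
    LABEL_DISORDERED: "disordered",
}


@dataclass
class LocalizationTable:
    """Raw SMLM detections.

    Parameters
    ----------
    x, y : arrays of nm coordinates (finite, >= 0)
    frame : optional integer frame indices
    precision : optional per-localization precision in nm
    photons : optional photon counts
    n_dropped : rows removed on ingest because of non-finite coordinates
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray | None = None
    precision: np.ndarray | None = None
    photons: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class RenderedImage:
    """2D histogram rendering of a localization table."""

    pixels: np.ndarray           # (rows, cols) nonnegative intensities
    pixel_size: float = RENDER_PX
    origin: tuple[float, float] = (0.0, 0.0)   # nm offset of pixel (0, 0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.pixels = np.asarray(self.pixels, dtype=float)

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in nm."""
        r, c = self.pixels.shape
        return (c * self.pixel_size, r * self.pixel_size)


@dataclass
class ClusterSet:
    """Centroids of molecular clusters (the unit of network reconstruction)."""

    centroids: np.ndarray          # (N, 2) [x, y] nm
    loc_count: np.ndarray | None = None
    role: str = "node"             # "node" | "midpoint"

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.loc_count is None:
            self.loc_count = np.ones(len(self.centroids), dtype=int)
        else:
            self.loc_count = np.asarray(self.loc_count, dtype=int)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class NetworkGraph:
    """Undirected node-link graph with its smallest closed three-link cycles."""

    nodes: np.ndarray                       # (N, 2) [x, y] nm
    links: np.ndarray                       # (L, 2) int, i < j
    triangles: np.ndarray                   # (T, 3) int, sorted
    method: str = "delaunay"                # "range" | "delaunay"
    link_range: tuple[float, float] = (160.0, 220.0)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        self.links = np.asarray(self.links, dtype=int).reshape(-1, 2)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def link_lengths(self) -> np.ndarray:
        if len(self.links) == 0:
            return np.zeros(0)
        d = self.nodes[self.links[:, 0]] - self.nodes[self.links[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def link_midpoints(self) -> np.ndarray:
        if len(self.links) == 0:
            return np.zeros((0, 2))
        return 0.5 * (self.nodes[self.links[:, 0]] + self.nodes[self.links[:, 1]])

    def triangle_areas(self) -> np.ndarray:
        if len(self.triangles) == 0:
            return np.zeros(0)
        a = self.nodes[self.triangles[:, 0]]
        b = self.nodes[self.triangles[:, 1]]
        c = self.nodes[self.triangles[:, 2]]
        return 0.5 * np.abs(
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
            - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        )

    def triangle_centroids(self) -> np.ndarray:
        if len(self.triangles) == 0:
            return np.zeros((0, 2))
        return self.nodes[self.triangles].mean(axis=1)

    def to_json_dict(self) -> dict:
        return {
            "nodes": self.nodes.tolist(),
            "links": self.links.tolist(),
            "triangles": self.triangles.tolist(),
            "method": self.method,
            "link_range": list(self.link_range),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "NetworkGraph":
        return cls(
            nodes=np.asarray(d["nodes"], dtype=float).reshape(-1, 2),
            links=np.asarray(d["links"], dtype=int).reshape(-1, 2),
            triangles=np.asarray(d["triangles"], dtype=int).reshape(-1, 3),
            method=d.get("method", "delaunay"),
            link_range=tuple(d.get("link_range", (160.0, 220.0))),
        )


@dataclass(frozen=True)
class WindowGrid:
    """Moving-window geometry on the 256 nm classification grid."""

    pitch: float = GRID_PITCH        # nm per grid pixel
    window_px: int = WINDOW_PX       # window edge, in grid pixels
    step_px: int = 1                 # window step, in grid pixels

    @property
    def window_nm(self) -> float:
        return self.pitch * self.window_px

    def n_pixels(self, extent: tuple[float, float]) -> tuple[int, int]:
        """(rows, cols) of the grid covering an (width, height) nm extent."""
        w, h = extent
        return (int(np.ceil(h / self.pitch)), int(np.ceil(w / self.pitch)))

    def window_origins(self, shape: tuple[int, int]):
        """Yield (row, col) grid indices of every complete window."""
        rows, cols = shape
        for i in range(0, rows - self.window_px + 1, self.step_px):
            for j in range(0, cols - self.window_px + 1, self.step_px):
                yield i, j

    def window_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) nm bounds of the window whose origin pixel is (i, j)."""
        x0 = j * self.pitch
        y0 = i * self.pitch
        return (x0, y0, x0 + self.window_nm, y0 + self.window_nm)


@dataclass
class CellMask:
    """Boolean cellular-area mask on the 256 nm grid."""

    grid: np.ndarray
    pitch: float = GRID_PITCH

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def area_um2(self) -> float:
        return float(self.grid.sum()) * (self.pitch / 1000.0) ** 2


def accumulate_window_means(
    window_values: np.ndarray, shape: tuple[int, int], grid: WindowGrid
) -> np.ndarray:
    """Spread per-window values back onto grid pixels as the mean over all
    complete windows covering each pixel.  NaN windows are skipped; pixels
    covered by no finite window come back NaN."""
    total = np.zeros(shape, dtype=float)
    count = np.zeros(shape, dtype=float)
    w = grid.window_px
    idx = 0
    for i, j in grid.window_origins(shape):
        v = window_values[idx]
        idx += 1
        if np.isfinite(v):
            total[i : i + w, j : j + w] += v
            count[i : i + w, j : j + w] += 1
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out
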