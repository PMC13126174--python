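"""1D periodicity quantification by windowed 2D FFT, and seed region
growing segmentation of 1D periodic domains.

Each 1024 nm analysis window of the rendered image is normalized,
multiplied with a 2D Hann window to limit spectral leakage, zero-padded
(2x per axis) and Fourier transformed.  The dominant point-symmetric peak
pair inside an annulus corresponding to real-space periods of 160-220 nm
gives the orientation theta and period d of the best-fitting 1D pattern;
the inverse FFT of the two retained peaks yields the corresponding
real-space grating image.  Five regularity scores are computed per
window; the integrated score combines the global and localized Pearson
correlations with a probabilistic OR,

    S = r_global + r_local - r_global * r_local,

after clipping negative correlations to zero, so S is in [0, 1] and is
monotone nondecreasing in each argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import rotate as nd_rotate
from skimage.feature import match_template

from .structures import (
    CellMask,
    RenderedImage,
    WindowGrid,
    accumulate_window_means,
)

PERIOD_BAND = (160.0, 220.0)


@dataclass
class WindowSpectrum:
    """Frequency-domain summary of one analysis window."""

    amplitudes: np.ndarray            # |FFT| of the padded window
    a_fft: float                      # dominant peak amplitude
    theta: float                      # degrees in [0, 180)
    d: float                          # period in nm
    peak_coords: tuple                # integer (row, col) of one peak


@dataclass
class Regularity1DScores:
    a_fft: float
    r_global: float
    r_proj: float
    r_local: float
    s_integrated: float


@dataclass
class OrientationPeriodMap:
    """Per-grid-pixel 1D regularity score, orientation and period."""

    score_grid: np.ndarray
    theta_grid: np.ndarray
    d_grid: np.ndarray
    grid: WindowGrid
    per_score_grids: dict | None = None   # other candidate scores, by name


def integrated_score(r_global: float, r_local: float) -> float:
    """Probabilistic-OR combination of the two correlations (inputs are
    clipped to [0, 1] first)."""
    a = min(max(float(r_global), 0.0), 1.0)
    b = min(max(float(r_local), 0.0), 1.0)
    return a + b - a * b


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2:
        return 0.0
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _annulus_mask(n: int, pixel_size: float, band: tuple[float, float]) -> np.ndarray:
    """Boolean mask of FFT bins whose real-space period lies in ``band``
    (fftshifted layout, DC at n//2)."""
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=pixel_size))
    fy, fx = np.meshgrid(freqs, freqs, indexing="ij")
    f = np.hypot(fx, fy)
    lo, hi = band
    return (f >= 1.0 / hi) & (f <= 1.0 / lo)


def _subpixel_peak(mag: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Sub-bin peak refinement by per-axis parabolic interpolation of the
    log magnitude (near-exact for smooth single-lobe peaks)."""
    r, c = peak

    def offset(vals: np.ndarray) -> float:
        L = np.log(np.maximum(vals, 1e-12))
        den = L[0] - 2.0 * L[1] + L[2]
        if den == 0:
            return 0.0
        return float(np.clip(0.5 * (L[0] - L[2]) / den, -0.5, 0.5))

    dr = dc = 0.0
    if 1 <= r < mag.shape[0] - 1:
        dr = offset(mag[r - 1 : r + 2, c])
    if 1 <= c < mag.shape[1] - 1:
        dc = offset(mag[r, c - 1 : c + 2])
    return float(r) + dr, float(c) + dc


def analyze_window_1d(
    window_img: np.ndarray | RenderedImage,
    pixel_size: float = 16.0,
    band: tuple[float, float] = PERIOD_BAND,
    pad_factor: int = 2,
    template_width_px: int = 6,
    template_periods: int = 3,
) -> tuple[WindowSpectrum | None, Regularity1DScores]:
    """Analyze one window (1024 nm -> 64x64 pixels at 16 nm).

    Returns ``(None, zero-scores)`` for an all-zero window (orientation and
    period are undefined there and flagged missing by the caller).
    """
    win = window_img.pixels if isinstance(window_img, RenderedImage) else window_img
    win = np.asarray(win, dtype=float)
    if win.size == 0 or win.std() == 0:
        return None, Regularity1DScores(0.0, 0.0, 0.0, 0.0, 0.0)

    n = win.shape[0]
    norm = (win - win.mean()) / win.std()
    hann = np.outer(np.hanning(n), np.hanning(n))
    tapered = norm * hann
    npad = n * pad_factor
    spec = np.fft.fftshift(np.fft.fft2(tapered, s=(npad, npad)))
    mag = np.abs(spec)
    ann = _annulus_mask(npad, pixel_size, band)
    if not ann.any():
        return None, Regularity1DScores(0.0, 0.0, 0.0, 0.0, 0.0)

    masked = np.where(ann, mag, 0.0)
    peak_flat = int(np.argmax(masked))
    pr, pc = np.unravel_index(peak_flat, masked.shape)
    center = npad // 2
    a_fft = float(mag[pr, pc])

    # sub-bin refinement of period/orientation
    rr, cc = _subpixel_peak(mag, (pr, pc))
    fy = (rr - center) / (npad * pixel_size)
    fx = (cc - center) / (npad * pixel_size)
    f = float(np.hypot(fx, fy))
    if f <= 0:
        return None, Regularity1DScores(a_fft, 0.0, 0.0, 0.0, 0.0)
    d = 1.0 / f
    theta = float(np.degrees(np.arctan2(fy, fx)) % 180.0)

    # grating: inverse FFT of the dominant symmetric integer-bin peak pair
    keep = np.zeros_like(spec)
    mr, mc = 2 * center - pr, 2 * center - pc   # point-symmetric partner
    keep[pr, pc] = spec[pr, pc]
    keep[mr % npad, mc % npad] = spec[mr % npad, mc % npad]
    grating_full = np.real(np.fft.ifft2(np.fft.ifftshift(keep)))
    grating = grating_full[:n, :n]

    r_global = _pearson(norm, grating)

    # 1D profiles projected along the periodicity axis
    ii, jj = np.mgrid[0:n, 0:n]
    u = jj * np.cos(np.radians(theta)) + ii * np.sin(np.radians(theta))
    bins = np.round(u - u.min()).astype(int)
    prof_img = np.bincount(bins.ravel(), weights=norm.ravel())
    prof_grt = np.bincount(bins.ravel(), weights=grating.ravel())
    r_proj = _pearson(prof_img, prof_grt)

    # localized correlation: rotate so the periodicity axis is horizontal,
    # crop an elongated template (3 periods x 6 px) from the rotated
    # grating, and take the maximum normalized cross-correlation over all
    # in-window placements
    rot_img = nd_rotate(norm, theta, reshape=False, order=1, mode="constant")
    rot_grt = nd_rotate(grating, theta, reshape=False, order=1, mode="constant")
    t_len = max(3, int(round(template_periods * d / pixel_size)))
    t_wid = template_width_px
    r0 = max(0, n // 2 - t_wid // 2)
    c0 = max(0, n // 2 - t_len // 2)
    template = rot_grt[r0 : r0 + t_wid, c0 : c0 + t_len]
    if (
        template.shape[0] >= 2
        and template.shape[1] >= 2
        and template.std() > 0
        and template.shape[0] <= rot_img.shape[0]
        and template.shape[1] <= rot_img.shape[1]
    ):
        ncc = match_template(rot_img, template)
        r_local = float(ncc.max()) if ncc.size else 0.0
    else:
        r_local = 0.0

    s = integrated_score(r_global, r_local)
    spectrum = WindowSpectrum(
        amplitudes=mag, a_fft=a_fft, theta=theta, d=d, peak_coords=(int(pr), int(pc))
    )
    return spectrum, Regularity1DScores(
        a_fft=a_fft,
        r_global=max(r_global, 0.0),
        r_proj=max(r_proj, 0.0),
        r_local=max(r_local, 0.0),
        s_integrated=s,
    )


def periodicity_maps(
    img: RenderedImage,
    mask: CellMask,
    grid: WindowGrid | None = None,
    band: tuple[float, float] = PERIOD_BAND,
    keep_candidate_scores: bool = False,
) -> OrientationPeriodMap:
    """Scan the moving window over a rendered image and build score /
    orientation / period maps on the 256 nm grid.

    Orientation and period per pixel come from the window whose score is
    highest among the windows covering the pixel (scores are averaged as
    usual; a mean of circular orientations across windows is not
    meaningful)."""
    grid = grid or WindowGrid()
    factor = int(round(grid.pitch / img.pixel_size))
    shape = mask.grid.shape
    wpx = grid.window_px * factor

    rows, cols = img.pixels.shape
    need_r, need_c = shape[0] * factor, shape[1] * factor
    padded = np.zeros((max(rows, need_r), max(cols, need_c)))
    padded[:rows, :cols] = img.pixels

    origins = list(grid.window_origins(shape))
    n_win = len(origins)
    s_all = np.full(n_win, np.nan)
    cand = {k: np.full(n_win, np.nan) for k in ("a_fft", "r_global", "r_proj", "r_local")}
    theta_w = np.full(n_win, np.nan)
    d_w = np.full(n_win, np.nan)
    for w_idx, (i, j) in enumerate(origins):
        sub = padded[i * factor : i * factor + wpx, j * factor : j * factor + wpx]
        spectrum, scores = analyze_window_1d(sub, img.pixel_size, band)
        s_all[w_idx] = scores.s_integrated
        for k in cand:
            cand[k][w_idx] = getattr(scores, k)
        if spectrum is not None:
            theta_w[w_idx] = spectrum.theta
            d_w[w_idx] = spectrum.d

    score_grid = accumulate_window_means(s_all, shape, grid)
    # per-pixel theta/d from the best-scoring covering window
    best = np.full(shape, -np.inf)
    theta_grid = np.full(shape, np.nan)
    d_grid = np.full(shape, np.nan)
    w = grid.window_px
    for w_idx, (i, j) in enumerate(origins):
        if not np.isfinite(s_all[w_idx]) or not np.isfinite(theta_w[w_idx]):
            continue
        sl = (slice(i, i + w), slice(j, j + w))
        upd = s_all[w_idx] > best[sl]
        best[sl][upd] = s_all[w_idx]
        theta_grid[sl][upd] = theta_w[w_idx]
        d_grid[sl][upd] = d_w[w_idx]

    outside = ~mask.grid
    for g in (score_grid, theta_grid, d_grid):
        g[outside] = np.nan
    per_score = None
    if keep_candidate_scores:
        per_score = {}
        for k in cand:
            pm = accumulate_window_means(cand[k], shape, grid)
            pm[outside] = np.nan
            per_score[k] = pm
    return OrientationPeriodMap(score_grid, theta_grid, d_grid, grid, per_score)


def _circ_diff_deg(a: float, b: float, period: float = 180.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def _circ_mean_deg(values: list[float], period: float = 180.0) -> float:
    ang = np.radians(np.asarray(values) * (360.0 / period))
    m = np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0
    return m * (period / 360.0)


def segment_1d(
    maps: OrientationPeriodMap,
    mask: np.ndarray | None = None,
    seed_thr: float = 0.6,
    grow_thr: float = 0.45,
    dtheta_max: float = 15.0,
    dd_max: float = 10.0,
    min_region_px: int = 4,
) -> np.ndarray:
    """Seed region growing segmentation of 1D periodic domains.

    Pixels above ``seed_thr`` (1% false-positive level) seed regions that
    iteratively annex 8-neighbors whose score exceeds ``grow_thr`` (5%
    level) and whose orientation / period agree with the region's running
    mean within ``dtheta_max`` degrees (circular, period 180) and
    ``dd_max`` nm.  Regions below ``min_region_px`` pixels are removed;
    touching regions merge by construction.
    """
    score = maps.score_grid
    theta = maps.theta_grid
    d = maps.d_grid
    shape = score.shape
    allowed = np.isfinite(score)
    if mask is not None:
        allowed &= np.asarray(mask, dtype=bool)

    seeds = allowed & (score > seed_thr) & np.isfinite(theta) & np.isfinite(d)
    out = np.zeros(shape, dtype=bool)
    visited = np.zeros(shape, dtype=bool)
    neighbors = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    from collections import deque

    seed_coords = np.argwhere(seeds)
    for si, sj in seed_coords:
        if visited[si, sj]:
            continue
        region = [(si, sj)]
        visited[si, sj] = True
        thetas = [theta[si, sj]]
        ds = [d[si, sj]]
        queue = deque(region)
        while queue:
            ci, cj = queue.popleft()
            mean_t = _circ_mean_deg(thetas)
            mean_d = float(np.mean(ds))
            for di, dj in neighbors:
                ni, nj = ci + di, cj + dj
                if not (0 <= ni < shape[0] and 0 <= nj < shape[1]):
                    continue
                if visited[ni, nj] or not allowed[ni, nj]:
                    continue
                is_seed = seeds[ni, nj]
                grow_ok = (
                    score[ni, nj] > grow_thr
                    and np.isfinite(theta[ni, nj])
                    and np.isfinite(d[ni, nj])
                    and _circ_diff_deg(theta[ni, nj], mean_t) < dtheta_max
                    and abs(d[ni, nj] - mean_d) <= dd_max
                )
                if is_seed or grow_ok:
                    visited[ni, nj] = True
                    region.append((ni, nj))
                    thetas.append(theta[ni, nj])
                    ds.append(d[ni, nj])
                    queue.append((ni, nj))
        if len(region) >= min_region_px:
            for ri, rj in region:
                out[ri, rj] = True
    return out


@dataclass
class PeriodDistribution:
    values: np.ndarray
    mode: float | None
    mean: float | None


def period_histogram(
    mask: np.ndarray, maps: OrientationPeriodMap, bin_width: float = 4.0
) -> PeriodDistribution:
    """Distribution of the measured period over segmented pixels; the mode
    is the center of the fullest ``bin_width``-nm histogram bin."""
    sel = np.asarray(mask, dtype=bool) & np.isfinite(maps.d_grid)
    values = maps.d_grid[sel]
    if values.size == 0:
        return PeriodDistribution(values, None, None)
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, edges = np.histogram(values, bins=edges)
    k = int(np.argmax(hist))
    mode = float(0.5 * (edges[k] + edges[k + 1]))
    return PeriodDistribution(values, mode, float(values.mean()))
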