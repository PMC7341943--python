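"""Box-counting fractal dimension of the projected rhizoid system.

The traced filaments are rasterised as 1-pixel-wide skeleton strokes on a
binary grid (the "biological fractal" treatment: geometry, not fluorescence
intensity).  The global box-counting dimension Db is the negative slope of
the least-squares fit of log N(s) against log s, where N(s) is the number
of occupied boxes at box size s; Db = 1 for a line, 2 for a plane-filling
set.  A sliding-window variant maps Db spatially, and a radial profile
summarises how space-filling the system is as a function of distance from
the thallus — mature cells are more fractal at the centre and less fractal
towards the growing edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _bresenham_line

from .swc import TracedTree

__all__ = [
    "RasterGrid",
    "FractalResult",
    "rasterize",
    "default_box_sizes",
    "box_count_db",
    "local_db_map",
    "radial_db_profile",
    "PIXEL_SIZE_DEFAULT",
    "WINDOW_PX_DEFAULT",
    "STRIDE_PX_DEFAULT",
]

PIXEL_SIZE_DEFAULT = 0.5  # µm, ~confocal lateral sampling
WINDOW_PX_DEFAULT = 64
STRIDE_PX_DEFAULT = 16
MIN_WINDOW_PIXELS = 10  # windows with fewer foreground pixels are undefined


@dataclass
class RasterGrid:
    """Binary pixel grid; rows are y, columns are x."""

    grid: np.ndarray
    pixel_size: float = PIXEL_SIZE_DEFAULT
    origin: tuple[float, float] = (0.0, 0.0)  # µm position of pixel (0, 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class FractalResult:
    """Global and (optionally) spatially resolved box-counting results."""

    db_global: float
    fit_r2: float
    box_sizes: np.ndarray
    counts: np.ndarray
    db_map: np.ndarray | None = None  # NaN where undefined
    window_px: int | None = None
    stride_px: int | None = None
    pixel_size: float = PIXEL_SIZE_DEFAULT
    origin: tuple[float, float] = (0.0, 0.0)
    map_centres: np.ndarray | None = None  # (rows, cols, 2) window centres, µm


def rasterize(
    segments: np.ndarray, pixel_size: float = PIXEL_SIZE_DEFAULT, margin_px: int = 2
) -> RasterGrid:
    """Rasterise 2-D segments as 1-px Bresenham strokes.

    ``segments`` is an ``(n, 2, 2)`` array of endpoint pairs in µm (as from
    :func:`rhizomorph.swc.project_xy`).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    segments = np.asarray(segments, dtype=float)
    if segments.size == 0:
        raise ValueError("empty segment set")
    pts = segments.reshape(-1, 2)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    origin = (float(lo[0] - margin_px * pixel_size), float(lo[1] - margin_px * pixel_size))
    w = int(math.ceil((hi[0] - origin[0]) / pixel_size)) + 1 + margin_px
    h = int(math.ceil((hi[1] - origin[1]) / pixel_size)) + 1 + margin_px
    grid = np.zeros((h, w), dtype=bool)
    for (x0, y0), (x1, y1) in segments:
        c0 = int(round((x0 - origin[0]) / pixel_size))
        r0 = int(round((y0 - origin[1]) / pixel_size))
        c1 = int(round((x1 - origin[0]) / pixel_size))
        r1 = int(round((y1 - origin[1]) / pixel_size))
        rr, cc = _bresenham_line(r0, c0, r1, c1)
        grid[rr, cc] = True
    return RasterGrid(grid=grid, pixel_size=pixel_size, origin=origin)


def rasterize_tree(tree: TracedTree, pixel_size: float = PIXEL_SIZE_DEFAULT) -> RasterGrid:
    """Convenience: project a tree to XY and rasterise it."""
    from .swc import project_xy

    return rasterize(project_xy(tree), pixel_size=pixel_size)


def default_box_sizes(short_side: int) -> list[int]:
    """Powers of 2 from 2 px up to a quarter of the grid's short side."""
    sizes = []
    s = 2
    while s <= short_side // 4:
        sizes.append(s)
        s *= 2
    return sizes


def _occupied_boxes(grid: np.ndarray, s: int) -> int:
    h, w = grid.shape
    nh = -(-h // s)
    nw = -(-w // s)
    padded = np.zeros((nh * s, nw * s), dtype=bool)
    padded[:h, :w] = grid
    blocks = padded.reshape(nh, s, nw, s).any(axis=(1, 3))
    return int(blocks.sum())


def box_count_db(grid: RasterGrid | np.ndarray, sizes=None) -> FractalResult:
    """Global box-counting dimension from a least-squares log-log fit.

    Requires a non-empty grid and at least four box sizes (a geometric
    series; the default is powers of two up to short-side/4).
    """
    if isinstance(grid, RasterGrid):
        arr = grid.grid
        pixel_size = grid.pixel_size
        origin = grid.origin
    else:
        arr = np.asarray(grid, dtype=bool)
        pixel_size = PIXEL_SIZE_DEFAULT
        origin = (0.0, 0.0)
    if not arr.any():
        raise ValueError("grid has no foreground pixels")
    if sizes is None:
        sizes = default_box_sizes(min(arr.shape))
    sizes = list(sizes)
    if len(sizes) < 4:
        raise ValueError(f"need >= 4 box sizes for a stable fit, got {len(sizes)}")
    counts = np.array([_occupied_boxes(arr, s) for s in sizes], dtype=float)
    log_s = np.log(np.array(sizes, dtype=float))
    log_n = np.log(counts)
    slope, intercept = np.polyfit(log_s, log_n, 1)
    pred = slope * log_s + intercept
    ss_res = float(np.sum((log_n - pred) ** 2))
    ss_tot = float(np.sum((log_n - log_n.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FractalResult(
        db_global=float(-slope),
        fit_r2=r2,
        box_sizes=np.array(sizes),
        counts=counts,
        pixel_size=pixel_size,
        origin=origin,
    )


def local_db_map(
    grid: RasterGrid,
    window_px: int = WINDOW_PX_DEFAULT,
    stride_px: int = STRIDE_PX_DEFAULT,
    sizes=None,
) -> FractalResult:
    """Sliding-window local Db map.

    Windows with fewer than ``MIN_WINDOW_PIXELS`` foreground pixels are
    reported as NaN.  The returned result also carries the global fit of
    the full grid.
    """
    arr = grid.grid
    if window_px > min(arr.shape):
        raise ValueError(
            f"window ({window_px} px) larger than grid {arr.shape}"
        )
    if sizes is None:
        sizes = default_box_sizes(window_px)
    if len(list(sizes)) < 4:
        raise ValueError("window too small: fewer than 4 box sizes fit")
    h, w = arr.shape
    rows = range(0, h - window_px + 1, stride_px)
    cols = range(0, w - window_px + 1, stride_px)
    db = np.full((len(rows), len(cols)), np.nan)
    centres = np.empty((len(rows), len(cols), 2))
    half = window_px / 2.0
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            centres[i, j, 0] = grid.origin[0] + (c + half) * grid.pixel_size  # x
            centres[i, j, 1] = grid.origin[1] + (r + half) * grid.pixel_size  # y
            sub = arr[r : r + window_px, c : c + window_px]
            if int(sub.sum()) < MIN_WINDOW_PIXELS:
                continue
            db[i, j] = box_count_db(sub, sizes=sizes).db_global
    base = box_count_db(grid)
    base.db_map = db
    base.window_px = window_px
    base.stride_px = stride_px
    base.map_centres = centres
    return base


def radial_db_profile(
    result: FractalResult,
    centre: tuple[float, float],
    bin_width: float | None = None,
) -> list[tuple[float, float]]:
    """Mean local Db per concentric annulus about a centre point (µm).

    Returns ``(annulus mid-radius, mean Db)`` pairs; annuli with no defined
    windows are NaN.  The default bin width is half the window size.
    """
    if result.db_map is None or result.map_centres is None:
        raise ValueError("no local Db map computed")
    defined = ~np.isnan(result.db_map)
    if not defined.any():
        raise ValueError("no defined local Db values")
    if bin_width is None:
        bin_width = (result.window_px or WINDOW_PX_DEFAULT) * result.pixel_size / 2.0
    dx = result.map_centres[..., 0] - centre[0]
    dy = result.map_centres[..., 1] - centre[1]
    r = np.hypot(dx, dy)
    rmax = float(r[defined].max())
    n_bins = max(1, int(math.ceil(rmax / bin_width)))
    profile = []
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        mask = defined & (r >= lo) & (r < hi if b < n_bins - 1 else r <= hi)
        mean = float(np.nanmean(result.db_map[mask])) if mask.any() else float("nan")
        profile.append(((lo + hi) / 2.0, mean))
    return profile
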