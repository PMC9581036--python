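"""Primitive image operators from which the detection workflows are composed.

Images are plain 2D numpy arrays (8/16-bit unsigned integers or floats).  All
rank filters use a *disk* neighborhood clipped to the image bounds at the
edges (no padding values are invented), matching ImageJ rank-filter behaviour
closely and keeping the operators easy to verify against brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .core import TargetList, TileGrid, stage_to_map_pixel

__all__ = [
    "Particle",
    "median_filter",
    "remove_outliers",
    "subtract_clamped",
    "threshold_nonzero",
    "threshold_global",
    "log_filter",
    "local_minima",
    "find_particles",
    "max_project",
    "assemble_tiles",
    "make_montage",
    "read_image",
    "write_image",
]


def disk_offsets(radius_px: int) -> list[tuple[int, int]]:
    """(dy, dx) offsets of the disk neighborhood of the given radius."""
    r = int(radius_px)
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def _neighborhood_median(img: np.ndarray, radius_px: int) -> np.ndarray:
    """Per-pixel median of the disk neighborhood clipped to image bounds.

    Implemented as a NaN-padded stack of shifted views so the edge semantics
    (median over in-bounds pixels only) are exact.
    """
    offsets = disk_offsets(radius_px)
    h, w = img.shape
    r = int(radius_px)
    padded = np.full((h + 2 * r, w + 2 * r), np.inf, dtype=np.float64)
    padded[r : r + h, r : r + w] = img
    stack = np.empty((len(offsets), h, w), dtype=np.float64)
    valid = np.zeros((h, w), dtype=np.intp)
    for i, (dy, dx) in enumerate(offsets):
        view = padded[r + dy : r + dy + h, r + dx : r + dx + w]
        stack[i] = view
        valid += np.isfinite(view)
    # out-of-bounds entries sort to the top; median over the n valid values
    stack.sort(axis=0)
    flat = stack.reshape(len(offsets), -1)
    n = valid.reshape(-1)
    lo = np.take_along_axis(flat, ((n - 1) // 2)[None, :], axis=0)[0]
    hi = np.take_along_axis(flat, (n // 2)[None, :], axis=0)[0]
    return ((lo + hi) / 2.0).reshape(h, w)


def _cast_back(values: np.ndarray, like: np.ndarray) -> np.ndarray:
    if np.issubdtype(like.dtype, np.integer):
        info = np.iinfo(like.dtype)
        return np.clip(np.rint(values), info.min, info.max).astype(like.dtype)
    return values.astype(like.dtype)


def median_filter(img: np.ndarray, radius_px: int) -> np.ndarray:
    """Disk-neighborhood median filter (edge neighborhoods clipped)."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    return _cast_back(_neighborhood_median(np.asarray(img), radius_px), np.asarray(img))


def remove_outliers(img: np.ndarray, radius_px: int, threshold: float, mode: str = "bright") -> np.ndarray:
    """ImageJ *Remove Outliers*: replace a pixel by its neighborhood median
    only when it deviates from it by more than ``threshold``.

    ``mode='bright'`` replaces pixels with ``p - median > threshold``;
    ``mode='dark'`` is symmetric.  All other pixels are left untouched.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in ("bright", "dark"):
        raise ValueError(f"mode must be 'bright' or 'dark', got {mode!r}")
    img = np.asarray(img)
    med = _neighborhood_median(img, radius_px)
    dev = img.astype(np.float64) - med
    outlier = dev > threshold if mode == "bright" else -dev > threshold
    out = img.astype(np.float64).copy()
    out[outlier] = med[outlier]
    return _cast_back(out, img)


def subtract_clamped(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel ``max(a - b, 0)``; the result keeps ``a``'s dtype."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a.astype(np.float64) - b.astype(np.float64)
    return _cast_back(np.maximum(diff, 0.0), a)


def threshold_nonzero(img: np.ndarray) -> np.ndarray:
    """Mask of strictly positive pixels."""
    return np.asarray(img) > 0


def threshold_global(img: np.ndarray, method: str = "otsu", value: Optional[float] = None) -> np.ndarray:
    """Global threshold mask: ``intensity > threshold``.

    ``method='otsu'`` maximises the between-class variance on the 256-bin
    histogram of the image; ``method='fixed'`` requires ``value``.
    """
    img = np.asarray(img)
    if method == "fixed":
        if value is None:
            raise ValueError("method='fixed' requires a threshold value")
        return img > value
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        return np.zeros(img.shape, dtype=bool)
    counts, edges = np.histogram(img, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    thr = threshold_otsu(hist=(counts, centers))
    return img > thr


def log_filter(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Laplacian-of-Gaussian band-pass, signed float output.

    Sign convention: *dark* blobs of diameter ≈ 2√2·sigma produce local
    minima of the response (the negated standard ∇²G); bright blobs produce
    maxima.  The filter is linear and removes any constant offset.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    return -ndi.gaussian_laplace(np.asarray(img, dtype=np.float64), sigma_px)


def local_minima(
    img: np.ndarray, prominence: float, min_distance_px: int = 1
) -> list[tuple[int, int]]:
    """Significant local minima: deeper than ``prominence`` below their
    surrounding saddle level (topographic dynamics), then non-maximum
    suppressed at ``min_distance_px``.

    Returns (row, col) points, deepest first; ties broken by (row, col).
    The global minimum is always significant for a non-constant image.
    """
    if prominence < 0:
        raise ValueError("prominence must be >= 0")
    if min_distance_px < 1:
        raise ValueError("min_distance_px must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    if img.min() == img.max():
        return []
    if prominence == 0:
        mask = morphology.local_minima(img, connectivity=2)
    else:
        # h-minima reconstruction: surviving minima have dynamics >= prominence
        mask = morphology.h_minima(img, h=prominence, footprint=np.ones((3, 3), dtype=bool))
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    candidates: list[tuple[float, int, int]] = []
    for region in range(1, n + 1):
        ys, xs = np.nonzero(labels == region)
        vals = img[ys, xs]
        best = np.flatnonzero(vals == vals.min())
        # representative = deepest pixel of the region, tie-break by (row, col)
        order = sorted(best, key=lambda i: (ys[i], xs[i]))
        i = order[0]
        candidates.append((vals[i], int(ys[i]), int(xs[i])))
    candidates.sort()
    kept: list[tuple[int, int]] = []
    for _, y, x in candidates:
        if all(math.hypot(y - ky, x - kx) >= min_distance_px for ky, kx in kept):
            kept.append((y, x))
    return kept


@dataclass(frozen=True)
class Particle:
    """A connected component surviving the size/shape gates."""

    area_px: int
    centroid: tuple[float, float]  # (row, col), pixel mean
    circularity: float  # 4*pi*A / P^2, Crofton perimeter
    mean_intensity: float
    coords: np.ndarray  # (n, 2) array of (row, col) pixels

    def contains_point(self, row: int, col: int) -> bool:
        return bool(np.any((self.coords[:, 0] == row) & (self.coords[:, 1] == col)))


def find_particles(
    mask: np.ndarray,
    min_area_px: int = 1,
    max_area_px: Optional[int] = None,
    min_circularity: float = 0.0,
    intensity_img: Optional[np.ndarray] = None,
) -> list[Particle]:
    """8-connected component analysis with area and circularity gates.

    Circularity is 4πA/P² with P the Crofton outer-perimeter estimate (less
    raster bias than edge counting).  Centroid is the pixel mean.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels, intensity_image=intensity_img)
    out: list[Particle] = []
    for p in props:
        area = int(p.area)
        if area < min_area_px or (max_area_px is not None and area > max_area_px):
            continue
        perim = p.perimeter_crofton if area > 1 else max(p.perimeter_crofton, 1.0)
        circ = 4.0 * math.pi * area / (perim * perim) if perim > 0 else 1.0
        if circ < min_circularity:
            continue
        out.append(
            Particle(
                area_px=area,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                circularity=float(circ),
                mean_intensity=float(p.intensity_mean) if intensity_img is not None else 0.0,
                coords=p.coords.copy(),
            )
        )
    return out


def max_project(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum over the z-slices of a stack."""
    if len(stack) == 0:
        raise ValueError("cannot project an empty stack")
    arrs = [np.asarray(s) for s in stack]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all slices must share one shape")
    out = arrs[0]
    for a in arrs[1:]:
        out = np.maximum(out, a)
    return out


def assemble_tiles(tiles: dict[tuple[int, int], np.ndarray], grid: TileGrid) -> np.ndarray:
    """Lay tiles side by side into the primary map (zero overlap).

    Tile (r, c) occupies block rows [r·H, (r+1)·H), cols [c·W, (c+1)·W).
    """
    h, w = grid.tile_h_px, grid.tile_w_px
    sample = next(iter(tiles.values()), None)
    dtype = sample.dtype if sample is not None else np.uint16
    out = np.zeros((grid.map_h_px, grid.map_w_px), dtype=dtype)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if (r, c) not in tiles:
                raise ValueError(f"missing tile at grid cell ({r}, {c})")
            t = np.asarray(tiles[(r, c)])
            if t.shape != (h, w):
                raise ValueError(f"tile ({r}, {c}) has shape {t.shape}, expected {(h, w)}")
            out[r * h : (r + 1) * h, c * w : (c + 1) * w] = t
    return out


def make_montage(
    map_img: np.ndarray,
    targets: TargetList,
    grid: TileGrid,
    box_px: int = 64,
    n_cols: int = 8,
) -> tuple[np.ndarray, dict[int, int]]:
    """Tight review montage of crops centered on each target.

    Crops are edge-clipped and zero-padded to ``box_px``, tiled row-major in
    ``n_cols`` columns.  The index map records montage cell -> target index.
    """
    if box_px < 8:
        raise ValueError("box_px must be >= 8")
    if n_cols < 1:
        raise ValueError("n_cols must be >= 1")
    if len(targets) == 0:
        return np.zeros((0, 0), dtype=np.asarray(map_img).dtype), {}
    map_img = np.asarray(map_img)
    n_rows = math.ceil(len(targets) / n_cols)
    out = np.zeros((n_rows * box_px, n_cols * box_px), dtype=map_img.dtype)
    index_map: dict[int, int] = {}
    half = box_px // 2
    for i, t in enumerate(targets):
        cy, cx = stage_to_map_pixel(grid, t.position)
        y0, x0 = int(round(cy)) - half, int(round(cx)) - half
        sy0, sx0 = max(y0, 0), max(x0, 0)
        sy1 = min(y0 + box_px, map_img.shape[0])
        sx1 = min(x0 + box_px, map_img.shape[1])
        cell = np.zeros((box_px, box_px), dtype=map_img.dtype)
        if sy1 > sy0 and sx1 > sx0:
            cell[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = map_img[sy0:sy1, sx0:sx1]
        r, c = divmod(i, n_cols)
        out[r * box_px : (r + 1) * box_px, c * box_px : (c + 1) * box_px] = cell
        index_map[i] = i
    return out, index_map


def read_image(path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF (multi-page -> 3D stack)."""
    import tifffile

    return tifffile.imread(path)


def write_image(path, img: np.ndarray) -> None:
    """Write a grayscale TIFF (2D image or 3D z-stack)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(img))
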