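"""Coordinate geometry and target bookkeeping shared by all modules.

Conventions: pixel coordinates are 0-based ``(row, col)`` with y increasing
downward; stage axes are aligned with pixel axes (x grows with columns, y with
rows).  Tile grid positions refer to tile *centers* and tiles are laid side by
side with zero overlap.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "StagePosition",
    "TileGrid",
    "Target",
    "TargetList",
    "pixel_to_stage",
    "map_pixel_to_stage",
    "stage_to_map_pixel",
    "stage_to_pixel",
    "dedup_targets",
    "save_targets",
    "load_targets",
    "focus_map_interpolate",
]


@dataclass(frozen=True)
class StagePosition:
    """Absolute stage coordinates in micrometres."""

    x_um: float
    y_um: float
    z_um: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x_um", "y_um", "z_um"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"StagePosition.{name} must be finite, got {v!r}")

    def distance_xy(self, other: "StagePosition") -> float:
        """Lateral (x, y) Euclidean distance in µm."""
        return math.hypot(self.x_um - other.x_um, self.y_um - other.y_um)


@dataclass(frozen=True)
class TileGrid:
    """Geometry binding tile indices to stage positions and pixel rasters.

    ``origin`` is the stage position of the *center* of tile (row 0, col 0).
    """

    origin: StagePosition
    n_rows: int
    n_cols: int
    tile_h_px: int
    tile_w_px: int
    pixel_size_um: float
    order: str = "row-major"  # or "serpentine" (acquisition order only)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must hold at least one tile")
        if self.tile_h_px < 1 or self.tile_w_px < 1:
            raise ValueError("tile raster must be at least 1x1 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.order not in ("row-major", "serpentine"):
            raise ValueError(f"unknown scan order {self.order!r}")

    @property
    def map_h_px(self) -> int:
        return self.n_rows * self.tile_h_px

    @property
    def map_w_px(self) -> int:
        return self.n_cols * self.tile_w_px

    def tile_center(self, row: int, col: int) -> StagePosition:
        """Stage position of the center of tile (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"tile ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return StagePosition(
            self.origin.x_um + col * self.tile_w_px * self.pixel_size_um,
            self.origin.y_um + row * self.tile_h_px * self.pixel_size_um,
            self.origin.z_um,
        )

    def scan_order(self) -> Iterator[tuple[int, int]]:
        """(row, col) indices in acquisition order."""
        for r in range(self.n_rows):
            cols = range(self.n_cols)
            if self.order == "serpentine" and r % 2 == 1:
                cols = reversed(cols)  # type: ignore[assignment]
            for c in cols:
                yield (r, c)


@dataclass(frozen=True)
class Target:
    """A detected object: where to point the secondary scan."""

    position: StagePosition
    label: str = ""
    score: float = 0.0
    frame_index: int = 0
    block_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("target score must be >= 0")


class TargetList(list):
    """Ordered collection of :class:`Target` (a plain list with helpers)."""

    def __init__(self, targets: Iterable[Target] = ()) -> None:
        super().__init__(targets)

    def sorted_by_score(self) -> "TargetList":
        """Descending score, ties broken by original order (stable)."""
        order = sorted(range(len(self)), key=lambda i: (-self[i].score, i))
        return TargetList(self[i] for i in order)


def pixel_to_stage(grid: TileGrid, row: int, col: int, px: float, py: float) -> StagePosition:
    """Stage position of pixel (px, py) inside tile (row, col).

    Pixel (0, 0) is the tile's top-left corner; the tile center pixel
    (tile_w/2, tile_h/2) maps exactly onto the tile's stage center.
    """
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise IndexError(f"tile ({row}, {col}) outside {grid.n_rows}x{grid.n_cols} grid")
    if not (0 <= px <= grid.tile_w_px and 0 <= py <= grid.tile_h_px):
        raise IndexError(f"pixel ({px}, {py}) outside {grid.tile_h_px}x{grid.tile_w_px} tile")
    center = grid.tile_center(row, col)
    return StagePosition(
        center.x_um + (px - grid.tile_w_px / 2.0) * grid.pixel_size_um,
        center.y_um + (py - grid.tile_h_px / 2.0) * grid.pixel_size_um,
        center.z_um,
    )


def map_pixel_to_stage(grid: TileGrid, y: float, x: float) -> StagePosition:
    """Stage position of pixel (row=y, col=x) in the *assembled* map."""
    row, col = int(y // grid.tile_h_px), int(x // grid.tile_w_px)
    row = min(max(row, 0), grid.n_rows - 1)
    col = min(max(col, 0), grid.n_cols - 1)
    return pixel_to_stage(grid, row, col, x - col * grid.tile_w_px, y - row * grid.tile_h_px)


def stage_to_map_pixel(grid: TileGrid, pos: StagePosition) -> tuple[float, float]:
    """(row, col) pixel of ``pos`` in the assembled map (may lie outside)."""
    gx = (pos.x_um - grid.origin.x_um) / grid.pixel_size_um + grid.tile_w_px / 2.0
    gy = (pos.y_um - grid.origin.y_um) / grid.pixel_size_um + grid.tile_h_px / 2.0
    return gy, gx


def stage_to_pixel(grid: TileGrid, pos: StagePosition) -> tuple[int, int, float, float]:
    """Exact inverse of :func:`pixel_to_stage`: (row, col, px, py).

    Raises ValueError if ``pos`` lies outside the grid footprint.
    """
    gx = (pos.x_um - grid.origin.x_um) / grid.pixel_size_um + grid.tile_w_px / 2.0
    gy = (pos.y_um - grid.origin.y_um) / grid.pixel_size_um + grid.tile_h_px / 2.0
    if not (0 <= gx < grid.map_w_px) or not (0 <= gy < grid.map_h_px):
        raise ValueError(f"position {pos} outside grid footprint")
    col, row = int(gx // grid.tile_w_px), int(gy // grid.tile_h_px)
    return row, col, gx - col * grid.tile_w_px, gy - row * grid.tile_h_px


def dedup_targets(targets: TargetList, min_separation_um: float) -> TargetList:
    """Greedy deduplication by descending score.

    A target is kept iff no already-kept target lies within
    ``min_separation_um`` (lateral stage distance).  Survivors are returned in
    descending score order, ties resolved by input order, which makes the
    result independent of input order for distinct scores.
    """
    if min_separation_um < 0:
        raise ValueError("min_separation_um must be >= 0")
    kept = TargetList()
    for t in TargetList(targets).sorted_by_score():
        if all(t.position.distance_xy(k.position) >= min_separation_um for k in kept):
            kept.append(t)
    return kept


_CSV_COLUMNS = ["x_um", "y_um", "z_um", "label", "score", "frame_index", "block_index"]


def save_targets(targets: Iterable[Target], path) -> None:
    """Write a target list as CSV (µm to 6 decimals); lossless round trip."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for t in targets:
            w.writerow(
                [
                    f"{t.position.x_um:.6f}",
                    f"{t.position.y_um:.6f}",
                    f"{t.position.z_um:.6f}",
                    t.label,
                    repr(float(t.score)),
                    t.frame_index,
                    "" if t.block_index is None else t.block_index,
                ]
            )


def load_targets(path) -> TargetList:
    """Read a target CSV written by :func:`save_targets`."""
    out = TargetList()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_COLUMNS:
            raise ValueError(f"{path}: line 1: expected columns {_CSV_COLUMNS}, got {header}")
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != len(_CSV_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected {len(_CSV_COLUMNS)} fields, got {len(rec)}")
            try:
                out.append(
                    Target(
                        position=StagePosition(float(rec[0]), float(rec[1]), float(rec[2])),
                        label=rec[3],
                        score=float(rec[4]),
                        frame_index=int(rec[5]),
                        block_index=None if rec[6] == "" else int(rec[6]),
                    )
                )
            except ValueError as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from e
    return out


def focus_map_interpolate(corner_z: tuple[float, float, float, float], u: float, v: float) -> float:
    """Bilinear coarse-focus interpolation from the four region corners.

    ``corner_z`` is ordered (top-left, top-right, bottom-left, bottom-right);
    ``u`` runs left→right and ``v`` top→bottom, both in [0, 1].  Exact at the
    corners.
    """
    if not (0 <= u <= 1 and 0 <= v <= 1):
        raise ValueError(f"(u, v) = ({u}, {v}) outside the unit square")
    tl, tr, bl, br = corner_z
    return (1 - v) * ((1 - u) * tl + u * tr) + v * ((1 - u) * bl + u * br)
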