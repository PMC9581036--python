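"""Acquisition state machines: tiled/block × fixed/live, target review and
capping, and scan-plan accounting.

The engine is backend-agnostic: anything exposing ``scan_primary`` and
``acquire_secondary`` (the in-process simulator, a CAM folder bridge, or an
offline replay source) drives identically, which is what makes offline
replay reproduce a live run's :class:`AcquisitionLog` exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .core import StagePosition, Target, TargetList, TileGrid, dedup_targets
from .imgops import assemble_tiles, make_montage, max_project, write_image
from .protocol import ReplayExhausted

__all__ = [
    "SecondaryConfig",
    "ExperimentConfig",
    "AcquisitionLog",
    "run_tiled_fixed",
    "run_block_fixed",
    "run_tiled_live",
    "run_block_live",
    "run_experiment",
    "apply_review",
    "estimate_scan_plan",
    "tiles_at_secondary_resolution",
]

MODES = ("tiled_fixed", "tiled_live", "block_fixed", "block_live")


@dataclass(frozen=True)
class SecondaryConfig:
    """Secondary-scan settings: a fixed-length time-lapse of ``n_timepoints``
    frames for live modes, a single stack per target for fixed modes."""

    n_timepoints: int = 1
    channels: Sequence[int] = (0,)
    n_z: int = 1
    interval_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1 or self.n_z < 1 or not self.channels:
            raise ValueError("invalid secondary scan settings")


@dataclass
class ExperimentConfig:
    """Everything a run needs besides the backend and the detector."""

    mode: str
    grid: Optional[TileGrid] = None  # tiled modes
    blocks: Optional[Sequence[TileGrid]] = None  # block modes
    channels: Sequence[int] = (0,)
    n_z_primary: int = 1
    detector: str = "metaphase"
    detector_params: dict = field(default_factory=dict)
    secondary: SecondaryConfig = field(default_factory=SecondaryConfig)
    max_events: int = 1  # live: stop after N secondary bursts
    max_primary_frames: int = 100  # live: primary frame (or cycle) budget
    target_cap: Optional[int] = None  # fixed: keep at most this many targets
    review: bool = False
    selection_path: Optional[str] = None  # review: accepted montage indices
    montage_path: Optional[str] = None
    montage_box_px: int = 48
    min_separation_um: float = 10.0
    secondary_dwell_frames: int = 0  # scene clock advance per burst
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.mode.startswith("tiled") and self.grid is None:
            raise ValueError("tiled modes require exactly one grid")
        if self.mode.startswith("block") and not self.blocks:
            raise ValueError("block modes require at least one block grid")
        if self.mode.endswith("live"):
            if self.secondary.n_timepoints < 1:
                raise ValueError("live modes require secondary n_timepoints >= 1")
            if self.max_events < 1:
                raise ValueError("max_events must be >= 1")


class AcquisitionLog:
    """Ordered record of every acquisition and detection decision.

    Events are dicts with an ``event`` kind plus fields and a wall-clock
    timestamp; :meth:`events_without_timestamps` is the comparison surface
    for replay-equivalence checks.
    """

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, kind: str, **fields) -> None:
        self.events.append({"event": kind, **fields, "ts": time.time()})

    def events_without_timestamps(self) -> list[dict]:
        return [{k: v for k, v in e.items() if k != "ts"} for e in self.events]

    def of_kind(self, event: str) -> list[dict]:
        return [e for e in self.events if e["event"] == event]

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")

    # -- contract helpers ---------------------------------------------------
    def secondary_bursts(self) -> list[list[dict]]:
        """Secondary-frame events grouped by burst (between mode switches)."""
        bursts, current, in_secondary = [], [], False
        for e in self.events:
            if e["event"] == "mode_switch" and e["to"] == "secondary":
                in_secondary, current = True, []
            elif e["event"] == "mode_switch" and e["to"] == "primary":
                if in_secondary:
                    bursts.append(current)
                in_secondary = False
            elif e["event"] == "secondary_frame" and in_secondary:
                current.append(e)
        if in_secondary and current:
            bursts.append(current)
        return bursts


# --------------------------------------------------------------------------
# shared steps


def _acquire_frame(backend, grid, channels, n_z, t_index, block_index, log):
    """One primary frame: scan, per-tile max projection, assembly per channel."""
    log.add("primary_frame_start", t=t_index, block=block_index)
    tiles = backend.scan_primary(grid, channels, n_z, t_index, block_index)
    maps = {}
    for ch in channels:
        projected = {rc: max_project(list(stacks[ch])) for rc, stacks in tiles.items()}
        maps[ch] = assemble_tiles(projected, grid)
    log.add("primary_frame_end", t=t_index, block=block_index)
    return maps


def _tag(targets: TargetList, frame_index: int, block_index=None) -> TargetList:
    return TargetList(
        dataclasses.replace(t, frame_index=frame_index, block_index=block_index)
        for t in targets
    )


def apply_review(
    targets: TargetList, index_map: dict, selection_path: Optional[str]
) -> TargetList:
    """Filter targets by the accepted montage cell indices in a selection
    file (one index per line).  An absent file accepts everything."""
    if selection_path is None or not Path(selection_path).exists():
        return TargetList(targets)
    accepted = set()
    for line in Path(selection_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx = int(line)
        if idx not in index_map:
            raise ValueError(f"selection index {idx} out of range (montage has {len(index_map)} cells)")
        accepted.add(index_map[idx])
    return TargetList(t for i, t in enumerate(targets) if i in accepted)


def _review_and_cap(cfg: ExperimentConfig, maps, grid, targets: TargetList, log) -> TargetList:
    if cfg.review and len(targets) > 0:
        review_map = maps[cfg.channels[0]]
        montage, index_map = make_montage(
            review_map, targets, grid, box_px=cfg.montage_box_px
        )
        if cfg.montage_path:
            write_image(cfg.montage_path, montage)
        targets = apply_review(targets, index_map, cfg.selection_path)
        log.add("review", n_accepted=len(targets))
    targets = dedup_targets(targets, cfg.min_separation_um)
    if cfg.target_cap is not None:
        targets = TargetList(targets.sorted_by_score()[: cfg.target_cap])
    return targets


def _secondary_pass(cfg: ExperimentConfig, backend, targets: TargetList, t_index, log):
    """Fixed modes: acquire every target once, centered on it."""
    log.add("mode_switch", to="secondary")
    for i, tgt in enumerate(targets):
        log.add("secondary_frame", target=i, k=1, of=1)
        backend.acquire_secondary(tgt.position, cfg.secondary.channels, cfg.secondary.n_z, t_index)
    log.add("mode_switch", to="primary")


# --------------------------------------------------------------------------
# fixed-sample modes


def run_tiled_fixed(cfg: ExperimentConfig, backend, detector: Callable):
    """Single primary map → detect → (review) → cap → one secondary scan."""
    log = AcquisitionLog()
    try:
        maps = _acquire_frame(backend, cfg.grid, cfg.channels, cfg.n_z_primary, 0, 0, log)
    except (TimeoutError, ReplayExhausted) as e:
        log.add("run_end", reason="aborted", detail=str(e))
        return TargetList(), log
    targets = _tag(detector([maps], cfg.grid, cfg.detector_params), 0)
    log.add("detection_call", t=0, block=0, n_targets=len(targets))
    targets = _review_and_cap(cfg, maps, cfg.grid, targets, log)
    if not targets:
        log.add("run_end", reason="no_targets")
        return targets, log
    _secondary_pass(cfg, backend, targets, 0, log)
    log.add("run_end", reason="completed", n_targets=len(targets))
    return targets, log


def run_block_fixed(cfg: ExperimentConfig, backend, detector: Callable):
    """Blocks analysed sequentially; one secondary scan at the very end."""
    log = AcquisitionLog()
    accumulated = TargetList()
    last_maps, last_grid = None, None
    for b, grid in enumerate(cfg.blocks):
        try:
            maps = _acquire_frame(backend, grid, cfg.channels, cfg.n_z_primary, 0, b, log)
        except (TimeoutError, ReplayExhausted) as e:
            log.add("run_end", reason="aborted", detail=str(e))
            return accumulated, log
        found = _tag(detector([maps], grid, cfg.detector_params), 0, block_index=b)
        log.add("detection_call", t=0, block=b, n_targets=len(found))
        accumulated.extend(found)
        last_maps, last_grid = maps, grid
    # review is usually disabled in block mode; honored when enabled
    targets = _review_and_cap(cfg, last_maps, last_grid, accumulated, log) if last_maps else accumulated
    if not targets:
        log.add("run_end", reason="no_targets")
        return targets, log
    _secondary_pass(cfg, backend, targets, 0, log)
    log.add("run_end", reason="completed", n_targets=len(targets))
    return targets, log


# --------------------------------------------------------------------------
# live modes


def _burst(cfg: ExperimentConfig, backend, target: Target, event_index: int, scene_t: int, log):
    """Fixed-length secondary time-lapse centered on one detected event."""
    log.add("mode_switch", to="secondary")
    L = cfg.secondary.n_timepoints
    for k in range(1, L + 1):
        log.add("secondary_frame", event_index=event_index, target_label=target.label, k=k, of=L)
        backend.acquire_secondary(
            target.position, cfg.secondary.channels, cfg.secondary.n_z, scene_t
        )
    log.add("mode_switch", to="primary")


def run_tiled_live(cfg: ExperimentConfig, backend, detector: Callable):
    """Periodic primary maps; a detection triggers an immediate fixed-length
    secondary burst (no user validation), during which the system is blind.

    The detector is invoked only once the 3-frame queue is full; the queue is
    flushed after every burst (pre-burst frames are stale)."""
    log = AcquisitionLog()
    events = TargetList()
    queue: list[dict] = []
    scene_t = 0
    for frame in range(cfg.max_primary_frames):
        try:
            maps = _acquire_frame(backend, cfg.grid, cfg.channels, cfg.n_z_primary, scene_t, 0, log)
        except (TimeoutError, ReplayExhausted) as e:
            log.add("run_end", reason="aborted", detail=str(e))
            return events, log
        scene_t += 1
        queue.append(maps)
        if len(queue) > 3:
            queue.pop(0)
        if len(queue) < 3:
            continue
        found = _tag(detector(queue, cfg.grid, cfg.detector_params), scene_t - 1)
        log.add("detection_call", t=scene_t - 1, block=0, n_targets=len(found))
        if not found:
            continue
        best = found.sorted_by_score()[0]  # single-target optimisation
        events.append(best)
        _burst(cfg, backend, best, len(events) - 1, scene_t, log)
        queue.clear()  # restart the 3-frame fill
        scene_t += cfg.secondary_dwell_frames
        if len(events) >= cfg.max_events:
            log.add("run_end", reason="max_events", n_events=len(events))
            return events, log
    log.add("run_end", reason="max_primary_frames", n_events=len(events))
    return events, log


def run_block_live(cfg: ExperimentConfig, backend, detector: Callable):
    """Round-robin block monitoring with per-block 3-frame queues.

    A hit triggers the burst immediately (before the next block's frame);
    only the triggering block's queue is flushed, the cycle resumes at the
    next block."""
    log = AcquisitionLog()
    events = TargetList()
    queues: list[list[dict]] = [[] for _ in cfg.blocks]
    scene_t = 0
    for cycle in range(cfg.max_primary_frames):
        for b, grid in enumerate(cfg.blocks):
            try:
                maps = _acquire_frame(backend, grid, cfg.channels, cfg.n_z_primary, scene_t, b, log)
            except (TimeoutError, ReplayExhausted) as e:
                log.add("run_end", reason="aborted", detail=str(e))
                return events, log
            queues[b].append(maps)
            if len(queues[b]) > 3:
                queues[b].pop(0)
            if len(queues[b]) < 3:
                continue
            found = _tag(detector(queues[b], grid, cfg.detector_params), scene_t, block_index=b)
            log.add("detection_call", t=scene_t, block=b, n_targets=len(found))
            if not found:
                continue
            best = found.sorted_by_score()[0]
            events.append(best)
            _burst(cfg, backend, best, len(events) - 1, scene_t, log)
            queues[b].clear()
            scene_t += cfg.secondary_dwell_frames
            if len(events) >= cfg.max_events:
                log.add("run_end", reason="max_events", n_events=len(events))
                return events, log
        scene_t += 1
    log.add("run_end", reason="max_primary_frames", n_events=len(events))
    return events, log


_RUNNERS = {
    "tiled_fixed": run_tiled_fixed,
    "block_fixed": run_block_fixed,
    "tiled_live": run_tiled_live,
    "block_live": run_block_live,
}


def run_experiment(cfg: ExperimentConfig, backend, detector: Optional[Callable] = None):
    """Dispatch to the state machine matching ``cfg.mode``."""
    if detector is None:
        from .detectors import get_detector

        detector = get_detector(cfg.detector)
    return _RUNNERS[cfg.mode](cfg, backend, detector)


# --------------------------------------------------------------------------
# scan-plan accounting


def estimate_scan_plan(
    n_tiles: int,
    n_channels: int = 1,
    n_z: int = 1,
    images_per_fov: Optional[int] = None,
    bytes_per_image: Optional[int] = None,
) -> dict:
    """Data-volume arithmetic for a hypothetical full-resolution scan.

    ``n_images = n_tiles * n_channels * n_z`` or, when ``images_per_fov`` is
    given, ``n_tiles * images_per_fov``."""
    if min(n_tiles, n_channels, n_z) < 0:
        raise ValueError("scan-plan inputs must be non-negative")
    if images_per_fov is not None:
        n_images = n_tiles * images_per_fov
    else:
        n_images = n_tiles * n_channels * n_z
    out = {"n_images": n_images, "n_fov": n_tiles}
    if bytes_per_image is not None:
        out["bytes"] = n_images * bytes_per_image
    return out


def tiles_at_secondary_resolution(n_rows: int, n_cols: int, k: int) -> int:
    """Tiles needed to cover an n_rows×n_cols primary grid at the secondary
    scan's k-fold finer sampling."""
    if k < 1 or int(k) != k:
        raise ValueError("linear resolution ratio k must be an integer >= 1")
    return (n_rows * k) * (n_cols * k)
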