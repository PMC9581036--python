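"""CAM-dialect text messaging, exchange-folder image transport and offline
replay.

The wire dialect is a documented, versioned subset of the Leica CAM command
style: one LF-terminated line of space-separated ``/key:value`` fields.
Command vocabulary: ``/cmd:{startscan, stopscan, setposition, startcycle,
stopcycle}``, notification ``/inf:scanfinished``, stage positions
``/xpos /ypos /zpos`` as decimal µm text.  Unknown commands are passed
through for forward compatibility.  Because fields are space-separated,
neither keys nor values may contain whitespace (a dialect restriction).
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DIALECT_VERSION",
    "Message",
    "encode_message",
    "decode_message",
    "TileFileName",
    "format_tile_name",
    "parse_tile_name",
    "collect_scan",
    "ReplayExhausted",
    "ReplayBackend",
    "replay_source",
]

DIALECT_VERSION = "1.0"

Message = dict  # ordered key -> value, all text


def encode_message(msg: Message) -> str:
    """Encode a message as one LF-terminated '/key:value ...' line."""
    if not msg:
        raise ValueError("cannot encode an empty message")
    parts = []
    for k, v in msg.items():
        k, v = str(k), str(v)
        if not k or re.search(r"\s", k):
            raise ValueError(f"invalid key {k!r}: empty or contains whitespace")
        if re.search(r"\s", v):
            raise ValueError(f"invalid value {v!r} for key {k!r}: contains whitespace")
        parts.append(f"/{k}:{v}")
    return " ".join(parts) + "\n"


def decode_message(line: str) -> Message:
    """Exact inverse of :func:`encode_message`."""
    line = line.rstrip("\n")
    if not line:
        raise ValueError("empty message line")
    msg: Message = {}
    for field in line.split(" "):
        if not field.startswith("/") or ":" not in field:
            raise ValueError(f"malformed field {field!r} (expected /key:value)")
        k, v = field[1:].split(":", 1)
        if not k:
            raise ValueError(f"malformed field {field!r}: empty key")
        msg[k] = v
    return msg


@dataclass(frozen=True)
class TileFileName:
    """Indices identifying one exchanged tile image."""

    experiment: str
    t_index: int
    block_index: int
    row: int
    col: int
    channel: int
    z_index: int

    def __post_init__(self) -> None:
        for f in ("t_index", "block_index", "row", "col", "channel", "z_index"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


_TILE_RE = re.compile(
    r"^(?P<exp>.+)_t(?P<t>\d{4,})_b(?P<b>\d{3,})_r(?P<r>\d{2,})"
    r"_c(?P<c>\d{2,})_ch(?P<ch>\d{2,})_z(?P<z>\d{3,})\.tif$"
)


def format_tile_name(name: TileFileName) -> str:
    return (
        f"{name.experiment}_t{name.t_index:04d}_b{name.block_index:03d}"
        f"_r{name.row:02d}_c{name.col:02d}_ch{name.channel:02d}_z{name.z_index:03d}.tif"
    )


def parse_tile_name(filename: str) -> TileFileName:
    m = _TILE_RE.match(filename)
    if m is None:
        raise ValueError(f"file name {filename!r} does not follow the tile convention")
    return TileFileName(
        experiment=m.group("exp"),
        t_index=int(m.group("t")),
        block_index=int(m.group("b")),
        row=int(m.group("r")),
        col=int(m.group("c")),
        channel=int(m.group("ch")),
        z_index=int(m.group("z")),
    )


def collect_scan(
    folder,
    expected: Iterable[TileFileName],
    timeout_s: float = 30.0,
    poll_s: float = 0.05,
) -> dict[TileFileName, np.ndarray]:
    """Poll the exchange folder until every expected tile exists and is
    stable (size unchanged across two polls), then load them all.

    Raises TimeoutError listing the missing files.
    """
    import tifffile

    folder = Path(folder)
    expected = list(expected)
    deadline = time.monotonic() + timeout_s
    last_sizes: dict[str, int] = {}
    while True:
        missing, unstable = [], []
        sizes: dict[str, int] = {}
        for name in expected:
            p = folder / format_tile_name(name)
            if not p.exists():
                missing.append(p.name)
                continue
            size = p.stat().st_size
            sizes[p.name] = size
            if last_sizes.get(p.name) != size:
                unstable.append(p.name)
        if not missing and not unstable:
            return {n: tifffile.imread(folder / format_tile_name(n)) for n in expected}
        if time.monotonic() >= deadline:
            raise TimeoutError(
                f"scan incomplete after {timeout_s} s; missing: {missing}, unstable: {unstable}"
            )
        last_sizes = sizes
        time.sleep(poll_s)


class ReplayExhausted(Exception):
    """Raised when a replay source has no frames beyond the requested t."""


class ReplayBackend:
    """Acquisition backend serving previously recorded primary-scan tiles.

    Drives the engine identically to a live backend: primary frames are read
    from the folder in ``t_index`` order; secondary acquisitions (whose images
    were never part of the primary record) return blank stacks so the run's
    control flow and log are reproduced exactly.
    """

    def __init__(self, folder) -> None:
        self.folder = Path(folder)
        self.index: dict[tuple[int, int], list[TileFileName]] = {}
        for p in sorted(self.folder.iterdir()):
            if not p.name.endswith(".tif"):
                continue
            try:
                name = parse_tile_name(p.name)
            except ValueError:
                continue  # non-conforming files are ignored
            self.index.setdefault((name.t_index, name.block_index), []).append(name)
        if not self.index:
            raise ValueError(f"{folder}: no conforming tiles found, nothing to replay")
        self.max_t = max(t for t, _ in self.index)

    def scan_primary(self, grid, channels, n_z, t_index, block_index=0):
        import tifffile

        key = (t_index, block_index)
        if t_index > self.max_t or key not in self.index:
            raise ReplayExhausted(f"no recorded frame for t={t_index}, block={block_index}")
        tiles: dict[tuple[int, int], dict[int, np.ndarray]] = {}
        by_tile: dict[tuple[int, int, int], list[TileFileName]] = {}
        for name in self.index[key]:
            by_tile.setdefault((name.row, name.col, name.channel), []).append(name)
        for (r, c, ch), names in by_tile.items():
            stack = np.stack(
                [
                    tifffile.imread(self.folder / format_tile_name(n))
                    for n in sorted(names, key=lambda n: n.z_index)
                ]
            )
            tiles.setdefault((r, c), {})[ch] = stack
        return tiles

    def acquire_secondary(self, position, channels: Sequence[int], n_z: int, t_index: int):
        blank = np.zeros((n_z, 1, 1), dtype=np.uint8)
        return {ch: blank for ch in channels}


def replay_source(folder) -> ReplayBackend:
    """Open a recorded primary-scan folder as an acquisition backend."""
    return ReplayBackend(folder)
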