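"""Virtual microscope: renders multi-channel z-stack tiles of parameterised
synthetic fluorescence samples with exportable ground truth.

The simulator emulates the sample types the detection workflows target:

* asynchronously growing nuclei with a rare condensed (mitotic) fraction at
  elevated DNA-stain intensity,
* nuclei carrying per-channel FISH spots drawn from configured phenotype
  fractions,
* micropattern grids (disk/cross/H/Y shapes) with 0/1/≥2 nuclei per pattern,
* live tubulin-channel scenes with Brownian cell motion and scheduled
  nuclear-envelope-breakdown (NEB) events in which the formerly dark nuclear
  disk fills with tubulin-level intensity.

Objects are rendered as 2D Gaussians (point-like objects) or rasterised
shapes blurred by the PSF, attenuated per µm of defocus, with optional
Poisson + Gaussian read noise.  The primary (survey) resolution mode renders
at the full secondary sampling and then applies an exact k×k block mean —
camera binning — so primary and secondary renders are mutually consistent by
construction.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .core import StagePosition, TileGrid

__all__ = [
    "NoiseSpec",
    "OpticsSpec",
    "NucleiSpec",
    "FishSpec",
    "MicropatternSpec",
    "LiveSpec",
    "SampleSpec",
    "OpticsState",
    "SceneObject",
    "Scene",
    "GroundTruth",
    "build_scene",
    "render",
    "SimulatorBackend",
    "CamServer",
    "grid_for_scene",
]


# --------------------------------------------------------------------------
# sample specification


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise: additive Gaussian read noise plus optional Poisson
    shot noise (``poisson_scale`` photons per intensity unit; 0 disables)."""

    read_sigma: float = 2.0
    poisson_scale: float = 0.0


@dataclass(frozen=True)
class OpticsSpec:
    """Scene-wide optical model shared by every render."""

    psf_sigma_um: float = 0.5
    z_attenuation_per_um: float = 0.3  # exp(-a*|dz|) amplitude decay
    bit_depth: int = 8
    background: float = 8.0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class NucleiSpec:
    """Fixed-sample nuclei population (DNA channel).

    ``condensed_fraction`` of the nuclei are condensed/mitotic: brighter by
    ``condensed_intensity_ratio`` and spatially tighter, emulating DNA
    condensation."""

    count: int = 200
    intensity: float = 40.0
    sigma_um: float = 3.0
    condensed_fraction: float = 0.025
    condensed_intensity_ratio: float = 3.0
    condensed_sigma_um: float = 1.8
    min_separation_um: float = 15.0

    def __post_init__(self) -> None:
        if self.count < 0 or not (0 <= self.condensed_fraction <= 1):
            raise ValueError("invalid nuclei population")
        if self.condensed_intensity_ratio <= 1:
            raise ValueError("condensed_intensity_ratio must be > 1")


@dataclass(frozen=True)
class FishSpec:
    """Per-nucleus FISH spots on ``n_channels`` extra channels.

    ``phenotypes`` is a list of (per-channel spot counts, fraction, label);
    fractions must sum to 1.  Each nucleus is assigned one phenotype."""

    n_channels: int = 3
    phenotypes: Sequence[tuple[tuple[int, ...], float, str]] = (
        ((1, 1, 1), 0.9, "normal"),
        ((1, 0, 1), 0.1, "missing-ch2"),
    )
    spot_intensity: float = 120.0
    spot_sigma_um: float = 0.6
    spot_min_separation_um: float = 3.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one FISH channel")
        total = sum(f for _, f, _ in self.phenotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phenotype fractions must sum to 1, got {total}")
        for counts, _, _ in self.phenotypes:
            if len(counts) != self.n_channels:
                raise ValueError("phenotype count tuple length != n_channels")


@dataclass(frozen=True)
class MicropatternSpec:
    """A block of printed micropatterns on a regular grid.

    Pattern shapes are rendered in their own label channel; occupancy is the
    number of nuclei seeded on each pattern, drawn from
    ``occupancy_probs``."""

    n_rows: int = 12
    n_cols: int = 12
    pitch_um: float = 30.0
    pattern_radius_um: float = 8.0
    intensity: float = 60.0
    occupancy_probs: dict = field(default_factory=lambda: {0: 0.55, 1: 0.15, 2: 0.30})
    shapes: Sequence[str] = ("disk", "cross", "H", "Y")
    nucleus_intensity: float = 50.0
    nucleus_sigma_um: float = 2.5

    def __post_init__(self) -> None:
        total = sum(self.occupancy_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy probabilities must sum to 1, got {total}")


@dataclass(frozen=True)
class LiveSpec:
    """Live tubulin-channel scene with scheduled NEB events.

    Each cell is a bright cytoplasm disk with a dark nuclear disk; from its
    NEB onset frame on, the nuclear disk fills at ``neb_fill_level``."""

    n_nuclei: int = 3
    nucleus_radius_um: float = 5.0
    cyto_radius_um: float = 10.0
    tubulin_level: float = 60.0
    nucleus_dark_level: float = 15.0
    neb_fill_level: float = 90.0
    brownian_sigma_um: float = 0.0
    neb_onsets: Sequence[tuple[int, int]] = ()  # (nucleus_id, onset frame)
    min_separation_um: float = 30.0

    def __post_init__(self) -> None:
        if self.neb_fill_level <= self.nucleus_dark_level:
            raise ValueError("neb_fill_level must exceed nucleus_dark_level")


@dataclass(frozen=True)
class SampleSpec:
    """Full description of a synthetic sample; the seed fixes everything."""

    field_w_um: float = 400.0
    field_h_um: float = 400.0
    seed: int = 0
    nuclei: Optional[NucleiSpec] = None
    fish: Optional[FishSpec] = None
    micropattern: Optional[MicropatternSpec] = None
    live: Optional[LiveSpec] = None
    optics: OpticsSpec = field(default_factory=OpticsSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)


@dataclass(frozen=True)
class OpticsState:
    """Current acquisition settings of the (virtual) microscope.

    ``pixel_size_um`` is the full secondary-scan sampling; the primary scan
    uses ``k``-fold camera binning, i.e. an effective pixel of
    ``k * pixel_size_um``.  ``fov_px`` is the raster side length *after*
    binning (the tile size handed to the analysis)."""

    pixel_size_um: float = 1.0
    fov_px: int = 64
    k: int = 1
    n_z: int = 1
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError("binning factor k must be an integer >= 1")
        if self.pixel_size_um <= 0 or self.fov_px < 1 or self.n_z < 1:
            raise ValueError("invalid optics state")

    @property
    def effective_pixel_um(self) -> float:
        return self.pixel_size_um * self.k


# --------------------------------------------------------------------------
# scene


@dataclass
class SceneObject:
    kind: str  # interphase | condensed | fish_spot | pattern | cell | ...
    x_um: float
    y_um: float
    z_um: float
    amplitude: float
    channel: int
    sigma_um: float = 0.0  # Gaussian objects
    shape: str = "gauss"  # gauss | disk | cross | H | Y
    radius_um: float = 0.0  # rasterised shapes
    object_id: int = -1
    neb_onset: Optional[int] = None  # live nuclear disks only
    moving: bool = False


class GroundTruth:
    """One record per rendered biological object (the test oracle)."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, **record) -> None:
        self.records.append(record)

    def of_kind(self, kind: str) -> list[dict]:
        return [r for r in self.records if r["kind"] == kind]

    def dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def save(self, path) -> None:
        self.dataframe().to_csv(path, index=False)


class Scene:
    """Rendered world: static and moving objects plus the sample spec."""

    def __init__(self, spec: SampleSpec, objects: list[SceneObject]) -> None:
        self.spec = spec
        self.objects = objects
        self.seed = spec.seed
        self._offsets_cache: dict[int, np.ndarray] = {}
        self._n_moving = sum(1 for o in objects if o.moving)

    # -- live motion -------------------------------------------------------
    def _motion_offsets(self, t_index: int) -> np.ndarray:
        """Cumulative Brownian (dx, dy) per moving object at frame t."""
        if self._n_moving == 0 or t_index <= 0:
            return np.zeros((self._n_moving, 2))
        if t_index in self._offsets_cache:
            return self._offsets_cache[t_index]
        prev = self._motion_offsets(t_index - 1)
        sigma = self.spec.live.brownian_sigma_um if self.spec.live else 0.0
        rng = np.random.default_rng([self.seed % (2**31), 7, t_index])
        step = rng.normal(0.0, sigma, size=(self._n_moving, 2))
        cur = prev + step
        self._offsets_cache[t_index] = cur
        return cur

    def object_position(self, obj: SceneObject, t_index: int) -> tuple[float, float]:
        """(x, y) of an object at frame t (moving objects share their cell's
        Brownian track via object_id)."""
        if not obj.moving:
            return obj.x_um, obj.y_um
        moving_ids = [o.object_id for o in self.objects if o.moving]
        # all shape objects of one cell share object_id -> same offset row
        unique_ids = sorted(set(moving_ids))
        offsets = self._motion_offsets(t_index)
        row = unique_ids.index(obj.object_id)
        # offsets are indexed per moving *object*; collapse to per-cell by
        # using the first occurrence of each id
        first_rows = {}
        for i, oid in enumerate(moving_ids):
            first_rows.setdefault(oid, i)
        dx, dy = offsets[first_rows[obj.object_id]]
        del row
        return obj.x_um + dx, obj.y_um + dy


# --------------------------------------------------------------------------
# scene construction


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    w: float,
    h: float,
    margin: float,
    min_sep: float,
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    """Uniform positions with minimum mutual separation (rejection)."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} objects with separation {min_sep} µm "
                f"in a {w}x{h} µm field (density too high)"
            )
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all(math.hypot(x - px, y - py) >= min_sep for px, py in pts):
            pts.append((x, y))
    return pts


def build_scene(spec: SampleSpec) -> tuple[Scene, GroundTruth]:
    """Instantiate all object populations of a spec with its seeded RNG."""
    rng = np.random.default_rng(spec.seed)
    objects: list[SceneObject] = []
    truth = GroundTruth()
    w, h = spec.field_w_um, spec.field_h_um
    next_id = 0

    if spec.nuclei is not None:
        ns = spec.nuclei
        pts = _sample_positions(rng, ns.count, w, h, 3 * ns.sigma_um, ns.min_separation_um)
        n_condensed = int(round(ns.count * ns.condensed_fraction))
        condensed_idx = set(rng.choice(ns.count, size=n_condensed, replace=False)) if n_condensed else set()
        for i, (x, y) in enumerate(pts):
            condensed = i in condensed_idx
            obj = SceneObject(
                kind="condensed" if condensed else "interphase",
                x_um=x,
                y_um=y,
                z_um=0.0,
                amplitude=ns.intensity * (ns.condensed_intensity_ratio if condensed else 1.0),
                channel=0,
                sigma_um=ns.condensed_sigma_um if condensed else ns.sigma_um,
                object_id=next_id,
            )
            objects.append(obj)
            truth.add(kind=obj.kind, x_um=x, y_um=y, z_um=0.0, object_id=next_id, label=obj.kind)
            next_id += 1

            if spec.fish is not None:
                fs = spec.fish
                fracs = np.array([f for _, f, _ in fs.phenotypes])
                pidx = int(rng.choice(len(fs.phenotypes), p=fracs))
                counts, _, label = fs.phenotypes[pidx]
                for ch, n_spots in enumerate(counts, start=1):
                    placed: list[tuple[float, float]] = []
                    guard = 0
                    while len(placed) < n_spots:
                        guard += 1
                        if guard > 1000:
                            raise RuntimeError("cannot place FISH spots with requested separation")
                        # keep spots well inside the segmentable nucleus core
                        r = (ns.sigma_um * 0.8) * math.sqrt(rng.uniform())
                        th = rng.uniform(0, 2 * math.pi)
                        sx, sy = x + r * math.cos(th), y + r * math.sin(th)
                        if all(
                            math.hypot(sx - qx, sy - qy) >= fs.spot_min_separation_um
                            for qx, qy in placed
                        ):
                            placed.append((sx, sy))
                    for sx, sy in placed:
                        objects.append(
                            SceneObject(
                                kind="fish_spot",
                                x_um=sx,
                                y_um=sy,
                                z_um=0.0,
                                amplitude=fs.spot_intensity,
                                channel=ch,
                                sigma_um=fs.spot_sigma_um,
                                object_id=next_id - 1,
                            )
                        )
                truth.records[-1]["spot_counts"] = "-".join(str(c) for c in counts)
                truth.records[-1]["label"] = label

    if spec.micropattern is not None:
        mp = spec.micropattern
        occ_keys = sorted(mp.occupancy_probs)
        occ_p = np.array([mp.occupancy_probs[k] for k in occ_keys])
        x0 = (w - (mp.n_cols - 1) * mp.pitch_um) / 2.0
        y0 = (h - (mp.n_rows - 1) * mp.pitch_um) / 2.0
        for r in range(mp.n_rows):
            for c in range(mp.n_cols):
                x, y = x0 + c * mp.pitch_um, y0 + r * mp.pitch_um
                shape = mp.shapes[(r + c) % len(mp.shapes)]
                occupancy = int(occ_keys[int(rng.choice(len(occ_keys), p=occ_p))])
                objects.append(
                    SceneObject(
                        kind="pattern",
                        x_um=x,
                        y_um=y,
                        z_um=0.0,
                        amplitude=mp.intensity,
                        channel=0,
                        shape=shape,
                        radius_um=mp.pattern_radius_um,
                        object_id=next_id,
                    )
                )
                ang = rng.uniform(0, 2 * math.pi)
                for j in range(occupancy):
                    # nuclei spread evenly on the pattern without overlapping
                    # (nuclei are stiff bodies; centers sit >= one diameter apart)
                    rad = 0.0 if occupancy == 1 else mp.pattern_radius_um * 0.55
                    nx = x + rad * math.cos(ang + j * 2 * math.pi / max(occupancy, 1))
                    ny = y + rad * math.sin(ang + j * 2 * math.pi / max(occupancy, 1))
                    objects.append(
                        SceneObject(
                            kind="pattern_nucleus",
                            x_um=nx,
                            y_um=ny,
                            z_um=0.0,
                            amplitude=mp.nucleus_intensity,
                            channel=1,
                            sigma_um=mp.nucleus_sigma_um,
                            object_id=next_id,
                        )
                    )
                truth.add(
                    kind="pattern",
                    x_um=x,
                    y_um=y,
                    z_um=0.0,
                    object_id=next_id,
                    occupancy=occupancy,
                    label=shape,
                )
                next_id += 1

    if spec.live is not None:
        lv = spec.live
        onsets = dict(lv.neb_onsets)
        pts = _sample_positions(rng, lv.n_nuclei, w, h, lv.cyto_radius_um + 5, lv.min_separation_um)
        moving = lv.brownian_sigma_um > 0
        for i, (x, y) in enumerate(pts):
            onset = onsets.get(i)
            objects.append(
                SceneObject(
                    kind="cell",
                    x_um=x,
                    y_um=y,
                    z_um=0.0,
                    amplitude=lv.tubulin_level,
                    channel=0,
                    shape="disk",
                    radius_um=lv.cyto_radius_um,
                    object_id=next_id,
                    moving=moving,
                )
            )
            objects.append(
                SceneObject(
                    kind="live_nucleus",
                    x_um=x,
                    y_um=y,
                    z_um=0.0,
                    amplitude=lv.nucleus_dark_level - lv.tubulin_level,  # dark hole
                    channel=0,
                    shape="disk",
                    radius_um=lv.nucleus_radius_um,
                    object_id=next_id,
                    neb_onset=onset,
                    moving=moving,
                )
            )
            truth.add(
                kind="live_nucleus",
                x_um=x,
                y_um=y,
                z_um=0.0,
                object_id=next_id,
                onset_frame=onset if onset is not None else -1,
                label="neb" if onset is not None else "quiet",
            )
            next_id += 1

    return Scene(spec, objects), truth


# --------------------------------------------------------------------------
# rendering


def _shape_mask(shape: str, radius_px: float, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Boolean mask of a pattern/cell shape on centered pixel coordinates."""
    r = radius_px
    if shape == "disk":
        return yy * yy + xx * xx <= r * r
    arm = max(r / 3.0, 1.0)
    if shape == "cross":
        return ((np.abs(xx) <= arm) & (np.abs(yy) <= r)) | ((np.abs(yy) <= arm) & (np.abs(xx) <= r))
    if shape == "H":
        return (
            ((np.abs(xx + r * 0.7) <= arm) & (np.abs(yy) <= r))
            | ((np.abs(xx - r * 0.7) <= arm) & (np.abs(yy) <= r))
            | ((np.abs(yy) <= arm) & (np.abs(xx) <= r * 0.7))
        )
    if shape == "Y":
        d1 = np.abs(xx * math.cos(math.radians(30)) - yy * math.sin(math.radians(30)))
        d2 = np.abs(xx * math.cos(math.radians(150)) - yy * math.sin(math.radians(150)))
        upper = (yy <= 0) & (yy * yy + xx * xx <= r * r) & ((d1 <= arm) | (d2 <= arm))
        stem = (np.abs(xx) <= arm) & (yy >= 0) & (yy <= r)
        return upper | stem
    raise ValueError(f"unknown shape {shape!r}")


def render(
    scene: Scene,
    pos: StagePosition,
    channel: int,
    z_index: int = 0,
    t_index: int = 0,
    optics: OpticsState = OpticsState(),
    noise: bool = True,
) -> np.ndarray:
    """Render one tile: the FOV of side ``fov_px * k * pixel_size_um`` µm
    centered on ``pos``, binned to ``fov_px`` pixels.

    Out-of-scene positions yield a blank (background + noise) tile.
    """
    spec = scene.spec
    pix = optics.pixel_size_um
    n_fine = optics.fov_px * optics.k
    half_um = n_fine * pix / 2.0
    # fine-grid pixel centers in stage coordinates
    ys = pos.y_um - half_um + (np.arange(n_fine) + 0.5) * pix
    xs = pos.x_um - half_um + (np.arange(n_fine) + 0.5) * pix
    z_slice_um = pos.z_um + (z_index - (optics.n_z - 1) / 2.0) * optics.z_step_um

    gauss_layer = np.zeros((n_fine, n_fine))
    shape_layer = np.zeros((n_fine, n_fine))

    for obj in scene.objects:
        if obj.channel != channel:
            continue
        ox, oy = scene.object_position(obj, t_index)
        zfac = math.exp(-spec.optics.z_attenuation_per_um * abs(z_slice_um - obj.z_um))
        amp = obj.amplitude * zfac
        if obj.kind == "live_nucleus" and obj.neb_onset is not None and t_index >= obj.neb_onset:
            # NEB: the dark nuclear disk fills with tubulin-level signal
            lv = spec.live
            amp = (lv.neb_fill_level - lv.tubulin_level) * zfac
        if obj.shape == "gauss":
            s_px = obj.sigma_um / pix
            cy, cx = (oy - ys[0]) / pix, (ox - xs[0]) / pix
            r = int(math.ceil(4 * s_px)) + 1
            y0, y1 = int(cy) - r, int(cy) + r + 1
            x0, x1 = int(cx) - r, int(cx) + r + 1
            if y1 <= 0 or x1 <= 0 or y0 >= n_fine or x0 >= n_fine:
                continue
            y0, y1 = max(y0, 0), min(y1, n_fine)
            x0, x1 = max(x0, 0), min(x1, n_fine)
            gy = (np.arange(y0, y1) - cy)[:, None]
            gx = (np.arange(x0, x1) - cx)[None, :]
            gauss_layer[y0:y1, x0:x1] += amp * np.exp(-(gy * gy + gx * gx) / (2 * s_px * s_px))
        else:
            r_px = obj.radius_um / pix
            cy, cx = (oy - ys[0]) / pix, (ox - xs[0]) / pix
            rr = int(math.ceil(r_px)) + 2
            y0, y1 = int(cy) - rr, int(cy) + rr + 1
            x0, x1 = int(cx) - rr, int(cx) + rr + 1
            if y1 <= 0 or x1 <= 0 or y0 >= n_fine or x0 >= n_fine:
                continue
            y0, y1 = max(y0, 0), min(y1, n_fine)
            x0, x1 = max(x0, 0), min(x1, n_fine)
            yy = (np.arange(y0, y1) - cy)[:, None]
            xx = (np.arange(x0, x1) - cx)[None, :]
            mask = _shape_mask(obj.shape, r_px, yy + np.zeros_like(xx), xx + np.zeros_like(yy))
            shape_layer[y0:y1, x0:x1] += amp * mask

    psf_px = spec.optics.psf_sigma_um / pix
    if shape_layer.any():
        shape_layer = ndi.gaussian_filter(shape_layer, psf_px)
    img = spec.optics.background + gauss_layer + shape_layer

    if optics.k > 1:
        img = img.reshape(optics.fov_px, optics.k, optics.fov_px, optics.k).mean(axis=(1, 3))

    if noise:
        rng = np.random.default_rng(
            [
                scene.seed % (2**31),
                11,
                t_index,
                channel,
                z_index,
                int(abs(pos.x_um) * 1000) % (2**31),
                int(abs(pos.y_um) * 1000) % (2**31),
            ]
        )
        if spec.noise.poisson_scale > 0:
            img = rng.poisson(np.maximum(img, 0) * spec.noise.poisson_scale) / spec.noise.poisson_scale
        if spec.noise.read_sigma > 0:
            img = img + rng.normal(0.0, spec.noise.read_sigma, img.shape)

    vmax = 2 ** spec.optics.bit_depth - 1
    img = np.clip(np.rint(img), 0, vmax)
    return img.astype(np.uint8 if spec.optics.bit_depth == 8 else np.uint16)


def grid_for_scene(spec: SampleSpec, optics: OpticsState, z_um: float = 0.0) -> TileGrid:
    """Tile grid covering the scene field at the given optics' effective
    (binned) sampling, anchored at the field's top-left corner."""
    tile_um = optics.fov_px * optics.effective_pixel_um
    n_cols = max(1, math.ceil(spec.field_w_um / tile_um))
    n_rows = max(1, math.ceil(spec.field_h_um / tile_um))
    return TileGrid(
        origin=StagePosition(tile_um / 2.0, tile_um / 2.0, z_um),
        n_rows=n_rows,
        n_cols=n_cols,
        tile_h_px=optics.fov_px,
        tile_w_px=optics.fov_px,
        pixel_size_um=optics.effective_pixel_um,
    )


# --------------------------------------------------------------------------
# acquisition backends


class SimulatorBackend:
    """In-process acquisition backend rendering from a scene.

    Implements the backend contract the engine drives: primary tile grids and
    secondary stacks centered on targets.  If ``record_folder`` is set, every
    primary tile is additionally written as a TIFF under the exchange-folder
    naming convention so a run can be replayed offline.
    """

    def __init__(
        self,
        scene: Scene,
        primary_optics: OpticsState,
        secondary_optics: Optional[OpticsState] = None,
        record_folder=None,
        experiment_id: str = "exp",
    ) -> None:
        self.scene = scene
        self.primary_optics = primary_optics
        self.secondary_optics = secondary_optics or OpticsState(
            pixel_size_um=primary_optics.pixel_size_um, fov_px=primary_optics.fov_px, k=1
        )
        self.record_folder = record_folder
        self.experiment_id = experiment_id

    def scan_primary(
        self,
        grid: TileGrid,
        channels: Sequence[int],
        n_z: int,
        t_index: int,
        block_index: int = 0,
    ) -> dict[tuple[int, int], dict[int, np.ndarray]]:
        """Acquire one primary frame: z-stacks for every tile and channel.

        Returns {(row, col): {channel: stack (n_z, h, w)}}.
        """
        optics = OpticsState(
            pixel_size_um=self.primary_optics.pixel_size_um,
            fov_px=grid.tile_w_px,
            k=self.primary_optics.k,
            n_z=n_z,
            z_step_um=self.primary_optics.z_step_um,
        )
        tiles: dict[tuple[int, int], dict[int, np.ndarray]] = {}
        for r, c in grid.scan_order():
            center = grid.tile_center(r, c)
            per_channel: dict[int, np.ndarray] = {}
            for ch in channels:
                stack = np.stack(
                    [
                        render(self.scene, center, ch, z_index=z, t_index=t_index, optics=optics)
                        for z in range(n_z)
                    ]
                )
                per_channel[ch] = stack
                if self.record_folder is not None:
                    self._record(stack, t_index, block_index, r, c, ch)
            tiles[(r, c)] = per_channel
        return tiles

    def _record(self, stack: np.ndarray, t: int, b: int, r: int, c: int, ch: int) -> None:
        import tifffile

        from .protocol import TileFileName, format_tile_name

        for z in range(stack.shape[0]):
            name = format_tile_name(
                TileFileName(self.experiment_id, t_index=t, block_index=b, row=r, col=c, channel=ch, z_index=z)
            )
            tifffile.imwrite(str(self.record_folder) + "/" + name, stack[z])

    def acquire_secondary(
        self,
        position: StagePosition,
        channels: Sequence[int],
        n_z: int,
        t_index: int,
    ) -> dict[int, np.ndarray]:
        """Acquire one secondary (full-resolution) stack centered on a target."""
        optics = OpticsState(
            pixel_size_um=self.secondary_optics.pixel_size_um,
            fov_px=self.secondary_optics.fov_px,
            k=1,
            n_z=n_z,
            z_step_um=self.secondary_optics.z_step_um,
        )
        return {
            ch: np.stack(
                [
                    render(self.scene, position, ch, z_index=z, t_index=t_index, optics=optics)
                    for z in range(n_z)
                ]
            )
            for ch in channels
        }


class CamServer:
    """Acquisition server speaking the CAM text dialect over any line
    transport, exchanging images through a folder.

    ``handle_line`` processes one command and returns the reply lines; a TCP
    loop (or a test) feeds it lines and relays replies.  Malformed commands
    produce an error reply and the server keeps running.
    """

    def __init__(
        self,
        scene: Scene,
        optics: OpticsState,
        exchange_folder,
        grid: TileGrid,
        channels: Sequence[int] = (0,),
        n_z: int = 1,
        experiment_id: str = "exp",
    ) -> None:
        self.backend = SimulatorBackend(
            scene, optics, record_folder=exchange_folder, experiment_id=experiment_id
        )
        self.grid = grid
        self.channels = list(channels)
        self.n_z = n_z
        self.position = StagePosition(0.0, 0.0, 0.0)
        self.t_index = 0
        self.cycling = False
        self.stopped = False

    def handle_line(self, line: str) -> list[str]:
        from .protocol import decode_message, encode_message

        try:
            msg = decode_message(line)
        except ValueError as e:
            return [encode_message({"err": "parse", "detail": str(e).replace(" ", "_")})]
        cmd = msg.get("cmd", "")
        if cmd == "setposition":
            try:
                self.position = StagePosition(
                    float(msg.get("xpos", self.position.x_um)),
                    float(msg.get("ypos", self.position.y_um)),
                    float(msg.get("zpos", self.position.z_um)),
                )
            except ValueError:
                return [encode_message({"err": "badposition"})]
            return [encode_message({"inf": "positionset"})]
        if cmd == "startscan":
            self.backend.scan_primary(self.grid, self.channels, self.n_z, self.t_index)
            self.t_index += 1
            return [encode_message({"inf": "scanfinished"})]
        if cmd == "stopscan":
            return [encode_message({"inf": "scanstopped"})]
        if cmd == "startcycle":
            self.cycling = True
            return [encode_message({"inf": "cyclestarted"})]
        if cmd == "stopcycle":
            self.cycling = False
            self.stopped = True
            return [encode_message({"inf": "cyclestopped"})]
        # unknown commands pass through unanswered (forward compatibility)
        return []

    def serve(self, lines) -> list[str]:
        """Process an iterable of command lines until stopcycle; returns all
        reply lines in order."""
        replies: list[str] = []
        for line in lines:
            replies.extend(self.handle_line(line))
            if self.stopped:
                break
        return replies
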