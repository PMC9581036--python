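"""The four built-in target-detection workflows and the detector registry.

Each workflow is a pure, deterministic function from primary-scan maps to a
:class:`~smartscan.core.TargetList`.  Detectors are addressable by name
through a plug-in registry so new workflows can be appended without touching
the engine; the built-ins are registered as ``metaphase``, ``fish``,
``micropattern`` and ``mitosis_live``.

Registry calling convention: ``fn(frames, grid, params) -> TargetList`` where
``frames`` is the queue of primary maps, oldest first, each a mapping
``channel -> 2D array``.  Fixed-sample workflows read only ``frames[-1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.morphology import closing, disk
from skimage.segmentation import watershed

from .core import Target, TargetList, TileGrid, dedup_targets, map_pixel_to_stage
from .imgops import (
    find_particles,
    local_minima,
    log_filter,
    median_filter,
    remove_outliers,
    subtract_clamped,
    threshold_global,
    threshold_nonzero,
)

__all__ = [
    "DetectorError",
    "FishSignature",
    "merge_params",
    "detect_metaphase",
    "detect_fish_phenotypes",
    "detect_isolated_on_pattern",
    "detect_mitosis_onset",
    "register_detector",
    "unregister_detector",
    "list_detectors",
    "get_detector",
    "METAPHASE_DEFAULTS",
    "FISH_DEFAULTS",
    "MICROPATTERN_DEFAULTS",
    "MITOSIS_DEFAULTS",
]


class DetectorError(ValueError):
    """Configuration or input contract violation in a detector."""


def merge_params(defaults: Mapping, overrides: Optional[Mapping]) -> dict:
    """Apply user overrides onto documented defaults; unknown keys rejected."""
    out = dict(defaults)
    for k, v in (overrides or {}).items():
        if k not in defaults:
            raise DetectorError(
                f"unknown detector parameter {k!r}; known: {sorted(defaults)}"
            )
        out[k] = v
    return out


# --------------------------------------------------------------------------
# FISH signatures


_OPS: dict[str, Callable[[int, int], bool]] = {
    "==": lambda a, b: a == b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
}


@dataclass(frozen=True)
class FishSignature:
    """Per-channel spot-count predicate defining one phenotype.

    ``rules`` is a sequence of (channel, op, count) with op in {==, >=, <=}.
    A nucleus matches iff every rule holds for its per-channel spot counts.
    """

    label: str
    rules: tuple[tuple[int, str, int], ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise DetectorError("a FISH signature must constrain at least one channel")
        for ch, op, count in self.rules:
            if op not in _OPS:
                raise DetectorError(f"unknown signature op {op!r} (use ==, >= or <=)")
            if ch < 0 or count < 0:
                raise DetectorError("signature channel and count must be >= 0")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "FishSignature":
        """Build from {'label': str, 'rules': [{'channel', 'op', 'count'}, ...]}."""
        rules = tuple(
            (int(r["channel"]), str(r["op"]), int(r["count"])) for r in cfg["rules"]
        )
        return cls(label=str(cfg["label"]), rules=rules)

    def matches(self, counts: Mapping[int, int]) -> bool:
        return all(_OPS[op](counts.get(ch, 0), n) for ch, op, n in self.rules)


# --------------------------------------------------------------------------
# helpers


def _bright_blob_minima(
    img: np.ndarray, sigma_px: float, prominence: float, min_distance_px: int
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Bright blobs as significant minima of the negated LoG response.

    Returns (points, response); deeper response = stronger blob.
    """
    resp = -log_filter(img, sigma_px)
    return local_minima(resp, prominence, min_distance_px), resp


def _region_circularity(region) -> float:
    p = region.perimeter_crofton
    return 4.0 * math.pi * region.area / (p * p) if p > 0 else 1.0


def _to_target(
    grid: TileGrid, y: float, x: float, label: str, score: float, block_index=None
) -> Target:
    pos = map_pixel_to_stage(grid, y, x)
    return Target(position=pos, label=label, score=max(float(score), 0.0), block_index=block_index)


# --------------------------------------------------------------------------
# metaphase (condensed-DNA) detection


METAPHASE_DEFAULTS: dict = {
    "dna_channel": 0,  # channel holding the DNA stain
    "median_radius_px": 2,  # speckle suppression before outlier removal
    "outlier_radius_px": 8,  # must exceed the condensed-nucleus core radius
    "outlier_threshold": 45.0,  # between interphase and condensed amplitude
    "min_area_px": 12,  # particles at least this large survive
    "max_area_px": None,
    "min_separation_um": 10.0,
}


def detect_metaphase(
    maps: Mapping[int, np.ndarray], grid: TileGrid, params: Optional[Mapping] = None
) -> TargetList:
    """Condensed (mitotic) nuclei from increased DNA-stain fluorescence.

    Pipeline: median filter → bright-outlier removal → clamped subtraction
    (isolating the small bright cores) → non-zero threshold → connected
    particles with an area gate.  Targets carry the particle's mean intensity
    in the difference image as score and are deduplicated.
    """
    p = merge_params(METAPHASE_DEFAULTS, params)
    ch = p["dna_channel"]
    if ch not in maps:
        raise DetectorError(f"DNA channel {ch} not present in the primary map")
    b = median_filter(maps[ch], p["median_radius_px"])
    c = remove_outliers(b, p["outlier_radius_px"], p["outlier_threshold"], "bright")
    d = subtract_clamped(b, c)
    mask = threshold_nonzero(d)
    particles = find_particles(
        mask, p["min_area_px"], p["max_area_px"], 0.0, intensity_img=d.astype(np.float64)
    )
    targets = TargetList(
        _to_target(grid, pt.centroid[0], pt.centroid[1], "metaphase", pt.mean_intensity)
        for pt in particles
    )
    return dedup_targets(targets, p["min_separation_um"])


# --------------------------------------------------------------------------
# FISH phenotype detection


FISH_DEFAULTS: dict = {
    "dapi_channel": 0,
    "fish_channels": (1, 2, 3),  # FISH maps, in signature channel order
    "split_min_distance_px": 8,  # watershed seed separation
    "min_area_px": 40,  # nucleus size gate ("invalid size" exclusion)
    "max_area_px": 800,
    "min_circularity": 0.6,  # nucleus shape gate ("invalid shape")
    "spot_sigma_px": 1.5,  # LoG scale matched to the spot diameter
    "spot_prominence": 10.0,
    "spot_min_distance_px": 3,
    "min_separation_um": 5.0,
}


def detect_fish_phenotypes(
    dapi_map: np.ndarray,
    fish_maps: Sequence[np.ndarray],
    grid: TileGrid,
    signatures: Sequence[FishSignature],
    params: Optional[Mapping] = None,
) -> TargetList:
    """Nuclei classified by their per-channel FISH spot counts.

    Nuclei are segmented from the DNA stain (Otsu threshold, hole filling,
    distance-transform watershed to split touching pairs), then excluded if
    they fail the area or circularity gates.  Spots are counted per FISH
    channel as significant bright-blob LoG extrema inside the nucleus mask.
    A nucleus becomes a target labeled with the FIRST matching signature
    (list order = user priority); nuclei matching none are ignored.
    """
    p = merge_params(FISH_DEFAULTS, params)
    if not signatures:
        raise DetectorError("at least one FISH signature is required")
    signatures = [
        s if isinstance(s, FishSignature) else FishSignature.from_config(s) for s in signatures
    ]
    channels = list(p["fish_channels"])[: len(fish_maps)]
    if len(fish_maps) != len(channels):
        raise DetectorError(
            f"{len(fish_maps)} FISH maps given but {len(channels)} channels configured"
        )
    max_ch = max(ch for s in signatures for ch, _, _ in s.rules)
    if max_ch > len(fish_maps):
        raise DetectorError(
            f"signature constrains channel {max_ch} but only {len(fish_maps)} FISH maps given"
        )

    # 1) nucleus segmentation
    mask = threshold_global(dapi_map, "otsu")
    mask = ndi.binary_fill_holes(mask)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=p["split_min_distance_px"], labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    labels = watershed(-distance, markers, mask=mask) if len(peaks) else measure.label(mask)

    # 3) per-channel spot maps, computed once
    spots_per_channel: list[list[tuple[int, int]]] = []
    for fmap in fish_maps:
        pts, _ = _bright_blob_minima(
            fmap, p["spot_sigma_px"], p["spot_prominence"], p["spot_min_distance_px"]
        )
        spots_per_channel.append(pts)

    dapi_f = np.asarray(dapi_map, dtype=np.float64)
    targets = TargetList()
    for region in measure.regionprops(labels, intensity_image=dapi_f):
        # 2) shape/size exclusion
        if not (p["min_area_px"] <= region.area <= p["max_area_px"]):
            continue
        if _region_circularity(region) < p["min_circularity"]:
            continue
        pixset = {(int(y), int(x)) for y, x in region.coords}
        counts = {
            ch_idx + 1: sum(1 for pt in pts if pt in pixset)
            for ch_idx, pts in enumerate(spots_per_channel)
        }
        # 4) first-match-wins phenotype assignment
        for sig in signatures:
            if sig.matches(counts):
                targets.append(
                    _to_target(
                        grid,
                        region.centroid[0],
                        region.centroid[1],
                        sig.label,
                        region.intensity_mean,
                    )
                )
                break
    return dedup_targets(targets, p["min_separation_um"])


# --------------------------------------------------------------------------
# micropattern single-occupancy detection


MICROPATTERN_DEFAULTS: dict = {
    "pattern_channel": 0,
    "dapi_channel": 1,
    "closing_radius_px": 2,  # bridge gaps in cross/H/Y shapes
    "min_pattern_area_px": 30,  # "valid pattern" size gate
    "max_pattern_area_px": 5000,
    "box_margin_px": 3,  # bounding-box dilation
    "log_sigma_px": 1.5,  # slightly under the nucleus scale: resolves touching pairs
    "nucleus_prominence": 2.0,
    "nucleus_min_distance_px": 3,
}


def detect_isolated_on_pattern(
    pattern_map: np.ndarray,
    dapi_map: np.ndarray,
    grid: TileGrid,
    params: Optional[Mapping] = None,
) -> TargetList:
    """Micropatterns occupied by exactly one nucleus.

    Patterns are segmented from their fluorescent label channel (Otsu +
    closing, area gates); nuclei are counted per dilated square pattern
    bounding box as significant LoG blob extrema of the DNA-stain map; only
    boxes holding exactly one nucleus yield a target at the box center.
    Prominence-based significance makes the counts invariant to any constant
    intensity offset.
    """
    p = merge_params(MICROPATTERN_DEFAULTS, params)
    mask = threshold_global(pattern_map, "otsu")
    if p["closing_radius_px"] > 0:
        mask = closing(mask, disk(p["closing_radius_px"]))
    labels = measure.label(mask, connectivity=2)

    nuclei, resp = _bright_blob_minima(
        dapi_map, p["log_sigma_px"], p["nucleus_prominence"], p["nucleus_min_distance_px"]
    )
    h, w = np.asarray(dapi_map).shape

    targets = TargetList()
    for region in measure.regionprops(labels):
        if not (p["min_pattern_area_px"] <= region.area <= p["max_pattern_area_px"]):
            continue
        y0, x0, y1, x1 = region.bbox
        cy, cx = (y0 + y1) / 2.0, (x0 + x1) / 2.0
        half = max(y1 - y0, x1 - x0) / 2.0 + p["box_margin_px"]
        by0, by1 = max(cy - half, 0), min(cy + half, h)
        bx0, bx1 = max(cx - half, 0), min(cx + half, w)
        inside = [(y, x) for y, x in nuclei if by0 <= y < by1 and bx0 <= x < bx1]
        if len(inside) != 1:
            continue  # exactly-one-nucleus rule
        ny, nx = inside[0]
        box = resp[int(by0) : int(by1), int(bx0) : int(bx1)]
        score = float(np.median(box) - resp[ny, nx])  # depth below box level
        targets.append(_to_target(grid, cy, cx, "isolated", score))
    return targets


# --------------------------------------------------------------------------
# live mitosis-onset (NEB) detection


MITOSIS_DEFAULTS: dict = {
    "channel": 0,  # tubulin channel
    "median_radius_px": 2,
    "threshold_method": "otsu",  # on the difference image; 'fixed' override
    "threshold_value": None,
    "min_area_px": 40,  # nucleus-like particle gates
    "max_area_px": 2000,
    "min_circularity": 0.5,
    "min_mean_diff": 15.0,  # NEB contrast floor; rejects noise-level changes
    "log_sigma_px": 3.0,  # matched to the (dark) nucleus diameter
    "nucleus_prominence": 2.0,  # dark-disk band-pass response is shallow
    "nucleus_min_distance_px": 5,
    "persistence": False,  # optional temporal-persistence gate (uses frame -3)
    "min_separation_um": 10.0,
}


def _neb_candidates(newer: np.ndarray, older: np.ndarray, p: Mapping):
    diff = subtract_clamped(newer, older)
    diff_f = median_filter(diff.astype(np.float64), p["median_radius_px"])
    mask = threshold_global(diff_f, p["threshold_method"], p["threshold_value"])
    parts = find_particles(
        mask, p["min_area_px"], p["max_area_px"], p["min_circularity"], intensity_img=diff_f
    )
    return [pt for pt in parts if pt.mean_intensity >= p["min_mean_diff"]]


def detect_mitosis_onset(
    frames: Sequence[np.ndarray], grid: TileGrid, params: Optional[Mapping] = None
) -> TargetList:
    """Nuclear-envelope breakdown from the three most recent tubulin maps.

    The newest frame minus the previous one (clamped) highlights regions
    where tubulin invaded formerly dark space; the difference is median
    filtered, thresholded, and nucleus-like particles (size, circularity,
    contrast gates) form the candidate pool.  A candidate is confirmed only
    if a nucleus — a significant LoG minimum of the *previous* frame, where
    the nucleus was still dark — lies inside its pixel set.  The optional
    persistence mode additionally requires overlap with a candidate from the
    previous frame pair (frames[-3] vs frames[-2]); it is OFF by default.
    """
    p = merge_params(MITOSIS_DEFAULTS, params)
    if len(frames) != 3:
        raise ValueError(f"exactly 3 frames required, got {len(frames)}")
    f_old, f_mid, f_new = (np.asarray(f) for f in frames)
    if not (f_old.shape == f_mid.shape == f_new.shape):
        raise ValueError("frames must share one shape")

    candidates = _neb_candidates(f_new, f_mid, p)
    if not candidates:
        return TargetList()

    nuclei = local_minima(
        log_filter(f_mid, p["log_sigma_px"]),
        p["nucleus_prominence"],
        p["nucleus_min_distance_px"],
    )
    if p["persistence"]:
        previous = _neb_candidates(f_mid, f_old, p)
        prev_pixels = {
            (int(y), int(x)) for pt in previous for y, x in pt.coords
        }

    targets = TargetList()
    for pt in candidates:
        if not any(pt.contains_point(y, x) for y, x in nuclei):
            continue  # intensity jump with no underlying nucleus: rejected
        if p["persistence"]:
            pixset = {(int(y), int(x)) for y, x in pt.coords}
            if not (pixset & prev_pixels):
                continue
        targets.append(
            _to_target(grid, pt.centroid[0], pt.centroid[1], "mitosis_onset", pt.mean_intensity)
        )
    return dedup_targets(targets, p["min_separation_um"])


# --------------------------------------------------------------------------
# registry


_REGISTRY: dict[str, Callable] = {}


def register_detector(name: str, fn: Callable) -> None:
    """Register a detector under a unique name.

    The function must follow the registry convention
    ``fn(frames, grid, params) -> TargetList``.
    """
    if name in _REGISTRY:
        raise ValueError(f"detector {name!r} already registered")
    _REGISTRY[name] = fn


def unregister_detector(name: str) -> None:
    _REGISTRY.pop(name, None)


def list_detectors() -> list[str]:
    return sorted(_REGISTRY)


def get_detector(name: str) -> Callable:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown detector {name!r}; available: {list_detectors()}") from None


def _metaphase_entry(frames, grid, params) -> TargetList:
    return detect_metaphase(frames[-1], grid, params)


def _fish_entry(frames, grid, params) -> TargetList:
    params = dict(params or {})
    signatures = params.pop("signatures", None)
    if not signatures:
        raise DetectorError("fish detector requires 'signatures' in params")
    p = merge_params(FISH_DEFAULTS, params)
    maps = frames[-1]
    if p["dapi_channel"] not in maps:
        raise DetectorError(f"DAPI channel {p['dapi_channel']} not present")
    fish_maps = [maps[ch] for ch in p["fish_channels"] if ch in maps]
    return detect_fish_phenotypes(maps[p["dapi_channel"]], fish_maps, grid, signatures, params)


def _micropattern_entry(frames, grid, params) -> TargetList:
    p = merge_params(MICROPATTERN_DEFAULTS, params)
    maps = frames[-1]
    return detect_isolated_on_pattern(
        maps[p["pattern_channel"]], maps[p["dapi_channel"]], grid, params
    )


def _mitosis_entry(frames, grid, params) -> TargetList:
    if len(frames) != 3:
        raise ValueError(f"mitosis_live requires a 3-frame queue, got {len(frames)}")
    ch = (params or {}).get("channel", MITOSIS_DEFAULTS["channel"])
    return detect_mitosis_onset([f[ch] for f in frames], grid, params)


register_detector("metaphase", _metaphase_entry)
register_detector("fish", _fish_entry)
register_detector("micropattern", _micropattern_entry)
register_detector("mitosis_live", _mitosis_entry)
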