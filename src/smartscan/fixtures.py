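"""Standard simulator fixtures: the study conditions every detection
workflow is exercised against.

Each fixture bundles a sample spec, its rendered scene and ground truth, the
matching primary-scan grid and optics, and the detector configuration a user
would put in an experiment file.  Objects are well separated so the fixtures
are unambiguous: they are the executable contract of the detectors, not a
claim about arbitrary real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .simulator import (
    FishSpec,
    LiveSpec,
    MicropatternSpec,
    NoiseSpec,
    NucleiSpec,
    OpticsSpec,
    OpticsState,
    SampleSpec,
    Scene,
    GroundTruth,
    SimulatorBackend,
    build_scene,
    grid_for_scene,
)

__all__ = ["FixtureBundle", "FIXTURE_KINDS", "make_fixture", "write_fixture"]


@dataclass
class FixtureBundle:
    """Everything needed to run one standard experiment end to end."""

    name: str
    spec: SampleSpec
    scene: Scene
    truth: GroundTruth
    primary_optics: OpticsState
    secondary_optics: OpticsState
    channels: Sequence[int]
    n_z_primary: int
    detector: str
    detector_params: dict = field(default_factory=dict)

    @property
    def grid(self):
        return grid_for_scene(self.spec, self.primary_optics)

    def backend(self, record_folder=None, experiment_id: str = "exp") -> SimulatorBackend:
        return SimulatorBackend(
            self.scene,
            self.primary_optics,
            self.secondary_optics,
            record_folder=record_folder,
            experiment_id=experiment_id,
        )


def metaphase_fixture(seed: int = 0) -> FixtureBundle:
    """Asynchronous nuclei with a rare condensed (mitotic) subpopulation.

    200 nuclei over a 400×400 µm field, 2.5% of them condensed at 3× the
    DNA-stain intensity; surveyed as a 10×10 tiled map at 2-fold binning."""
    spec = SampleSpec(
        field_w_um=400.0,
        field_h_um=400.0,
        seed=seed,
        nuclei=NucleiSpec(
            count=200,
            intensity=40.0,
            sigma_um=3.0,
            condensed_fraction=0.025,
            condensed_intensity_ratio=3.0,
            condensed_sigma_um=1.8,
            min_separation_um=15.0,
        ),
        optics=OpticsSpec(psf_sigma_um=0.4, bit_depth=8, background=8.0),
        noise=NoiseSpec(read_sigma=1.5),
    )
    scene, truth = build_scene(spec)
    return FixtureBundle(
        name="metaphase",
        spec=spec,
        scene=scene,
        truth=truth,
        primary_optics=OpticsState(pixel_size_um=0.5, fov_px=40, k=2, n_z=3, z_step_um=2.0),
        secondary_optics=OpticsState(pixel_size_um=0.5, fov_px=64, k=1, n_z=5, z_step_um=1.0),
        channels=(0,),
        n_z_primary=3,
        detector="metaphase",
        detector_params={},
    )


def fish_fixture(seed: int = 0, n_nuclei: int = 50) -> FixtureBundle:
    """Nuclei carrying per-channel FISH spots; 20% show the abnormal
    signature (1, 0, 1) — the chromosome tagged in channel 2 is missing."""
    spec = SampleSpec(
        field_w_um=300.0,
        field_h_um=300.0,
        seed=seed,
        nuclei=NucleiSpec(
            count=n_nuclei,
            intensity=40.0,
            sigma_um=3.0,
            condensed_fraction=0.0,
            min_separation_um=16.0,
        ),
        fish=FishSpec(
            n_channels=3,
            phenotypes=(
                ((1, 1, 1), 0.8, "normal"),
                ((1, 0, 1), 0.2, "missing-ch2"),
            ),
            spot_intensity=120.0,
            spot_sigma_um=0.6,
            spot_min_separation_um=3.0,
        ),
        optics=OpticsSpec(psf_sigma_um=0.3, bit_depth=8, background=6.0),
        noise=NoiseSpec(read_sigma=1.0),
    )
    scene, truth = build_scene(spec)
    return FixtureBundle(
        name="fish",
        spec=spec,
        scene=scene,
        truth=truth,
        primary_optics=OpticsState(pixel_size_um=0.5, fov_px=100, k=1, n_z=3, z_step_um=2.0),
        secondary_optics=OpticsState(pixel_size_um=0.25, fov_px=64, k=1, n_z=9, z_step_um=0.5),
        channels=(0, 1, 2, 3),
        n_z_primary=3,
        detector="fish",
        detector_params={
            "spot_sigma_px": 1.2,
            "spot_min_distance_px": 3,
            "min_area_px": 60,
            "max_area_px": 1200,
            "signatures": [
                {"label": "missing-ch2", "rules": [
                    {"channel": 1, "op": "==", "count": 1},
                    {"channel": 2, "op": "==", "count": 0},
                    {"channel": 3, "op": "==", "count": 1},
                ]},
            ],
        },
    )


def micropattern_fixture(seed: int = 0, occupancy_probs: Optional[dict] = None) -> FixtureBundle:
    """One micropattern block: a 12×12 grid of printed shapes with 0/1/≥2
    nuclei per pattern (singles at the ~15% frequency seen in practice)."""
    spec = SampleSpec(
        field_w_um=400.0,
        field_h_um=400.0,
        seed=seed,
        micropattern=MicropatternSpec(
            n_rows=12,
            n_cols=12,
            pitch_um=30.0,
            pattern_radius_um=8.0,
            intensity=60.0,
            occupancy_probs=occupancy_probs or {0: 0.55, 1: 0.15, 2: 0.30},
            nucleus_intensity=50.0,
            nucleus_sigma_um=2.5,
        ),
        optics=OpticsSpec(psf_sigma_um=0.5, bit_depth=8, background=8.0),
        noise=NoiseSpec(read_sigma=1.5),
    )
    scene, truth = build_scene(spec)
    return FixtureBundle(
        name="micropattern",
        spec=spec,
        scene=scene,
        truth=truth,
        primary_optics=OpticsState(pixel_size_um=1.0, fov_px=100, k=1, n_z=1),
        secondary_optics=OpticsState(pixel_size_um=0.25, fov_px=96, k=1, n_z=15, z_step_um=0.5),
        channels=(0, 1),
        n_z_primary=1,
        detector="micropattern",
        detector_params={},
    )


def mitosis_fixture(
    seed: int = 0,
    neb_onsets: Sequence[tuple[int, int]] = ((0, 4),),
    n_nuclei: int = 3,
    brownian_sigma_um: float = 0.3,
) -> FixtureBundle:
    """Live tubulin scene: slowly moving cells with dark nuclei; scheduled
    NEB events fill the nuclear disk with bright tubulin signal."""
    spec = SampleSpec(
        field_w_um=128.0,
        field_h_um=128.0,
        seed=seed,
        live=LiveSpec(
            n_nuclei=n_nuclei,
            nucleus_radius_um=5.0,
            cyto_radius_um=10.0,
            tubulin_level=60.0,
            nucleus_dark_level=15.0,
            neb_fill_level=90.0,
            brownian_sigma_um=brownian_sigma_um,
            neb_onsets=tuple(neb_onsets),
            min_separation_um=30.0,
        ),
        optics=OpticsSpec(psf_sigma_um=0.4, bit_depth=8, background=5.0),
        noise=NoiseSpec(read_sigma=1.0),
    )
    scene, truth = build_scene(spec)
    return FixtureBundle(
        name="mitosis_live",
        spec=spec,
        scene=scene,
        truth=truth,
        primary_optics=OpticsState(pixel_size_um=0.5, fov_px=64, k=2, n_z=1),
        secondary_optics=OpticsState(pixel_size_um=0.25, fov_px=96, k=1, n_z=5, z_step_um=1.0),
        channels=(0,),
        n_z_primary=1,
        detector="mitosis_live",
        detector_params={},
    )


FIXTURE_KINDS = {
    "metaphase": metaphase_fixture,
    "fish": fish_fixture,
    "micropattern": micropattern_fixture,
    "mitosis_live": mitosis_fixture,
}


def make_fixture(kind: str, seed: int = 0, **kwargs) -> FixtureBundle:
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {sorted(FIXTURE_KINDS)}")
    return FIXTURE_KINDS[kind](seed=seed, **kwargs)


def write_fixture(kind: str, out_folder, seed: int = 0, n_frames: Optional[int] = None) -> FixtureBundle:
    """Write a ready-to-replay primary-scan folder plus its ground-truth CSV.

    Fixed-sample kinds record a single primary frame; the live kind records a
    short time series covering its scheduled events."""
    bundle = make_fixture(kind, seed=seed)
    out = Path(out_folder)
    out.mkdir(parents=True, exist_ok=True)
    backend = bundle.backend(record_folder=out)
    if n_frames is None:
        n_frames = 8 if kind == "mitosis_live" else 1
    for t in range(n_frames):
        backend.scan_primary(bundle.grid, bundle.channels, bundle.n_z_primary, t)
    bundle.truth.save(out / "ground_truth.csv")
    return bundle
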