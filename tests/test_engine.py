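"""Acquisition state machines: sequencing contracts, review, capping,
blindness, replay equivalence and scan-plan arithmetic."""

import numpy as np
import pytest

from smartscan.core import StagePosition, Target, TargetList, TileGrid
from smartscan.detectors import get_detector
from smartscan.engine import (
    AcquisitionLog,
    ExperimentConfig,
    SecondaryConfig,
    apply_review,
    estimate_scan_plan,
    run_block_fixed,
    run_block_live,
    run_tiled_fixed,
    run_tiled_live,
    tiles_at_secondary_resolution,
)
from smartscan.fixtures import make_fixture
from smartscan.protocol import replay_source


def live_config(bundle, n_events=3, L=12, max_frames=25):
    return ExperimentConfig(
        mode="tiled_live",
        grid=bundle.grid,
        channels=bundle.channels,
        n_z_primary=bundle.n_z_primary,
        detector=bundle.detector,
        detector_params=bundle.detector_params,
        secondary=SecondaryConfig(n_timepoints=L, channels=(0,), n_z=3),
        max_events=n_events,
        max_primary_frames=max_frames,
    )


class TestTiledFixed:
    def test_cap_keeps_highest_scoring_targets(self, metaphase_bundle):
        cfg = ExperimentConfig(
            mode="tiled_fixed",
            grid=metaphase_bundle.grid,
            channels=metaphase_bundle.channels,
            n_z_primary=metaphase_bundle.n_z_primary,
            detector_params=metaphase_bundle.detector_params,
            target_cap=3,
        )
        targets, log = run_tiled_fixed(
            cfg, metaphase_bundle.backend(), get_detector("metaphase")
        )
        assert len(targets) == 3
        assert len(log.of_kind("secondary_frame")) == 3
        detected = log.of_kind("detection_call")[0]["n_targets"]
        assert detected == 5  # cap selected 3 of the 5 detections
        assert targets[0].score >= targets[1].score >= targets[2].score

    def test_zero_targets_ends_without_secondary(self, metaphase_bundle):
        cfg = ExperimentConfig(mode="tiled_fixed", grid=metaphase_bundle.grid)
        targets, log = run_tiled_fixed(
            cfg,
            metaphase_bundle.backend(),
            lambda frames, grid, params: TargetList(),
        )
        assert targets == []
        assert log.of_kind("secondary_frame") == []
        assert log.events[-1]["reason"] == "no_targets"

    def test_review_selection_file_filters_targets(self, metaphase_bundle, tmp_path):
        selection = tmp_path / "selection.txt"
        selection.write_text("2\n")
        cfg = ExperimentConfig(
            mode="tiled_fixed",
            grid=metaphase_bundle.grid,
            channels=metaphase_bundle.channels,
            n_z_primary=metaphase_bundle.n_z_primary,
            detector_params=metaphase_bundle.detector_params,
            review=True,
            selection_path=str(selection),
            montage_path=str(tmp_path / "montage.tif"),
        )
        targets, log = run_tiled_fixed(
            cfg, metaphase_bundle.backend(), get_detector("metaphase")
        )
        assert len(targets) == 1
        assert len(log.of_kind("secondary_frame")) == 1
        assert (tmp_path / "montage.tif").exists()

    def test_acquired_targets_subset_of_detections(self, metaphase_bundle):
        cfg = ExperimentConfig(
            mode="tiled_fixed",
            grid=metaphase_bundle.grid,
            channels=metaphase_bundle.channels,
            n_z_primary=metaphase_bundle.n_z_primary,
            detector_params=metaphase_bundle.detector_params,
            target_cap=2,
        )
        detector = get_detector("metaphase")
        all_targets, _ = run_tiled_fixed(
            cfg.__class__(**{**cfg.__dict__, "target_cap": None}),
            metaphase_bundle.backend(),
            detector,
        )
        capped, _ = run_tiled_fixed(cfg, metaphase_bundle.backend(), detector)
        all_pos = {(t.position.x_um, t.position.y_um) for t in all_targets}
        assert {(t.position.x_um, t.position.y_um) for t in capped} <= all_pos
        assert len(capped) <= 2


class TestApplyReview:
    targets = TargetList(
        Target(position=StagePosition(float(i), 0.0, 0.0)) for i in range(3)
    )

    def test_subset_in_original_order(self, tmp_path):
        f = tmp_path / "sel.txt"
        f.write_text("0\n2\n")
        out = apply_review(self.targets, {0: 0, 1: 1, 2: 2}, str(f))
        assert [t.position.x_um for t in out] == [0.0, 2.0]

    def test_missing_file_accepts_all(self, tmp_path):
        out = apply_review(self.targets, {0: 0, 1: 1, 2: 2}, str(tmp_path / "absent.txt"))
        assert len(out) == 3

    def test_out_of_range_index_rejected(self, tmp_path):
        f = tmp_path / "sel.txt"
        f.write_text("5\n")
        with pytest.raises(ValueError):
            apply_review(self.targets, {0: 0, 1: 1, 2: 2}, str(f))


class TestBlockFixed:
    @staticmethod
    def _quadrant_blocks(bundle):
        """Split the micropattern fixture's 4x4 tile grid into 4 blocks."""
        g = bundle.grid
        blocks = []
        for br in range(2):
            for bc in range(2):
                origin = g.tile_center(br * 2, bc * 2)
                blocks.append(
                    TileGrid(origin, 2, 2, g.tile_h_px, g.tile_w_px, g.pixel_size_um)
                )
        return blocks

    def test_single_secondary_scan_after_all_blocks(self, micropattern_bundle):
        blocks = self._quadrant_blocks(micropattern_bundle)
        cfg = ExperimentConfig(
            mode="block_fixed",
            blocks=blocks,
            channels=micropattern_bundle.channels,
            n_z_primary=1,
            detector_params=micropattern_bundle.detector_params,
            min_separation_um=5.0,
        )
        targets, log = run_block_fixed(
            cfg, micropattern_bundle.backend(), get_detector("micropattern")
        )
        singles = [
            r for r in micropattern_bundle.truth.of_kind("pattern") if r["occupancy"] == 1
        ]
        assert len(targets) == len(singles)
        # ordering contract: no secondary frame before the last detection call
        kinds = [e["event"] for e in log.events]
        assert kinds.index("secondary_frame") > len(kinds) - 1 - kinds[::-1].index(
            "detection_call"
        )
        # every block contributed its own tag
        assert {t.block_index for t in targets} <= {0, 1, 2, 3}

    def test_all_blocks_empty_means_no_secondary(self, micropattern_bundle):
        blocks = self._quadrant_blocks(micropattern_bundle)
        cfg = ExperimentConfig(mode="block_fixed", blocks=blocks)
        targets, log = run_block_fixed(
            cfg, micropattern_bundle.backend(), lambda f, g, p: TargetList()
        )
        assert targets == [] and log.of_kind("secondary_frame") == []
        assert len(log.of_kind("detection_call")) == 4


class TestTiledLive:
    def test_three_events_three_bursts_of_L_frames(self):
        bundle = make_fixture("mitosis_live", seed=5, neb_onsets=((0, 4), (1, 9), (2, 14)))
        cfg = live_config(bundle, n_events=3, L=12, max_frames=25)
        events, log = run_tiled_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        bursts = log.secondary_bursts()
        assert len(events) == 3
        assert [len(b) for b in bursts] == [12, 12, 12]
        assert log.events[-1] == {
            k: log.events[-1][k] for k in log.events[-1]
        }  # structural sanity
        assert log.events[-1]["reason"] == "max_events"
        # each burst within 1 primary frame of its scheduled onset
        detections = [
            e for e in log.of_kind("detection_call") if e["n_targets"] > 0
        ]
        assert [e["t"] for e in detections] == [4, 9, 14]

    def test_no_detection_calls_during_bursts(self):
        bundle = make_fixture("mitosis_live", seed=5, neb_onsets=((0, 4), (1, 9)))
        cfg = live_config(bundle, n_events=2, L=5, max_frames=20)
        _, log = run_tiled_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        in_secondary = False
        for e in log.events:
            if e["event"] == "mode_switch":
                in_secondary = e["to"] == "secondary"
            assert not (in_secondary and e["event"] == "detection_call")

    def test_frames_zero_and_one_never_analyzed(self):
        bundle = make_fixture("mitosis_live", seed=6, neb_onsets=())
        cfg = live_config(bundle, n_events=1, L=3, max_frames=6)
        _, log = run_tiled_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        ts = [e["t"] for e in log.of_kind("detection_call")]
        assert min(ts) == 2  # first call only after the 3-frame queue fills

    def test_simultaneous_events_trigger_single_burst(self):
        bundle = make_fixture("mitosis_live", seed=7, neb_onsets=((0, 4), (1, 4)))
        cfg = live_config(bundle, n_events=5, L=4, max_frames=12)
        events, log = run_tiled_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        detections = [e for e in log.of_kind("detection_call") if e["n_targets"] > 0]
        assert detections[0]["n_targets"] == 2
        # only the highest-scoring one acquired at that frame; the step change
        # is gone afterwards, so the second is never re-detected
        assert len(events) == 1

    def test_run_ends_after_max_events(self):
        bundle = make_fixture("mitosis_live", seed=8, neb_onsets=((0, 5),))
        cfg = live_config(bundle, n_events=1, L=4, max_frames=20)
        events, log = run_tiled_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        assert len(events) == 1
        assert log.events[-1]["reason"] == "max_events"
        # no primary frames acquired after the final burst
        last_burst_idx = max(
            i for i, e in enumerate(log.events) if e["event"] == "mode_switch"
        )
        assert all(
            e["event"] != "primary_frame_start" for e in log.events[last_burst_idx:]
        )


class TestBlockLive:
    def _blocks(self, bundle):
        g = bundle.grid
        return [
            TileGrid(g.tile_center(0, 0), 1, 2, g.tile_h_px, g.tile_w_px, g.pixel_size_um),
            TileGrid(g.tile_center(1, 0), 1, 2, g.tile_h_px, g.tile_w_px, g.pixel_size_um),
        ]

    def test_no_events_scans_all_blocks_every_cycle(self):
        bundle = make_fixture("mitosis_live", seed=9, neb_onsets=())
        cfg = ExperimentConfig(
            mode="block_live",
            blocks=self._blocks(bundle),
            channels=(0,),
            n_z_primary=1,
            detector_params=bundle.detector_params,
            secondary=SecondaryConfig(n_timepoints=3),
            max_events=1,
            max_primary_frames=4,
        )
        _, log = run_block_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        assert len(log.of_kind("primary_frame_start")) == 4 * 2
        assert log.of_kind("secondary_frame") == []
        assert log.events[-1]["reason"] == "max_primary_frames"

    def test_burst_precedes_next_blocks_frame(self):
        bundle = make_fixture("mitosis_live", seed=9, neb_onsets=((0, 3),))
        cfg = ExperimentConfig(
            mode="block_live",
            blocks=self._blocks(bundle),
            channels=(0,),
            n_z_primary=1,
            detector_params=bundle.detector_params,
            secondary=SecondaryConfig(n_timepoints=4),
            max_events=1,
            max_primary_frames=8,
        )
        events, log = run_block_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        if events:  # the scheduled nucleus lies in one of the two strips
            kinds = [e["event"] for e in log.events]
            first_secondary = kinds.index("secondary_frame")
            hit_block = [e for e in log.of_kind("detection_call") if e["n_targets"]][0]["block"]
            after = [
                e
                for e in log.events[first_secondary:]
                if e["event"] == "primary_frame_start"
            ]
            assert all(e["block"] != hit_block or e["t"] > 0 for e in after[:1])
            assert log.events[-1]["reason"] == "max_events"


class TestReplayEquivalence:
    def test_offline_replay_reproduces_live_run(self, tmp_path):
        bundle = make_fixture("mitosis_live", seed=10, neb_onsets=((0, 4), (1, 8)))
        record = tmp_path / "rec"
        record.mkdir()
        cfg = live_config(bundle, n_events=2, L=6, max_frames=15)
        live_targets, live_log = run_tiled_live(
            cfg, bundle.backend(record_folder=record), get_detector("mitosis_live")
        )
        replay_targets, replay_log = run_tiled_live(
            cfg, replay_source(record), get_detector("mitosis_live")
        )
        assert live_log.events_without_timestamps() == replay_log.events_without_timestamps()
        assert [
            (t.position.x_um, t.position.y_um, t.label, t.score) for t in live_targets
        ] == [(t.position.x_um, t.position.y_um, t.label, t.score) for t in replay_targets]


class TestLogWellFormedness:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_schedules_keep_log_contracts(self, seed):
        rng = np.random.default_rng(seed)
        onsets = tuple((i, int(4 + 5 * i + rng.integers(0, 2))) for i in range(rng.integers(1, 3)))
        bundle = make_fixture("mitosis_live", seed=20 + seed, neb_onsets=onsets)
        L = int(rng.integers(2, 8))
        cfg = live_config(bundle, n_events=len(onsets), L=L, max_frames=20)
        events, log = run_tiled_live(cfg, bundle.backend(), get_detector("mitosis_live"))
        switches = [e["to"] for e in log.of_kind("mode_switch")]
        # alternating to_secondary / to_primary
        assert switches[::2] == ["secondary"] * len(switches[::2])
        assert switches[1::2] == ["primary"] * len(switches[1::2])
        for burst in log.secondary_bursts():
            assert len(burst) == L
            assert [e["k"] for e in burst] == list(range(1, L + 1))
        assert len(log.secondary_bursts()) == min(cfg.max_events, len(onsets))


class TestScanPlan:
    def test_mitotic_study_tile_count(self):
        # 10x10 primary grid at 3x finer secondary sampling
        assert tiles_at_secondary_resolution(10, 10, 3) == 900

    def test_mitotic_study_image_count(self):
        assert estimate_scan_plan(900, 3, 65)["n_images"] == 175_500

    def test_micropattern_chip_image_count(self):
        assert estimate_scan_plan(20_736, images_per_fov=75)["n_images"] == 1_555_200

    def test_zero_tiles(self):
        assert estimate_scan_plan(0, 3, 65)["n_images"] == 0

    def test_identity_ratio(self):
        assert tiles_at_secondary_resolution(7, 9, 1) == 63

    def test_general_case(self):
        assert tiles_at_secondary_resolution(2, 3, 2) == 24

    def test_bytes_accounting(self):
        plan = estimate_scan_plan(10, 2, 5, bytes_per_image=1000)
        assert plan["bytes"] == 100_000
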