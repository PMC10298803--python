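"""Grid ROIs, binarization, 3D event extraction, splitting, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tonotopy import segmentation
from tonotopy.segmentation import (
    binarize_activity,
    extract_events,
    make_grid_rois,
    split_overlapping_events,
    suggest_split_k,
    summarize_events,
)
from tonotopy.synth import gen_isc_ihc_movie, isc_region_mask
from tonotopy.types import ActivityEvent, CalciumMovie

from _oracles import filtered_flood_fill_events, flood_fill_components


def _movie(data, frame_rate=2.0, scale=1.0):
    return CalciumMovie(np.asarray(data, float), frame_rate, scale)


class TestMakeGridRois:
    def test_square_mask_tiles_exactly(self):
        movie = _movie(np.full((5, 100, 100), 10.0))
        mask = np.ones((100, 100), dtype=bool)
        grid = make_grid_rois(movie, mask, grid_px=10)
        assert grid.n_rois == 100
        assert grid.shape == (10, 10)

    def test_small_edge_tiles_discarded(self):
        movie = _movie(np.full((5, 104, 100), 10.0))
        mask = np.ones((104, 100), dtype=bool)
        grid = make_grid_rois(movie, mask, grid_px=10)
        # the trailing 4-px row band is under half a tile and is dropped
        assert grid.shape[0] == 11
        assert grid.n_rois == 100

    def test_empty_mask_raises(self):
        movie = _movie(np.full((5, 20, 20), 10.0))
        with pytest.raises(ValueError):
            make_grid_rois(movie, np.zeros((20, 20), dtype=bool), 10)

    def test_traces_are_dff_of_tile_means(self):
        data = np.full((4, 20, 20), 10.0)
        data[2, :10, :10] = 20.0  # one tile doubles on one frame
        grid = make_grid_rois(_movie(data), np.ones((20, 20), bool), 10)
        i = grid.roi_index[(0, 0)]
        assert grid.traces[i] == pytest.approx([0, 0, 1.0, 0])


class TestBinarize:
    def test_constant_trace_never_active(self):
        movie = _movie(np.full((10, 20, 20), 10.0))
        grid = make_grid_rois(movie, np.ones((20, 20), bool), 10)
        assert not binarize_activity(grid).any()

    def test_threshold_is_median_plus_3sd_strict(self):
        # trace of 20 zeros with one frame at 1.0: median 0, SD = sqrt(1/20)
        data = np.full((20, 10, 10), 10.0)
        data[7] = 20.0
        grid = make_grid_rois(_movie(data), np.ones((10, 10), bool), 10)
        raster = binarize_activity(grid)
        trace = grid.traces[0]
        thresh = np.median(trace) + 3 * np.std(trace)
        assert (trace[7] > thresh) == raster[7, 0, 0]
        assert raster.sum() == int(trace[7] > thresh)

    def test_noiseless_planted_raster_brackets_footprint(self, small_isc_config):
        # plateau frames are guaranteed active; rise/decay frames may fall
        # under a per-ROI threshold inflated by other events on the same ROI
        movie, _, gt = gen_isc_ihc_movie(small_isc_config)
        grid = make_grid_rois(movie, isc_region_mask(small_isc_config.image_shape), 10)
        raster = binarize_activity(grid)
        planted, core = set(), set()
        for ev in gt.events:
            planted |= {tuple(v) for v in ev.voxels}
            core |= {tuple(v) for v in ev.core_voxels}
        detected = {tuple(map(int, v)) for v in np.argwhere(raster)}
        assert core <= detected <= planted


class TestExtractEvents:
    def test_single_blob_passes_filters(self):
        raster = np.zeros((10, 8, 8), bool)
        raster[2:6, 2:5, 2:4] = True  # 4 frames, 6 ROIs
        events = extract_events(raster)
        assert len(events) == 1
        assert events[0].start_frame == 2 and events[0].end_frame == 5
        assert events[0].n_rois == 6

    def test_short_blob_filtered(self):
        raster = np.zeros((10, 8, 8), bool)
        raster[2:4, 0:4, 0:4] = True  # only 2 frames
        assert extract_events(raster) == []

    def test_two_separated_blobs(self):
        raster = np.zeros((20, 10, 10), bool)
        raster[2:6, 0:3, 0:2] = True
        raster[10:14, 6:9, 6:8] = True
        events = extract_events(raster)
        assert len(events) == 2

    def test_matches_flood_fill_oracle_on_random_rasters(self, rng):
        for _ in range(40):
            raster = rng.random((12, 10, 10)) < 0.12
            got = extract_events(raster, frame_rate_hz=1.0)
            expected = filtered_flood_fill_events(raster)
            got_sets = sorted(
                [frozenset(map(tuple, e.voxels)) for e in got], key=sorted
            )
            exp_sets = sorted([frozenset(c) for c in expected], key=sorted)
            assert got_sets == exp_sets

    def test_six_connectivity_matches_oracle(self, rng):
        raster = rng.random((15, 12, 12)) < 0.2
        got = extract_events(raster, connectivity=6, frame_rate_hz=1.0)
        expected = filtered_flood_fill_events(raster, connectivity=6)
        assert sorted([frozenset(map(tuple, e.voxels)) for e in got], key=sorted) == sorted(
            [frozenset(c) for c in expected], key=sorted
        )

    @given(
        raster=arrays(
            np.bool_, (8, 6, 6), elements=st.booleans()
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_voxel_conservation_property(self, raster):
        events = extract_events(raster, frame_rate_hz=1.0)
        event_voxels = sum(len(e.voxels) for e in events)
        filtered = sum(
            len(c)
            for c in flood_fill_components(raster)
            if c not in [set(map(tuple, e.voxels)) for e in events]
        )
        assert event_voxels + filtered == int(raster.sum())

    def test_count_non_increasing_in_filters(self, rng):
        raster = rng.random((20, 12, 12)) < 0.15
        base = len(extract_events(raster, min_frames=1, min_rois=1, frame_rate_hz=1.0))
        for mf, mr in [(3, 1), (1, 5), (3, 5), (5, 8)]:
            n = len(extract_events(raster, min_frames=mf, min_rois=mr, frame_rate_hz=1.0))
            assert n <= base


class TestSplitting:
    @staticmethod
    def _fused_event(gap_bridge=True):
        raster = np.zeros((30, 20, 20), bool)
        raster[5:11, 2:6, 2:6] = True  # blob A
        raster[12:18, 12:16, 12:16] = True  # blob B
        if gap_bridge:
            # 1-voxel-wide bridge connecting them in space-time
            for k, (f, r, c) in enumerate(zip(range(10, 13), range(5, 8), range(5, 8))):
                raster[f, r:r+5, c:c+5] = False
            raster[10, 6, 6] = True
            raster[11, 8, 8] = True
            raster[11, 7, 7] = True
            raster[12, 11, 11] = True
            raster[11, 9, 9] = True
            raster[11, 10, 10] = True
        events = extract_events(raster, frame_rate_hz=1.0)
        return raster, events

    def test_k1_is_identity(self):
        _, events = self._fused_event(gap_bridge=False)
        ev = events[0]
        assert split_overlapping_events(ev, 1) == [ev]

    def test_bridge_fused_blobs_recovered(self):
        raster, events = self._fused_event()
        assert len(events) == 1  # genuinely fused
        parts = split_overlapping_events(events[0], k=2, seed=0)
        assert len(parts) == 2
        blob_a = {(f, r, c) for f in range(5, 11) for r in range(2, 6) for c in range(2, 6)}
        blob_b = {(f, r, c) for f in range(12, 18) for r in range(12, 16) for c in range(12, 16)}
        # best-permutation agreement >= 95% of each blob
        sets = [set(map(tuple, p.voxels)) for p in parts]
        agree = max(
            min(len(sets[0] & blob_a) / len(blob_a), len(sets[1] & blob_b) / len(blob_b)),
            min(len(sets[1] & blob_a) / len(blob_a), len(sets[0] & blob_b) / len(blob_b)),
        )
        assert agree >= 0.95

    def test_split_parts_below_filters_dropped(self):
        # two 2-frame blobs fused by a bridge: split yields no surviving events
        raster = np.zeros((10, 10, 10), bool)
        raster[2:4, 0:3, 0:3] = True
        raster[4:6, 4:7, 4:7] = True
        raster[3, 3, 3] = True
        events = extract_events(raster, min_frames=3, frame_rate_hz=1.0)
        assert len(events) == 1  # fused blob passes the 4-frame span
        parts = split_overlapping_events(events[0], k=2, seed=0, min_frames=3)
        assert parts == []

    def test_k_larger_than_voxels_raises(self):
        _, events = self._fused_event(gap_bridge=False)
        with pytest.raises(ValueError):
            split_overlapping_events(events[0], k=10**6)

    def test_suggest_split_k_on_bimodal_event(self):
        raster, events = self._fused_event()
        assert suggest_split_k(events[0]) == 2
        _, single = self._fused_event(gap_bridge=False)
        assert suggest_split_k(single[0]) == 1


class TestSummarize:
    def test_frequency_arithmetic(self):
        events = [
            ActivityEvent(np.zeros((1, 3), int), 0, 3, 6, 2.0, 0.001)
            for _ in range(6)
        ]
        m = summarize_events(events, recording_duration_s=600.0, region_area_mm2=0.02)
        assert m.frequency_per_001mm2_per_min == pytest.approx(0.3)

    def test_empty_events(self):
        m = summarize_events([], 600.0, 0.02)
        assert m.frequency_per_001mm2_per_min == 0.0
        assert m.mean_duration_s is None and m.mean_area_mm2 is None

    def test_means_match_planted(self, small_isc_config):
        movie, _, gt = gen_isc_ihc_movie(small_isc_config)
        grid = make_grid_rois(movie, isc_region_mask(small_isc_config.image_shape), 10)
        events = extract_events(
            binarize_activity(grid),
            frame_rate_hz=movie.frame_rate_hz,
            roi_area_mm2=(10 * movie.pixel_scale_um) ** 2 / 1e6,
        )
        m = summarize_events(events, movie.duration_s, 0.5 * 0.01)
        planted = [e for e in gt.events if len(e.members) >= 5]
        assert m.n_events == len(planted)
        # detected duration lies between the plateau and the full trapezoid
        planted_mean = np.mean([(e.end_frame - e.start_frame + 1) / 2.0 for e in planted])
        assert abs(m.mean_duration_s - planted_mean) <= 1.0
        # every member tile is active at the plateau, so areas match exactly
        planted_area = np.mean([len(e.members) for e in planted]) * (10 * 0.83) ** 2 / 1e6
        assert m.mean_area_mm2 == pytest.approx(planted_area)
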