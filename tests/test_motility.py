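"""Extension detection, persistence classification, stability index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliamotion import (CellSegmentation, ParameterError, classify_stability,
                        detect_extensions, make_toy_binary_series,
                        score_series, simulate_timelapse, stability_index,
                        stability_threshold_frames, SimulationConfig)
from gliamotion.preprocess import ProjectedSeries

from conftest import oracle_stability, random_toy_spec


def _base_and_seg(shape=(32, 32)):
    base = np.zeros(shape, dtype=bool)
    base[10:20, 10:14] = True
    return base, CellSegmentation.from_single_mask(base)


class TestStabilityThresholdFrames:
    @pytest.mark.parametrize("interval,expected", [
        (60.0, 3),    # 1 frame/min, 3-min rule: a series of three images
        (90.0, 2),
        (180.0, 1),
        (45.0, 4),
    ])
    def test_ceiling_conversion(self, interval, expected):
        assert stability_threshold_frames(interval) == expected

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ParameterError):
            stability_threshold_frames(0.0)

    @given(interval=st.floats(1.0, 600.0),
           persistence=st.floats(1.0, 600.0))
    @settings(max_examples=50, deadline=None)
    def test_window_covers_required_time(self, interval, persistence):
        """threshold * interval >= persistence, minimally so."""
        k = stability_threshold_frames(interval, persistence)
        assert k * interval >= persistence - 1e-9
        assert (k - 1) * interval < persistence + 1e-9


class TestDetectExtensions:
    def test_static_series_no_events(self):
        base, seg = _base_and_seg()
        series = make_toy_binary_series([], 5, base)
        assert detect_extensions(series, seg) == []

    def test_single_block_event(self):
        base, seg = _base_and_seg()
        block = np.zeros_like(base)
        block[12:15, 14:17] = True  # 3x3, touching the base bar
        series = make_toy_binary_series([(2, block, 5)], 10, base)
        events = detect_extensions(series, seg)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_frame == 2
        assert ev.n_pixels == 9
        assert ev.cell_id == 1

    def test_detached_component_discarded(self):
        base, seg = _base_and_seg()
        block = np.zeros_like(base)
        block[2:5, 25:28] = True  # far from any foreground
        series = make_toy_binary_series([(1, block, 3)], 5, base)
        assert detect_extensions(series, seg) == []

    def test_min_event_px_filter(self):
        base, seg = _base_and_seg()
        block = np.zeros_like(base)
        block[12, 14:16] = True  # 2 px, below min_event_px=4
        series = make_toy_binary_series([(1, block, 5)], 6, base)
        assert detect_extensions(series, seg, min_event_px=4) == []
        assert len(detect_extensions(series, seg, min_event_px=1)) == 1

    def test_noiseless_simulation_counts_match_truth(self):
        cfg = SimulationConfig(image_size=256, n_z=5, n_cells=2,
                               n_primary_processes=4, noise_scale=0.0, seed=7)
        stack, gt = simulate_timelapse(cfg)
        series = ProjectedSeries(
            np.stack(gt.frame_masks), cfg.pixel_size_um,
            cfg.frame_interval_s, [{"op": "synthetic"}])
        seg = CellSegmentation.from_single_mask(gt.frame_masks[0])
        events = detect_extensions(series, seg, min_event_px=1)
        assert len(events) == gt.n_events


class TestClassifyStability:
    @pytest.mark.parametrize("lifetime,persistence,stable", [
        (3, 3, True),    # present frames 2,3,4: exactly 3 min -> stable
        (2, 2, False),   # present frames 2,3 only
        (8, 8, True),    # present frames 2..9 of 10
    ])
    def test_persistence_from_lifetime(self, lifetime, persistence, stable):
        base, seg = _base_and_seg()
        block = np.zeros_like(base)
        block[12:15, 14:17] = True
        series = make_toy_binary_series([(2, block, lifetime)], 10, base)
        events = classify_stability(detect_extensions(series, seg), series)
        assert events[0].persistence_frames == persistence
        assert events[0].stable is stable

    def test_threshold_exceeding_series_rejected(self):
        base, seg = _base_and_seg()
        series = make_toy_binary_series([], 4, base)
        with pytest.raises(ParameterError, match="exceeds"):
            classify_stability([], series, stability_threshold_frames=5)


class TestStabilityIndex:
    def test_mixed_events_half(self):
        base, seg = _base_and_seg((48, 48))
        b1 = np.zeros_like(base)
        b1[12:15, 14:17] = True
        b2 = np.zeros_like(base)
        b2[16:19, 7:10] = True  # cols 7-9; col 9 is 4-adjacent to base col 10
        series = make_toy_binary_series([(2, b1, 5), (3, b2, 1)], 10, base)
        events = classify_stability(detect_extensions(series, seg), series)
        results = stability_index(events, per_cell=False)
        assert results[0].n_events == 2
        assert results[0].stability_index == 0.5

    def test_all_stable(self):
        base, seg = _base_and_seg()
        b1 = np.zeros_like(base)
        b1[12:15, 14:17] = True
        series = make_toy_binary_series([(1, b1, 9)], 10, base)
        events = classify_stability(detect_extensions(series, seg), series)
        res = stability_index(events, per_cell=False)[0]
        assert res.stability_index == 1.0

    def test_zero_events_undefined(self):
        res = stability_index([], per_cell=False)[0]
        assert res.undefined
        assert np.isnan(res.stability_index)

    def test_unclassified_events_rejected(self):
        base, seg = _base_and_seg()
        block = np.zeros_like(base)
        block[12:15, 14:17] = True
        series = make_toy_binary_series([(1, block, 5)], 6, base)
        raw = detect_extensions(series, seg)
        with pytest.raises(ParameterError, match="classified"):
            stability_index(raw)


class TestOracleEquivalence:
    def test_pipeline_equals_bruteforce_on_random_toys(self, rng):
        """Exact SI equality with the enumeration oracle, 120 random specs."""
        for case in range(120):
            n_frames = int(rng.integers(5, 11))
            spec, base = random_toy_spec(rng, n_frames=n_frames)
            series = make_toy_binary_series(spec, n_frames, base)
            seg = CellSegmentation.from_single_mask(base)
            events, results = score_series(series, seg, per_cell=False)
            n, n_stable, si = oracle_stability(spec, n_frames)
            r = results[0]
            assert r.n_events == n, f"case {case}: event count"
            assert r.n_stable == n_stable, f"case {case}: stable count"
            assert r.stability_index == si, f"case {case}: SI"

    def test_monotone_in_stable_fraction(self):
        """Estimated SI increases with the simulated stable fraction."""
        sis = []
        for sf in (0.1, 0.5, 0.9):
            cfg = SimulationConfig(image_size=256, n_z=5, n_cells=2,
                                   n_primary_processes=5, extension_prob=0.5,
                                   stable_fraction=sf, noise_scale=0.0, seed=42)
            stack, gt = simulate_timelapse(cfg)
            series = ProjectedSeries(np.stack(gt.frame_masks),
                                     cfg.pixel_size_um, cfg.frame_interval_s,
                                     [{"op": "synthetic"}])
            seg = CellSegmentation.from_single_mask(gt.frame_masks[0])
            _, results = score_series(series, seg, per_cell=False)
            sis.append(results[0].stability_index)
        assert sis[0] < sis[1] < sis[2]
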