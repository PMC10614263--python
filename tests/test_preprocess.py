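"""Projection, drift registration, bleach normalization, binarization."""

import numpy as np
import pytest

from gliamotion import (ParameterError, ProjectedSeries, SimulationConfig,
                        TimeLapseStack, apply_artifacts, binarize,
                        correct_bleach, correct_drift, max_project,
                        preprocess_stack, simulate_timelapse)


def _stack(data, px=0.5, dt=60.0, dz=2.0):
    return TimeLapseStack(np.asarray(data, dtype=np.float32), px, dt, dz)


class TestMaxProject:
    def test_constant_in_z_equals_single_plane(self, rng):
        plane = rng.random((2, 20, 20)).astype(np.float32)
        data = np.repeat(plane[:, None], 4, axis=1)
        out = max_project(_stack(data))
        np.testing.assert_array_equal(out.data, plane)

    def test_single_bright_voxel(self):
        data = np.zeros((1, 8, 16, 16), dtype=np.float32)
        data[0, 5, 10, 10] = 7.0
        out = max_project(_stack(data))
        assert out.data[0, 10, 10] == 7.0
        assert out.data.sum() == 7.0

    def test_matches_explicit_loop_oracle(self, rng):
        data = rng.random((3, 5, 12, 12)).astype(np.float32)
        out = max_project(_stack(data))
        for t in range(3):
            for y in range(12):
                for x in range(12):
                    assert out.data[t, y, x] == max(
                        data[t, z, y, x] for z in range(5))

    def test_slab_selection_and_empty_slab(self):
        data = np.zeros((1, 10, 4, 4), dtype=np.float32)
        data[0, 9] = 5.0
        out = max_project(_stack(data, dz=2.0), z_range_um=(0.0, 10.0))
        assert out.data.max() == 0.0  # plane 9 at 18 um excluded
        with pytest.raises(ParameterError, match="z_range"):
            max_project(_stack(data, dz=2.0), z_range_um=(100.0, 200.0))

    def test_idempotent_on_single_plane(self, rng):
        data = rng.random((2, 1, 8, 8)).astype(np.float32)
        once = max_project(_stack(data))
        twice = max_project(_stack(once.data[:, None]))
        np.testing.assert_array_equal(once.data, twice.data)

    def test_calibration_propagated(self, rng):
        out = max_project(_stack(rng.random((2, 2, 4, 4)), px=0.11, dt=30.0))
        assert out.pixel_size_um == 0.11
        assert out.frame_interval_s == 30.0


class TestCorrectDrift:
    def test_identical_frames_zero_shifts(self, rng):
        frame = rng.random((32, 32))
        series = ProjectedSeries(np.stack([frame] * 4), 1.0, 60.0)
        out = correct_drift(series)
        assert out.provenance[-1]["shifts_px"] == [[0, 0]] * 4

    def test_known_drift_recovered_exactly(self, small_sim_config):
        """Applied per-frame drift (3, -2): corrections are (-3t, 2t)."""
        cfg = SimulationConfig(**{**small_sim_config.to_dict(),
                                  "noise_scale": 0.0})
        stack, _ = simulate_timelapse(cfg)
        drifted = apply_artifacts(stack, drift=(3, -2))
        series = max_project(drifted)
        out = correct_drift(series)
        shifts = out.provenance[-1]["shifts_px"]
        assert shifts == [[-3 * t, 2 * t] for t in range(cfg.n_frames)]

    def test_corrected_matches_undrifted_away_from_border(self, small_sim_config):
        cfg = SimulationConfig(**{**small_sim_config.to_dict(),
                                  "noise_scale": 0.0})
        stack, _ = simulate_timelapse(cfg)
        clean = max_project(stack)
        drifted = correct_drift(max_project(apply_artifacts(stack, drift=(2, 1))))
        m = 40  # border margin: cumulative drift 9*2 px plus slack
        np.testing.assert_allclose(drifted.data[:, m:-m, m:-m],
                                   clean.data[:, m:-m, m:-m], atol=1e-5)

    def test_needs_two_frames(self, rng):
        series = ProjectedSeries(rng.random((1, 8, 8)), 1.0, 60.0)
        with pytest.raises(ParameterError):
            correct_drift(series)


class TestCorrectBleach:
    def test_no_bleach_identity(self, rng):
        frame = rng.random((16, 16))
        data = np.stack([frame] * 3)
        out = correct_bleach(ProjectedSeries(data, 1.0, 60.0))
        np.testing.assert_allclose(out.data, data)
        assert out.provenance[-1]["factors"] == [1.0, 1.0, 1.0]

    def test_uniform_decay_closed_form(self):
        t = np.arange(5)
        data = np.ones((5, 8, 8)) * np.exp(-0.1 * t)[:, None, None]
        out = correct_bleach(ProjectedSeries(data, 1.0, 60.0))
        factors = out.provenance[-1]["factors"]
        np.testing.assert_allclose(factors, np.exp(0.1 * t), rtol=1e-6)
        assert factors[3] == pytest.approx(np.exp(0.3), abs=1e-6)

    def test_frame_means_constant_after_correction(self, rng):
        data = rng.random((6, 32, 32)) * np.exp(-0.2 * np.arange(6))[:, None, None]
        out = correct_bleach(ProjectedSeries(data, 1.0, 60.0))
        means = out.data.mean(axis=(1, 2))
        assert means.std() / means.mean() < 1e-6

    def test_bleached_simulation_restored(self, small_sim_config):
        # static geometry: mean-ratio correction is then an exact inverse
        cfg = SimulationConfig(**{**small_sim_config.to_dict(),
                                  "noise_scale": 0.0, "extension_prob": 0.0})
        stack, _ = simulate_timelapse(cfg)
        bleached = apply_artifacts(stack, bleach_rate=0.1)
        restored = correct_bleach(max_project(bleached))
        np.testing.assert_allclose(restored.data, max_project(stack).data,
                                   atol=1e-4)

    def test_zero_mean_frame_errors_with_frame_index(self):
        data = np.ones((3, 4, 4))
        data[1] = 0.0
        with pytest.raises(ParameterError, match="frame 1"):
            correct_bleach(ProjectedSeries(data, 1.0, 60.0))


class TestBinarize:
    def test_two_level_image_any_threshold(self):
        data = np.zeros((2, 10, 10))
        data[:, 3:7, 3:7] = 100.0
        for thr in (1.0, 50.0, 99.0):
            out = binarize(ProjectedSeries(data, 1.0, 60.0), method="fixed",
                           threshold=thr)
            np.testing.assert_array_equal(out.data, data > 50)

    def test_otsu_threshold_from_frame0_applied_to_all(self):
        data = np.zeros((3, 20, 20))
        data[0, 5:15, 5:15] = 100.0
        data[1, 5:15, 5:15] = 100.0
        data[2] = 0.0  # all-background later frame must stay empty
        out = binarize(ProjectedSeries(data, 1.0, 60.0))
        assert out.data[0].sum() == 100
        assert out.data[2].sum() == 0
        thr = out.provenance[-1]["threshold"]
        assert 0 < thr < 100

    def test_fixed_without_threshold_errors(self, rng):
        series = ProjectedSeries(rng.random((2, 8, 8)), 1.0, 60.0)
        with pytest.raises(ParameterError, match="threshold"):
            binarize(series, method="fixed")

    def test_mask_overlaps_truth_jaccard(self, small_sim_config):
        """Binarization recovers the true occupancy at default noise."""
        stack, gt = simulate_timelapse(small_sim_config)
        _, binary = preprocess_stack(stack)
        truth = gt.frame_masks[0]
        est = binary.data[0]
        jac = (truth & est).sum() / (truth | est).sum()
        assert jac >= 0.7

    def test_intensity_scaling_invariance(self, small_sim_config):
        """Global intensity scaling does not change the binary mask."""
        stack, _ = simulate_timelapse(small_sim_config)
        series = max_project(stack)
        b1 = binarize(series)
        b2 = binarize(series.with_data(series.data * 7.5))
        np.testing.assert_array_equal(b1.data, b2.data)
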