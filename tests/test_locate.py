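"""Localization: variance autofocus, peak finding, depth assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bf2holo.locate import (
    Particle3D,
    PeakParams,
    assign_depth,
    find_inplane_positions,
    locate_all,
    variance_focus,
)
from bf2holo.optics import OpticalConfig
from bf2holo.reconstruct import ReconstructionStack, reconstruct_volume
from bf2holo.simulate import ParticleSpec, SceneConfig, render_hologram

BEAD_PARAMS = PeakParams(min_distance=15, threshold=0.45, window_half_size=15, smooth_sigma=14)


class TestVarianceFocus:
    def test_constant_window_is_zero(self):
        assert variance_focus(np.full((5, 5), 3.2)) == pytest.approx(0.0, abs=1e-20)

    def test_two_by_two_hand_example(self):
        """[[0,0],[2,2]] has mean 1 and population variance 1."""
        assert variance_focus(np.array([[0.0, 0.0], [2.0, 2.0]])) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(arrays(np.float64, (7, 9), elements=st.floats(-10, 10)))
    def test_algebraic_identity_and_invariances(self, window):
        oracle = np.mean(window**2) - np.mean(window) ** 2
        got = variance_focus(window)
        assert got == pytest.approx(oracle, abs=1e-10)
        # constant offset leaves the focus value unchanged
        assert variance_focus(window + 5.0) == pytest.approx(got, abs=1e-9)
        # intensity scaling acts quadratically
        assert variance_focus(2.0 * window) == pytest.approx(4.0 * got, abs=1e-8)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            variance_focus(np.empty((0, 0)))


class TestFindInplanePositions:
    def test_all_zero_image_gives_empty_list(self):
        assert find_inplane_positions(np.zeros((32, 32)), PeakParams()) == []

    def test_isolated_gaussian_bump_found_subpixel(self):
        yy, xx = np.mgrid[0:128, 0:128]
        image = np.exp(-((yy - 40) ** 2 + (xx - 60) ** 2) / (2 * 3.0**2))
        params = PeakParams(min_distance=5, threshold=0.3, window_half_size=5, smooth_sigma=0)
        positions = find_inplane_positions(image, params, pixel_pitch=1.0)
        assert len(positions) == 1
        x, y = positions[0]
        assert abs(x - 60.5) < 0.5 and abs(y - 40.5) < 0.5

    def test_five_bead_scene_all_found_no_spurious(self):
        optics = OpticalConfig(image_shape=(384, 384))
        truths = [(60, 60, 30), (140, 65, 60), (65, 140, 90), (140, 140, 120), (100, 100, 150)]
        scene = SceneConfig(
            particles=[ParticleSpec(x=x, y=y, z=z) for x, y, z in truths],
            optics=optics,
            rng_seed=9,
        )
        stack = reconstruct_volume(render_hologram(scene), 0, 160, 2, subtract_mean=True)
        detections = locate_all(stack, PeakParams())
        assert len(detections) == len(truths)
        for x_true, y_true, _ in truths:
            best = min(np.hypot(d.x - x_true, d.y - y_true) for d in detections)
            assert best <= optics.pixel_pitch

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            find_inplane_positions(np.empty((0, 0)), PeakParams())


class TestAssignDepth:
    def test_identical_planes_tie_breaks_to_z_min(self):
        optics = OpticalConfig(image_shape=(32, 32))
        plane = np.random.default_rng(3).random((32, 32)).astype(np.float32)
        stack = ReconstructionStack(np.stack([plane] * 7), 10.0 + np.arange(7.0), optics)
        det = assign_depth(stack, (8.0, 8.0), window_half_size=5)
        assert det.z == 10.0
        assert np.allclose(det.focus_curve[:, 1], det.focus_curve[0, 1])

    def test_noise_free_bead_depth_within_two_micrometres(self, noise_free_bead_scene):
        holo = render_hologram(noise_free_bead_scene)
        stack = reconstruct_volume(holo, 0, 100, 1, subtract_mean=True)
        det = assign_depth(stack, (70.0, 65.0), window_half_size=15)
        assert abs(det.z - 50.0) <= 2.0
        assert det.focus_curve.shape == (stack.n_z, 2)

    def test_result_independent_of_plane_iteration_order(self, noise_free_bead_scene):
        holo = render_hologram(noise_free_bead_scene)
        stack = reconstruct_volume(holo, 30, 70, 1, subtract_mean=True)
        det1 = assign_depth(stack, (70.0, 65.0), 15)
        # reversed stack, re-sorted: same physical volume
        order = np.argsort(stack.z_values[::-1])[::-1]
        stack2 = ReconstructionStack(
            stack.amplitudes[::-1][order].copy(), stack.z_values, stack.optics
        )
        det2 = assign_depth(stack2, (70.0, 65.0), 15)
        assert det1.z == det2.z

    def test_window_outside_image_rejected(self):
        optics = OpticalConfig(image_shape=(32, 32))
        stack = ReconstructionStack(np.ones((2, 32, 32)), np.arange(2.0), optics)
        with pytest.raises(ValueError):
            assign_depth(stack, (300.0, 300.0), 5)

    def test_planar_target_depth_statistics(self, optics_bead):
        """Beads in one plane at z=100: mean assigned depth within 5 um."""
        truths = [(35, 35), (100, 40), (40, 100), (102, 98)]
        scene = SceneConfig(
            particles=[ParticleSpec(x=x, y=y, z=100.0) for x, y in truths],
            optics=optics_bead,
            rng_seed=6,
        )
        stack = reconstruct_volume(render_hologram(scene), 0, 150, 1, subtract_mean=True)
        detections = locate_all(stack, BEAD_PARAMS)
        assert len(detections) == len(truths)
        z_values = np.array([d.z for d in detections])
        assert abs(z_values.mean() - 100.0) <= 5.0
        assert z_values.std() <= 5.0


class TestLocateAll:
    def test_empty_stack_gives_empty_list(self):
        optics = OpticalConfig(image_shape=(32, 32))
        stack = ReconstructionStack(np.zeros((3, 32, 32)), np.arange(3.0), optics)
        assert locate_all(stack, PeakParams()) == []

    def test_three_depths_recovered(self, optics_bead):
        truths = [(40, 70, 30.0), (70, 40, 90.0), (95, 95, 150.0)]
        scene = SceneConfig(
            particles=[ParticleSpec(x=x, y=y, z=z) for x, y, z in truths],
            optics=optics_bead,
            rng_seed=12,
        )
        stack = reconstruct_volume(render_hologram(scene), 0, 180, 1, subtract_mean=True)
        detections = locate_all(stack, BEAD_PARAMS)
        assert len(detections) == 3
        for x_true, y_true, z_true in truths:
            det = min(detections, key=lambda d: (d.x - x_true) ** 2 + (d.y - y_true) ** 2)
            assert abs(det.z - z_true) <= 3.0

    def test_two_plane_scene_clusters_into_two_groups(self, optics_bead):
        truths = [(35, 35, 60.0), (100, 40, 60.0), (40, 100, 140.0), (100, 100, 140.0)]
        scene = SceneConfig(
            particles=[ParticleSpec(x=x, y=y, z=z) for x, y, z in truths],
            optics=optics_bead,
            rng_seed=4,
        )
        stack = reconstruct_volume(render_hologram(scene), 0, 180, 1, subtract_mean=True)
        z_found = sorted(d.z for d in locate_all(stack, BEAD_PARAMS))
        assert len(z_found) == 4
        # 1-D largest-gap split
        gaps = np.diff(z_found)
        split = int(np.argmax(gaps)) + 1
        low, high = z_found[:split], z_found[split:]
        assert len(low) == 2 and len(high) == 2
        assert np.ptp(low) <= 5 and np.ptp(high) <= 5
        assert abs(np.mean(low) - 60) <= 5 and abs(np.mean(high) - 140) <= 5
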