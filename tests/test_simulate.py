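"""Simulator contracts: determinism, physics signatures, dataset generation."""

import numpy as np
import pytest
from scipy.stats import kstest

from bf2holo.optics import OpticalConfig
from bf2holo.reconstruct import project_stack, reconstruct_volume
from bf2holo.simulate import (
    ParticleSpec,
    SceneConfig,
    make_dataset,
    render_brightfield,
    render_hologram,
    render_pair,
    scene_from_manifest_rows,
)


class TestParticleSpec:
    def test_rejects_negative_depth(self):
        with pytest.raises(ValueError):
            ParticleSpec(x=10, y=10, z=-1.0)

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            ParticleSpec(x=10, y=10, z=10, kind="cube")

    def test_default_bead_diameter(self):
        assert 2 * ParticleSpec(x=0, y=0, z=0).radius == pytest.approx(14.92)


class TestRenderHologram:
    def test_empty_scene_is_uniform_unity(self, optics_small):
        scene = SceneConfig(particles=[], optics=optics_small, noise_sigma_hologram=0.0)
        holo = render_hologram(scene)
        np.testing.assert_allclose(holo.values, 1.0)

    def test_intensities_bounded(self, single_bead_scene):
        holo = render_hologram(single_bead_scene)
        assert holo.values.min() >= 0.0 and holo.values.max() <= 1.0

    def test_seeded_rendering_is_bit_reproducible(self, single_bead_scene):
        a = render_hologram(single_bead_scene)
        b = render_hologram(single_bead_scene)
        np.testing.assert_array_equal(a.values, b.values)

    def test_fringe_spacing_grows_with_depth(self, optics_bead):
        """Deeper particles make coarser rings: fewer radial zero crossings."""

        def crossings(z):
            scene = SceneConfig(
                particles=[ParticleSpec(x=67.8, y=67.8, z=z)],
                optics=optics_bead,
                noise_sigma_hologram=0.0,
            )
            holo = render_hologram(scene)
            center = 127
            profile = holo.values[center, center : center + 60] - np.median(holo.values)
            return int(np.sum(np.abs(np.diff(np.sign(profile))) > 0))

        assert crossings(150.0) < crossings(50.0)

    def test_out_of_view_particle_skipped_with_warning(self, optics_small):
        scene = SceneConfig(
            particles=[ParticleSpec(x=500.0, y=500.0, z=50.0)], optics=optics_small
        )
        with pytest.warns(UserWarning, match="outside"):
            holo = render_hologram(scene)
        assert holo.particles == []

    def test_overlapping_particles_warn(self, optics_small):
        particles = [
            ParticleSpec(x=30.0, y=30.0, z=50.0),
            ParticleSpec(x=33.0, y=30.0, z=80.0),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            render_hologram(SceneConfig(particles=particles, optics=optics_small))

    def test_noise_changes_values_not_shape_or_metadata(self, optics_bead):
        base = dict(particles=[ParticleSpec(x=70, y=65, z=50)], optics=optics_bead, rng_seed=1)
        clean = render_hologram(SceneConfig(noise_sigma_hologram=0.0, **base))
        noisy = render_hologram(SceneConfig(noise_sigma_hologram=0.06, **base))
        assert clean.values.shape == noisy.values.shape
        assert len(clean.particles) == len(noisy.particles) == 1
        assert not np.array_equal(clean.values, noisy.values)


class TestRenderBrightfield:
    def test_empty_scene_uniform(self, optics_small):
        scene = SceneConfig(particles=[], optics=optics_small, noise_sigma_bf=0.0)
        np.testing.assert_allclose(render_brightfield(scene).values, 1.0)

    def test_in_focus_particle_is_sharp_dark_disk(self, optics_bead):
        p = ParticleSpec(x=70, y=65, z=0.0)
        scene = SceneConfig(particles=[p], optics=optics_bead, noise_sigma_bf=0.0)
        bf = render_brightfield(scene)
        rows, cols = np.where(bf.values < 0.5)
        assert len(rows) > 0
        extent_um = (cols.max() - cols.min()) * optics_bead.pixel_pitch
        assert extent_um == pytest.approx(2 * p.radius, abs=2 * optics_bead.pixel_pitch)

    def test_contrast_decreases_monotonically_with_depth(self, optics_bead):
        """Blur spreads the absorbed light, so in-disk contrast falls with z."""

        def disk_contrast(z):
            p = ParticleSpec(x=70, y=65, z=z)
            scene = SceneConfig(particles=[p], optics=optics_bead, noise_sigma_bf=0.0)
            bf = render_brightfield(scene)
            yy, xx = np.mgrid[0:256, 0:256]
            pitch = optics_bead.pixel_pitch
            rho = np.hypot((yy + 0.5) * pitch - p.y, (xx + 0.5) * pitch - p.x)
            return float(np.abs(1.0 - bf.values[rho < p.radius]).mean())

        c0, c50, c200 = disk_contrast(0), disk_contrast(50), disk_contrast(200)
        assert c200 < c50 < c0


class TestGeometryConsistency:
    def test_refocus_recovers_inplane_position_within_one_pixel(
        self, noise_free_bead_scene
    ):
        """Closes the loop: render, refocus at true z, find the extremum."""
        from scipy.ndimage import gaussian_filter

        holo = render_hologram(noise_free_bead_scene)
        p = noise_free_bead_scene.particles[0]
        stack = reconstruct_volume(holo, p.z, p.z, 1.0, subtract_mean=True)
        contrast = gaussian_filter(np.abs(stack.amplitudes[0] - stack.amplitudes[0].mean()), 14)
        row, col = np.unravel_index(np.argmax(contrast), contrast.shape)
        pitch = noise_free_bead_scene.optics.pixel_pitch
        assert abs((col + 0.5) * pitch - p.x) <= pitch
        assert abs((row + 0.5) * pitch - p.y) <= pitch


class TestMakeDataset:
    def test_dataset_files_and_replay(self, tmp_path):
        optics = OpticalConfig(image_shape=(64, 64))
        m1 = make_dataset(4, tmp_path / "a", seed=7, particle_density=(1, 3), optics=optics)
        m2 = make_dataset(4, tmp_path / "b", seed=7, particle_density=(1, 3), optics=optics)
        assert sorted(p.name for p in (tmp_path / "a").glob("*.tif")) == sorted(
            f"pair{i:05d}_{kind}.tif" for i in range(4) for kind in ("bf", "holo")
        )
        assert (tmp_path / "a" / "manifest.csv").exists()
        drop = ["bf_path", "holo_path"]
        assert m1.drop(columns=drop).equals(m2.drop(columns=drop))
        import tifffile

        a = tifffile.imread(tmp_path / "a" / "pair00000_holo.tif")
        b = tifffile.imread(tmp_path / "b" / "pair00000_holo.tif")
        np.testing.assert_array_equal(a, b)

    def test_depths_respect_range(self, tmp_path):
        optics = OpticalConfig(image_shape=(64, 64))
        manifest = make_dataset(
            10, tmp_path, seed=3, depth_range=(0.0, 200.0), optics=optics, write_images=False
        )
        assert manifest.z_um.between(0.0, 200.0).all()

    def test_depths_uniform_by_ks(self, tmp_path):
        optics = OpticalConfig(image_shape=(64, 64))
        manifest = make_dataset(
            100, tmp_path, seed=11, particle_density=(1, 2),
            depth_range=(0.0, 200.0), optics=optics, write_images=False,
        )
        stat = kstest(manifest.z_um / 200.0, "uniform")
        assert stat.pvalue > 0.01

    def test_scene_replay_from_manifest(self, tmp_path):
        optics = OpticalConfig(image_shape=(64, 64))
        manifest = make_dataset(2, tmp_path, seed=5, optics=optics, write_images=False)
        rows = manifest[manifest.pair_id == 0]
        scene = scene_from_manifest_rows(rows, optics)
        bf, holo = render_pair(scene)
        bf2, holo2 = render_pair(scene)
        np.testing.assert_array_equal(holo.values, holo2.values)
        np.testing.assert_array_equal(bf.values, bf2.values)

    def test_rejects_bad_arguments(self, tmp_path):
        with pytest.raises(ValueError):
            make_dataset(0, tmp_path, seed=1)
        with pytest.raises(ValueError):
            make_dataset(2, tmp_path, seed=1, particle_density=(0, 2))
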