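"""Synthetic scene generator: textures, waves, deformations, ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from cardiomotion import (
    DeformationModel,
    SyntheticScene,
    WaveModel,
    add_noise,
    compensate_video,
    ellipse_mask,
    make_dataset,
    make_pair,
    make_texture,
    make_video,
    render_frame,
    wave_field,
)
from cardiomotion.synthetic import action_potential_shape


class TestTexture:
    def test_same_seed_identical(self):
        a = make_texture(64, 64, 3.0, seed=5)
        b = make_texture(64, 64, 3.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_value_range(self):
        tex = make_texture(64, 64, 3.0, seed=1)
        assert tex.min() >= 0.05 and tex.max() <= 1.0
        mask = ellipse_mask(64, 64)
        assert tex[mask].min() == pytest.approx(0.2)
        assert tex[mask].max() == pytest.approx(1.0)
        assert np.all(tex[~mask] == 0.05)

    def test_autocorrelation_tracks_correlation_length(self):
        # Gaussian-smoothed white noise has autocorrelation ~ N(0, sqrt(2)*s);
        # the measured half-width at half-maximum must be within 30% of the
        # analytic value sqrt(2 ln 2) * sqrt(2) * s
        for corr in (2.0, 4.0):
            rng = np.random.default_rng(3)
            field = ndimage.gaussian_filter(
                rng.standard_normal((256, 256)), corr, mode="wrap"
            )
            acf = np.fft.ifft2(np.abs(np.fft.fft2(field)) ** 2).real
            acf /= acf[0, 0]
            profile = acf[0, :64]
            half_width = np.argmax(profile < 0.5)
            expected = np.sqrt(2 * np.log(2)) * np.sqrt(2.0) * corr
            assert abs(half_width - expected) / expected < 0.3

    def test_too_small_correlation_rejected(self):
        with pytest.raises(ValueError):
            make_texture(32, 32, 0.5)


class TestWaveField:
    def test_zero_before_first_arrival(self):
        model = WaveModel(kind="planar", speed=0.5)
        v = wave_field(model, (32, 32), t=0.0)
        # wave enters at x = 0; far pixels not yet excited
        assert np.all(v[:, 16:] == 0.0)

    def test_peak_amplitude_is_one(self):
        model = WaveModel()
        s_peak = model.tau_rise * np.log1p(model.tau_decay / model.tau_rise)
        assert action_potential_shape(
            np.array([s_peak]), model.tau_rise, model.tau_decay
        )[0] == pytest.approx(1.0)
        # on the pixel grid the peak is sampled within 1/speed frames of s*
        v = wave_field(model, (64, 64), t=60.0)
        assert v.max() == pytest.approx(1.0, abs=0.01)

    def test_planar_front_advances_at_wave_speed(self):
        # track the leading v = 0.5 crossing along x between two times
        model = WaveModel(kind="planar", speed=0.5, direction=0.0)
        def front(t):
            v = wave_field(model, (4, 128), t)[0]
            return np.max(np.where(v >= 0.5)[0])
        dx = front(120.0) - front(80.0)
        assert dx == pytest.approx(0.5 * 40, abs=2)

    def test_spiral_wave_is_bounded(self):
        model = WaveModel(kind="spiral", origin=(32, 32))
        v = wave_field(model, (64, 64), t=200.0)
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_values_in_unit_interval(self):
        v = wave_field(WaveModel(), (32, 32), t=55.0)
        assert v.min() >= 0.0 and v.max() <= 1.0


class TestDeformation:
    def test_zero_amplitude_gives_zero_field(self):
        scene = SyntheticScene(deformation=DeformationModel(amplitude=0.0))
        assert np.all(scene.displacement(50) == 0.0)

    def test_magnitude_bounded_by_amplitude(self, default_scene):
        mags = [
            np.hypot(*np.moveaxis(default_scene.displacement(t), -1, 0)).max()
            for t in range(0, 150, 10)
        ]
        assert max(mags) <= 5.0 + 1e-6

    def test_contractile_matches_brute_force_construction(self):
        # independent re-derivation: low-pass the masked excitation with time
        # constant tau_em, Gaussian-smooth, take the negative gradient and
        # normalize the peak magnitude to the amplitude
        scene = SyntheticScene(
            width=32, height=32, duration=30,
            wave=WaveModel(speed=1.0, period=30.0),
            deformation=DeformationModel(amplitude=2.0, tau_em=4.0, sigma_d=5.0),
        )
        mask = scene.mask
        state = np.zeros((32, 32))
        raw = []
        for t in range(30):
            v = wave_field(scene.wave, (32, 32), float(t)) * mask
            state = state + (v - state) / 4.0
            phi = ndimage.gaussian_filter(state, 5.0, mode="nearest")
            gy, gx = np.gradient(phi)
            raw.append(np.stack([-gx, -gy], axis=-1))
        raw = np.array(raw)
        peak = np.hypot(raw[..., 0], raw[..., 1]).max()
        expected = raw * 2.0 / peak
        actual = np.array([scene.displacement(t) for t in range(30)])
        np.testing.assert_allclose(actual, expected, atol=1e-5)

    def test_bulk_deformation_is_zero_at_t0(self):
        scene = SyntheticScene(deformation=DeformationModel(kind="bulk"))
        np.testing.assert_allclose(scene.displacement(0), 0.0, atol=1e-9)

    def test_bulk_magnitude_bounded(self):
        scene = SyntheticScene(deformation=DeformationModel(kind="bulk", amplitude=3.0))
        for t in (20, 40, 75):
            d = scene.displacement(t)
            assert np.hypot(d[..., 0], d[..., 1]).max() <= 3.0 + 1e-6

    def test_deformation_is_invertible(self, default_scene):
        # |grad u| < 1 for relative displacements: the pair construction's
        # fixed-point inversion is a contraction
        u = default_scene.displacement(116) - default_scene.displacement(68)
        for c in range(2):
            gy, gx = np.gradient(u[..., c])
            assert max(np.abs(gx).max(), np.abs(gy).max()) < 1.0


class TestRenderFrame:
    def test_zero_fluorescence_returns_texture(self, default_scene):
        v = np.ones((128, 128))
        out = render_frame(default_scene.texture, v, 0.0, default_scene.mask)
        np.testing.assert_array_equal(out, default_scene.texture)

    def test_fluorescence_darkening_values(self):
        texture = np.full((4, 4), 0.5)
        v = np.ones((4, 4))
        out = render_frame(texture, v, -0.07)
        np.testing.assert_allclose(out, 0.465)
        out = render_frame(np.full((4, 4), 0.8), np.full((4, 4), 0.5), -0.10)
        np.testing.assert_allclose(out, 0.76)

    def test_background_unchanged(self, default_scene):
        v = np.ones((128, 128))
        out = render_frame(default_scene.texture, v, -0.2, default_scene.mask)
        np.testing.assert_array_equal(
            out[~default_scene.mask], default_scene.texture[~default_scene.mask]
        )

    def test_excessive_modulation_rejected(self):
        with pytest.raises(ValueError):
            render_frame(np.ones((2, 2)), np.ones((2, 2)), -1.5)


class TestAddNoise:
    def test_zero_sigma_is_identity(self, rng):
        frames = rng.random((3, 8, 8))
        np.testing.assert_array_equal(add_noise(frames, 0.0, 1), frames)

    def test_noise_standard_deviation(self):
        frames = np.zeros((128, 128))
        noisy = add_noise(frames, 0.03, seed=9)
        assert abs(noisy.std() - 0.03) / 0.03 < 0.05

    def test_same_seed_reproducible(self, rng):
        frames = rng.random((2, 16, 16))
        a = add_noise(frames, 0.05, seed=4)
        b = add_noise(frames, 0.05, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_values_not_clipped(self):
        noisy = add_noise(np.zeros((64, 64)), 0.5, seed=2)
        assert noisy.min() < 0.0


class TestMakePair:
    def test_static_scene_gives_identical_pair(self):
        scene = SyntheticScene(
            f=0.0, sigma=0.0, deformation=DeformationModel(amplitude=0.0)
        )
        image_a, image_b, u = make_pair(scene, 10, 60)
        np.testing.assert_array_equal(image_a, image_b)
        np.testing.assert_array_equal(u, 0.0)

    def test_round_trip_self_consistency(self, default_scene):
        # sampling B at x + u must reproduce the rendered frame at t2
        image_a, image_b, u = make_pair(default_scene, 20, 90)
        h, w = image_b.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        resampled = ndimage.map_coordinates(
            image_b, np.stack([yy + u[..., 1], xx + u[..., 0]]),
            order=1, mode="nearest",
        )
        assert np.abs(resampled - default_scene.rendered(90)).mean() <= 1e-2

    def test_displacement_bounded_by_twice_amplitude(self, default_scene):
        _, _, u = make_pair(default_scene, 5, 140)
        assert np.hypot(u[..., 0], u[..., 1]).max() <= 2 * 5.0 + 1e-6

    def test_equal_times_rejected(self, default_scene):
        with pytest.raises(ValueError):
            make_pair(default_scene, 10, 10)


class TestMakeDataset:
    def test_reproducible_under_master_seed(self, default_scene):
        a = make_dataset(default_scene, 3, seed=11)
        b = make_dataset(default_scene, 3, seed=11)
        for (a1, a2, au), (b1, b2, bu) in zip(a, b):
            np.testing.assert_array_equal(a1, b1)
            np.testing.assert_array_equal(a2, b2)
            np.testing.assert_array_equal(au, bu)

    def test_pair_count_and_nonzero_motion(self, default_scene):
        pairs = make_dataset(default_scene, 5, seed=2)
        assert len(pairs) == 5
        mean_u = np.mean(
            [np.hypot(u[..., 0], u[..., 1]).mean() for _, _, u in pairs]
        )
        assert mean_u > 0.0

    def test_different_seeds_differ(self, default_scene):
        a = make_dataset(default_scene, 2, seed=1)
        b = make_dataset(default_scene, 2, seed=99)
        assert not np.array_equal(a[0][0], b[0][0])


class TestMakeVideo:
    def test_static_scene_constant_video(self):
        scene = SyntheticScene(
            f=0.0, sigma=0.0, deformation=DeformationModel(amplitude=0.0)
        )
        video, truth = make_video(scene, 5)
        for t in range(1, 5):
            np.testing.assert_array_equal(video.frames[t], video.frames[0])
        np.testing.assert_array_equal(truth.fields, 0.0)

    def test_flow_field_count_matches_frames(self, default_scene):
        video, truth = make_video(default_scene, 10)
        assert video.n_frames == 10
        assert truth.n_frames == 10
        np.testing.assert_array_equal(truth.fields[0], 0.0)

    def test_compensation_round_trip(self):
        scene = SyntheticScene(sigma=0.0)
        video, truth = make_video(scene, 50)
        out = compensate_video(video, truth)
        maes = [
            np.abs(out.frames[t] - scene.rendered(t)).mean() for t in range(1, 50)
        ]
        assert np.mean(maes) <= 0.02

    def test_determinism_across_instances(self):
        video1, _ = make_video(SyntheticScene(sigma=0.02), 6)
        video2, _ = make_video(SyntheticScene(sigma=0.02), 6)
        np.testing.assert_allclose(video1.frames, video2.frames, atol=1e-12)
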