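"""Flow backends: registry contracts, accuracy on constructed motions."""

import numpy as np
import pytest
from scipy import ndimage

from cardiomotion import (
    FlowBackendSpec,
    FlowSequence,
    VideoStack,
    available_backends,
    estimate_flow_pair,
    estimate_flow_video,
    pyramidal_lk_dense,
    register_backend,
    smooth_flow,
)
from cardiomotion.optflow import get_backend

BACKENDS = ["lucas_kanade", "tvl1", "farneback", "lucas_kanade_native"]


@pytest.fixture(scope="module")
def texture():
    rng = np.random.default_rng(7)
    smooth = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 3.0, mode="wrap")
    return (smooth - smooth.min()) / (smooth.max() - smooth.min())


def shifted(image, dx, dy):
    """Content moved by (+dx, +dy): sample at (x - dx, y - dy)."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(
        image, np.stack([yy - dy, xx - dx]), order=3, mode="nearest"
    )


class TestRegistry:
    def test_reference_backends_registered(self):
        for name in BACKENDS:
            assert name in available_backends()

    def test_unknown_backend_raises(self, texture):
        with pytest.raises(KeyError, match="unknown flow backend"):
            estimate_flow_pair(texture, texture, "brox_gpu")

    def test_plugin_registration(self, texture):
        register_backend(
            "zero_plugin", lambda a, b, **kw: np.zeros(a.shape + (2,))
        )
        try:
            flow = estimate_flow_pair(texture, texture, "zero_plugin")
            assert np.all(flow == 0.0)
        finally:
            from cardiomotion.optflow import _REGISTRY

            _REGISTRY.pop("zero_plugin", None)

    def test_minimum_size_upscaling(self):
        # a backend declaring a minimum size receives upscaled frames and
        # the returned flow is scaled back down
        seen = {}

        def probe(a, b, **kw):
            seen["shape"] = a.shape
            return np.full(a.shape + (2,), 2.0)

        register_backend("min_size_probe", probe, min_size=160)
        try:
            small = np.random.default_rng(0).random((64, 64))
            flow = estimate_flow_pair(small, small, "min_size_probe")
            assert min(seen["shape"]) >= 160
            assert flow.shape == (64, 64, 2)
            np.testing.assert_allclose(flow, 2.0 / (160 // 64 + 1), atol=1e-9)
        finally:
            from cardiomotion.optflow import _REGISTRY

            _REGISTRY.pop("min_size_probe", None)

    def test_shape_mismatch_raises(self, texture):
        with pytest.raises(ValueError, match="shape mismatch"):
            estimate_flow_pair(texture, texture[:-2], "farneback")


class TestEstimateFlowPair:
    @pytest.mark.parametrize("backend", BACKENDS)
    def test_identity_pair_near_zero(self, texture, backend):
        flow = estimate_flow_pair(texture, texture, backend)
        assert np.abs(flow).mean() < 0.05

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_integer_translation_recovered(self, texture, backend):
        frame = shifted(texture, 3.0, 0.0)
        flow = estimate_flow_pair(texture, frame, backend)
        interior = flow[16:-16, 16:-16]
        err = np.hypot(interior[..., 0] - 3.0, interior[..., 1]).mean()
        assert err < 0.1

    def test_quantizes_unit_input_to_8bit(self, texture):
        seen = {}

        def probe(a, b, **kw):
            seen["dtype"] = a.dtype
            return np.zeros(a.shape + (2,))

        register_backend("dtype_probe", probe)
        try:
            estimate_flow_pair(texture, texture, "dtype_probe")
            assert seen["dtype"] == np.uint8
        finally:
            from cardiomotion.optflow import _REGISTRY

            _REGISTRY.pop("dtype_probe", None)

    def test_nonfinite_backend_output_sanitized(self, texture):
        register_backend(
            "nan_probe", lambda a, b, **kw: np.full(a.shape + (2,), np.nan)
        )
        try:
            flow = estimate_flow_pair(texture, texture, "nan_probe")
            assert np.all(np.isfinite(flow))
        finally:
            from cardiomotion.optflow import _REGISTRY

            _REGISTRY.pop("nan_probe", None)


class TestEstimateFlowVideo:
    def test_static_video_fields_near_zero(self, texture):
        stack = VideoStack(np.stack([texture] * 3), bit_depth="unit")
        flow = estimate_flow_video(stack, 0, "farneback")
        assert np.all(flow.fields[0] == 0.0)
        assert np.abs(flow.fields).mean() < 0.05

    def test_constructed_shift_recovered(self, texture):
        frames = np.stack([texture, texture, shifted(texture, 2.0, 0.0)])
        stack = VideoStack(frames, bit_depth="unit")
        flow = estimate_flow_video(stack, 0, "farneback")
        interior = flow.fields[2][16:-16, 16:-16]
        assert np.hypot(interior[..., 0] - 2.0, interior[..., 1]).mean() < 0.1

    def test_reference_out_of_range(self, texture):
        stack = VideoStack(np.stack([texture] * 3), bit_depth="unit")
        with pytest.raises(IndexError):
            estimate_flow_video(stack, 3, "farneback")

    def test_direct_to_reference_no_chaining(self, texture):
        # permuting non-reference frames must permute outputs correspondingly
        frames = np.stack(
            [texture, shifted(texture, 1.0, 0.0), shifted(texture, 0.0, 2.0)]
        )
        permuted = frames[[0, 2, 1]]
        flow_a = estimate_flow_video(VideoStack(frames), 0, "farneback")
        flow_b = estimate_flow_video(VideoStack(permuted), 0, "farneback")
        np.testing.assert_allclose(flow_a.fields[1], flow_b.fields[2], atol=1e-12)
        np.testing.assert_allclose(flow_a.fields[2], flow_b.fields[1], atol=1e-12)


class TestNativeLucasKanade:
    def test_identical_images_give_zero_flow(self, texture):
        flow = pyramidal_lk_dense(texture, texture)
        assert np.abs(flow).mean() < 0.02

    def test_half_pixel_shift(self, texture):
        frame = shifted(texture, 0.5, 0.0)
        flow = pyramidal_lk_dense(texture, frame)
        interior = flow[16:-16, 16:-16]
        assert np.hypot(interior[..., 0] - 0.5, interior[..., 1]).mean() < 0.15

    def test_textureless_images_fall_back_to_zero(self):
        flow = pyramidal_lk_dense(np.full((64, 64), 0.5), np.full((64, 64), 0.5))
        np.testing.assert_array_equal(flow, 0.0)

    def test_even_window_rejected(self, texture):
        with pytest.raises(ValueError, match="odd"):
            pyramidal_lk_dense(texture, texture, window=14)

    def test_translation_equivariance(self, texture):
        # shifting both inputs by the same integer vector leaves interior
        # flow unchanged
        frame = shifted(texture, 1.5, 0.0)
        base = pyramidal_lk_dense(texture, frame)
        ref_s = np.roll(texture, (4, 4), axis=(0, 1))
        frm_s = np.roll(frame, (4, 4), axis=(0, 1))
        moved = pyramidal_lk_dense(ref_s, frm_s)
        a = base[16:-16, 16:-16]
        b = np.roll(moved, (-4, -4), axis=(0, 1))[16:-16, 16:-16]
        assert np.abs(a - b).mean() < 0.05


class TestSmoothFlow:
    def make_flow(self, rng):
        fields = rng.standard_normal((5, 8, 8, 2))
        fields[1] = 0.0
        return FlowSequence(fields, reference_index=1)

    def test_constant_field_unchanged(self):
        fields = np.full((3, 8, 8, 2), 1.5)
        fields[0] = 0.0
        flow = FlowSequence(fields, reference_index=0)
        out = smooth_flow(flow, 3, 3, 1)
        np.testing.assert_allclose(out.fields[1:], 1.5)

    def test_matches_componentwise_oracle(self, rng):
        from test_preprocess import brute_force_box_mean

        flow = self.make_flow(rng)
        out = smooth_flow(flow, 3, 3, 3)
        for c in range(2):
            expected = brute_force_box_mean(flow.fields[..., c], 3, 3, 3)
            expected[1] = 0.0  # reference field re-zeroed
            np.testing.assert_allclose(out.fields[..., c], expected, atol=1e-9)

    def test_reference_field_rezeroed(self, rng):
        out = smooth_flow(self.make_flow(rng), 3, 3, 3)
        np.testing.assert_array_equal(out.fields[1], 0.0)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            smooth_flow(self.make_flow(rng), 2, 3, 3)


class TestBackendContracts:
    def test_backend_bit_depths(self):
        for name in BACKENDS:
            assert get_backend(name).input_bit_depth == 8

    def test_backend_spec_carries_params(self, texture):
        spec = FlowBackendSpec("lucas_kanade_native", {"window": 9})
        flow = estimate_flow_pair(texture, texture, spec)
        assert flow.shape == texture.shape + (2,)
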