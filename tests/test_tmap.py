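"""Thresholding, normalisation and rendering of activation maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dipmap.protocol import SessionProtocol
from dipmap.simulate import ChannelGeometry, NoiseParams, default_profiles, make_cohort
from dipmap.tmap import (
    TMapParams,
    build_dataset,
    jet_colormap,
    render_tmap,
    t_to_activation,
)


class TestThresholding:
    def test_strict_threshold_and_normalisation(self):
        params = TMapParams()
        v = t_to_activation(np.array([1.65, 2.0]), np.array([0.01, 0.01]), params)
        np.testing.assert_allclose(v, [0.0, 1.0])  # 1.65 is excluded (strict >)

    def test_all_subthreshold_gives_zero_vector(self):
        params = TMapParams()
        v = t_to_activation(np.array([1.0, -3.0, 1.64]), np.array([0.2, 0.9, 0.06]), params)
        np.testing.assert_array_equal(v, np.zeros(3))

    def test_normalisation_arithmetic(self):
        params = TMapParams()
        v = t_to_activation(np.array([2.0, 4.0, 1.0]), np.array([0.01, 0.01, 0.01]), params)
        np.testing.assert_allclose(v, [0.5, 1.0, 0.0])

    def test_p_value_gate(self):
        params = TMapParams()
        v = t_to_activation(np.array([3.0, 3.0]), np.array([0.2, 0.01]), params)
        np.testing.assert_allclose(v, [0.0, 1.0])

    def test_infinite_t_saturates(self):
        params = TMapParams()
        v = t_to_activation(np.array([np.inf, 3.0, 1.0]), np.array([0.0, 0.01, 0.5]), params)
        assert v[0] == 1.0
        assert 0.0 < v[1] <= 1.0
        assert v[2] == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariants_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        params = TMapParams()
        t = rng.normal(0, 3, 36)
        p = rng.uniform(0, 1, 36)
        v = t_to_activation(t, p, params)
        assert np.all((v >= 0) & (v <= 1))
        suppressed = (t <= params.t_crt) | (p >= params.alpha)
        assert np.all(v[suppressed] == 0)
        if np.any(v > 0):
            assert v.max() == 1.0


class TestRendering:
    def test_output_shape_is_227_rgb(self, geometry):
        params = TMapParams()
        img = render_tmap(np.zeros(36), geometry, params)
        assert img.shape == (227, 227, 3)

    def test_all_zero_map_is_uniform_colormap_origin(self, geometry):
        params = TMapParams()
        img = render_tmap(np.zeros(36), geometry, params)
        origin = jet_colormap(256)[0]
        assert np.all(img.reshape(-1, 3) == origin)

    def test_single_hot_channel_peak_location(self, geometry):
        """Image maximum lies within 3 px of the hot channel's pixel."""
        params = TMapParams(grayscale=True)  # grayscale is monotone in the value
        for ch in (7, 14, 28):  # interior channels: linear interpolation governs
            v = np.zeros(36)
            v[ch] = 1.0
            img = render_tmap(v, geometry, params)
            intensity = img[..., 0]
            row, col = np.unravel_index(np.argmax(intensity), intensity.shape)
            x, y = geometry.xy[ch]
            exp_col = round(x * 226)
            exp_row = round((1 - y) * 226)
            assert abs(row - exp_row) <= 3 and abs(col - exp_col) <= 3

    def test_rendering_is_deterministic(self, geometry):
        params = TMapParams()
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, 36)
        np.testing.assert_array_equal(
            render_tmap(v, geometry, params), render_tmap(v, geometry, params)
        )

    def test_collinear_geometry_falls_back_to_nearest(self):
        geom = ChannelGeometry(
            channel_ids=("a", "b", "c"),
            xy=np.array([[0.1, 0.5], [0.5, 0.5], [0.9, 0.5]]),
        )
        params = TMapParams(image_size=64)
        img = render_tmap(np.array([0.0, 1.0, 0.0]), geom, params)
        assert img.shape == (64, 64, 3)
        assert np.all(np.isfinite(img))

    def test_grayscale_flag(self, geometry):
        params = TMapParams(grayscale=True)
        img = render_tmap(np.linspace(0, 1, 36), geometry, params)
        np.testing.assert_allclose(img[..., 0], img[..., 1])
        np.testing.assert_allclose(img[..., 1], img[..., 2])


class TestBuildDataset:
    def test_counts_and_metadata_small_cohort(self, geometry):
        pt, pl = default_profiles(geometry)
        proto = SessionProtocol(pre_rest_s=5.0, n_trials=2, post_rest_s=5.0)
        cohort = make_cohort(2, 2, pt, pl, NoiseParams(), seed=0,
                             protocol=proto, geometry=geometry)
        params = TMapParams(image_size=32)
        ds = build_dataset(cohort, [2.0, 4.0], params)
        # 2 subjects x 2 sessions x 2 trials x 2 windows
        assert len(ds) == 16
        assert (ds.labels == "RHTF").sum() == 8
        assert set(ds.meta["window_s"]) == {2.0, 4.0}
        assert ds.images.shape == (16, 32, 32, 3)
        assert ds.images.dtype == np.float32
        assert ds.images.min() >= 0.0 and ds.images.max() <= 1.0

    def test_empty_cohort_gives_empty_dataset(self):
        ds = build_dataset([], [2.0], TMapParams(image_size=32))
        assert len(ds) == 0

    def test_window_overrunning_session_rejected(self, geometry):
        pt, pl = default_profiles(geometry)
        proto = SessionProtocol(pre_rest_s=5.0, n_trials=1, post_rest_s=1.0, rest_s=2.0)
        cohort = make_cohort(1, 1, pt, pl, NoiseParams(), seed=0,
                             protocol=proto, geometry=geometry)
        with pytest.raises(ValueError):
            build_dataset(cohort, [14.0], TMapParams(image_size=32))
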