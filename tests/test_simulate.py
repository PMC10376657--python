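"""Synthetic session generator: construction, determinism, spectra."""

from dataclasses import replace

import numpy as np
import pytest

from dipmap.hrf import chrf
from dipmap.protocol import SessionProtocol
from dipmap.simulate import (
    ActivationProfile,
    ChannelGeometry,
    NoiseParams,
    default_geometry,
    default_profiles,
    make_cohort,
    simulate_session,
)
from dipmap.tmap import trial_regressor


def clean_profile(geometry, **kw):
    """Focal-only profile: full HRF on one footprint, nothing shared."""
    base = dict(
        class_label="RHTF",
        active_channels=(geometry.channel_ids[0],),
        amplitude=1.0, jitter_sd=0.0, spread_amplitude=0.0,
        channel_gain_sd=0.0, spread_center_jitter_sd=0.0, vaso_sd=0.0,
        focal_delayed_fraction=1.0,
    )
    base.update(kw)
    return ActivationProfile(**base)


class TestGeometry:
    def test_default_patch_has_36_distinct_channels(self, geometry):
        assert geometry.n_channels == 36
        assert len(set(map(tuple, geometry.xy.tolist()))) == 36
        assert np.all((geometry.xy >= 0) & (geometry.xy <= 1))

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError):
            ChannelGeometry(channel_ids=("a", "b"), xy=np.array([[0.1, 0.1], [0.1, 0.1]]))

    def test_unknown_channel_id_rejected(self, geometry):
        with pytest.raises(KeyError):
            geometry.index_of(["CH99"])

    def test_json_roundtrip(self, geometry, tmp_path):
        geometry.to_json(tmp_path / "geom.json")
        back = ChannelGeometry.from_json(tmp_path / "geom.json")
        assert back.channel_ids == geometry.channel_ids
        np.testing.assert_allclose(back.xy, geometry.xy)


class TestSimulateSession:
    def test_zero_noise_zero_amplitude_is_silent(self, geometry):
        proto = SessionProtocol()
        profile = clean_profile(geometry, amplitude=0.0)
        ts = simulate_session(proto, geometry, profile, NoiseParams.silent(), seed=0)
        np.testing.assert_array_equal(ts.data, np.zeros_like(ts.data))

    def test_noiseless_active_channel_is_scaled_dhrf(self, geometry):
        """First-trial segment of the active channel equals amplitude*dHRF."""
        proto = SessionProtocol()
        beta = 1.7
        profile = clean_profile(geometry, amplitude=beta)
        ts = simulate_session(proto, geometry, profile, NoiseParams.silent(), seed=0)
        onset = proto.onsets()[0]
        reg = trial_regressor(proto.trial_s, fs=proto.fs)
        seg = ts.data[0, onset : onset + len(reg)]
        np.testing.assert_allclose(seg, beta * reg.samples, rtol=1e-12, atol=1e-12)
        # every other channel stays exactly zero
        assert np.max(np.abs(ts.data[1:])) == 0.0

    def test_same_seed_is_bitwise_identical(self, geometry):
        proto = SessionProtocol(n_trials=2)
        profile, _ = default_profiles(geometry)
        a = simulate_session(proto, geometry, profile, NoiseParams(), seed=7)
        b = simulate_session(proto, geometry, profile, NoiseParams(), seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        c = simulate_session(proto, geometry, profile, NoiseParams(), seed=8)
        assert np.any(a.data != c.data)

    def test_sample_count_matches_protocol(self, geometry):
        proto = SessionProtocol(pre_rest_s=10, n_trials=2, post_rest_s=5)
        profile, _ = default_profiles(geometry)
        ts = simulate_session(proto, geometry, profile, NoiseParams(), seed=0)
        assert ts.data.shape == (36, proto.n_samples)

    def test_cardiac_only_noise_peaks_at_cardiac_frequency(self, geometry):
        """Dominant spectral peak of an inactive channel within 1 bin of 1.2 Hz."""
        proto = SessionProtocol()
        profile = clean_profile(geometry, amplitude=0.0)
        noise = NoiseParams(cardiac_amp=0.5, respiratory_amp=0, mayer_amp=0,
                            drift_slope=0, white_sd=0)
        ts = simulate_session(proto, geometry, profile, noise, seed=3)
        x = ts.data[5]
        spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
        freqs = np.fft.rfftfreq(len(x), d=1 / proto.fs)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 1.2) <= freqs[1]


class TestMakeCohort:
    def test_cohort_counts(self, geometry):
        pt, pl = default_profiles(geometry)
        cohort = make_cohort(11, 6, pt, pl, NoiseParams.silent(), seed=0, geometry=geometry)
        assert len(cohort) == 22
        rhtf = [s for s in cohort if s.label == "RHTF"]
        assert len(rhtf) == 11
        assert sum(s.protocol.n_trials for s in rhtf) == 66

    def test_single_subject_single_trial(self, geometry):
        pt, pl = default_profiles(geometry)
        cohort = make_cohort(1, 1, pt, pl, NoiseParams.silent(), seed=0, geometry=geometry)
        assert len(cohort) == 2
        assert all(s.protocol.n_trials == 1 for s in cohort)
        assert {s.label for s in cohort} == {"RHTF", "RHLF"}

    def test_cohort_determinism(self, geometry):
        pt, pl = default_profiles(geometry)
        a = make_cohort(2, 2, pt, pl, NoiseParams(), seed=7, geometry=geometry)
        b = make_cohort(2, 2, pt, pl, NoiseParams(), seed=7, geometry=geometry)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.data, sb.data)

    def test_identical_footprints_logged(self, geometry, caplog):
        pt, _ = default_profiles(geometry)
        same = replace(pt, class_label="RHLF")
        with caplog.at_level("WARNING"):
            make_cohort(1, 1, pt, same, NoiseParams.silent(), seed=0, geometry=geometry)
        assert any("identical" in rec.message for rec in caplog.records)

    def test_invalid_subject_count_rejected(self, geometry):
        pt, pl = default_profiles(geometry)
        with pytest.raises(ValueError):
            make_cohort(0, 6, pt, pl, NoiseParams(), seed=0, geometry=geometry)


class TestProfileValidation:
    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ActivationProfile(class_label="RHTF", active_channels=("CH01",), amplitude=-1.0)

    def test_noise_validation(self):
        with pytest.raises(ValueError):
            NoiseParams(white_sd=-0.1)
        with pytest.raises(ValueError):
            NoiseParams(cardiac_freq=0.0)
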