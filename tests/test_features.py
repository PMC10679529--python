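import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from conftest import apen_bruteforce
from tremorloop.features import (
    ApEnParams,
    RecordingSession,
    TriaxialRecording,
    approximate_entropy,
    peak_frequency,
    resultant_acceleration,
    session_features,
    smooth_recording,
    state_summary,
    vector_spectrum_peak,
)
from tremorloop.synth import EffectProfile, SessionSpec, SubjectSpec, generate_session


def _rec(x, y, z, fs=100.0):
    n = len(x)
    t = np.arange(n) / fs
    return TriaxialRecording(times=t, x=np.asarray(x, float), y=np.asarray(y, float),
                             z=np.asarray(z, float), fs_hz=fs)


class TestResultantAcceleration:
    @pytest.mark.parametrize(
        "xyz, expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 2.0, 2.0), 3.0)],
    )
    def test_known_triples(self, xyz, expected):
        rec = _rec([xyz[0]] * 4, [xyz[1]] * 4, [xyz[2]] * 4)
        np.testing.assert_allclose(resultant_acceleration(rec), expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TriaxialRecording(times=np.arange(3) / 100.0, x=np.zeros(3), y=np.zeros(2),
                              z=np.zeros(3), fs_hz=100.0)

    def test_rotation_invariance(self, rng):
        """The Euclidean norm is unchanged by any rigid rotation of the axes."""
        sig = rng.normal(size=(200, 3))
        rec = _rec(sig[:, 0], sig[:, 1], sig[:, 2])
        ra = resultant_acceleration(rec)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            rotated = sig @ rot.T
            rec_rot = _rec(rotated[:, 0], rotated[:, 1], rotated[:, 2])
            np.testing.assert_allclose(resultant_acceleration(rec_rot), ra, atol=1e-10)


class TestSmoothing:
    def test_zero_parameter_is_interpolation(self, rng):
        series = rng.normal(size=50)
        np.testing.assert_allclose(smooth_recording(series, 100.0, 0.0), series, atol=1e-8)

    def test_mild_smoothing_keeps_peak_frequency(self):
        fs, f = 100.0, 5.0
        t = np.arange(1000) / fs
        series = np.sin(2 * np.pi * f * t)
        smoothed = smooth_recording(series, fs, smoothing_param=1e-6)
        before = peak_frequency(series, fs, (1, 10)).freq_hz
        after = peak_frequency(smoothed, fs, (1, 10)).freq_hz
        assert abs(after - before) <= fs / len(series)

    def test_spike_suppressed(self):
        fs, f = 100.0, 5.0
        t = np.arange(500) / fs
        clean = np.sin(2 * np.pi * f * t)
        spiky = clean.copy()
        spiky[250] += 5.0
        smoothed = smooth_recording(spiky, fs)  # GCV-selected penalty
        assert np.max(np.abs(smoothed - clean)) < np.max(np.abs(spiky - clean))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            smooth_recording(np.array([1.0, 2.0, 3.0]), 100.0)


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(50, 3.7), ApEnParams(m=2, r=0.5, r_is_fraction=False)) == 0.0

    def test_alternating_pattern_matches_bruteforce(self):
        u = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], float)
        params = ApEnParams(m=2, r=0.5, r_is_fraction=False)
        expected = apen_bruteforce(u, 2, 0.5)
        assert approximate_entropy(u, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n,m,seed", [(50, 1, 0), (120, 2, 1), (400, 2, 2), (200, 3, 3)])
    def test_matches_bruteforce_on_random_series(self, n, m, seed):
        u = np.random.default_rng(seed).normal(size=n)
        r = 0.2 * np.std(u)
        expected = apen_bruteforce(u, m, r)
        got = approximate_entropy(u, ApEnParams(m=m, r=r, r_is_fraction=False))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_noise_more_complex_than_sinusoid(self, rng):
        n = 300
        noise = rng.uniform(-1, 1, n)
        t = np.arange(n) / 100.0
        tone = np.sin(2 * np.pi * 5 * t)
        tone = tone / tone.std() * noise.std()
        params = ApEnParams(m=2, r=0.2)
        assert approximate_entropy(noise, params) > approximate_entropy(tone, params)

    def test_shift_invariance(self, rng):
        u = rng.normal(size=150)
        params = ApEnParams()
        assert approximate_entropy(u + 100.0, params) == pytest.approx(
            approximate_entropy(u, params), abs=1e-9
        )

    def test_scale_invariance_with_fractional_radius(self, rng):
        u = rng.normal(size=150)
        params = ApEnParams(m=2, r=0.2, r_is_fraction=True)
        assert approximate_entropy(3.5 * u, params) == pytest.approx(
            approximate_entropy(u, params), abs=1e-9
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.array([1.0, 2.0, 3.0]), ApEnParams(m=2, r=0.2))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=12, max_size=40).filter(
            lambda u: max(u) - min(u) > 1e-6
        ),
        st.integers(1, 3),
    )
    def test_property_matches_bruteforce(self, values, m):
        """The optimized statistic equals the defining-equation oracle on
        arbitrary short series."""
        u = np.asarray(values)
        r = 0.3 * np.std(u)
        params = ApEnParams(m=m, r=r, r_is_fraction=False)
        assert approximate_entropy(u, params) == pytest.approx(
            apen_bruteforce(u, m, r), abs=1e-12
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.floats(-50, 50))
    def test_property_shift_invariance(self, seed, shift):
        u = np.random.default_rng(seed).normal(size=80)
        params = ApEnParams()
        assert approximate_entropy(u + shift, params) == pytest.approx(
            approximate_entropy(u, params), abs=1e-8
        )


class TestPeakFrequency:
    def test_on_bin_tone_exact(self):
        fs = 100.0
        t = np.arange(1000) / fs
        peak = peak_frequency(np.sin(2 * np.pi * 5 * t), fs, (1, 10))
        assert peak.freq_hz == 5.0
        assert peak.amplitude == pytest.approx(1.0, rel=1e-9)

    def test_dominant_of_two_tones(self):
        fs = 100.0
        t = np.arange(1000) / fs
        series = np.sin(2 * np.pi * 4 * t) + 0.5 * np.sin(2 * np.pi * 6 * t)
        assert peak_frequency(series, fs, (1, 10)).freq_hz == 4.0

    def test_off_bin_tone_within_one_bin(self):
        fs = 100.0
        t = np.arange(1000) / fs
        peak = peak_frequency(np.sin(2 * np.pi * 5.03 * t), fs, (1, 10))
        assert abs(peak.freq_hz - 5.03) <= peak.resolution_hz

    def test_noise_peak_much_weaker_than_tone(self):
        fs, n = 100.0, 2000
        t = np.arange(n) / fs
        tone = np.sqrt(2) * np.sin(2 * np.pi * 5 * t)  # unit variance
        tone_amp = peak_frequency(tone, fs, (1, 10)).amplitude
        for seed in range(5):
            noise = np.random.default_rng(seed).normal(size=n)  # unit variance
            assert peak_frequency(noise, fs, (1, 10)).amplitude < 0.3 * tone_amp

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            peak_frequency(np.sin(np.arange(100)), 100.0, (20.0, 10.0))


class TestSessionFeatures:
    @staticmethod
    def _clean_subject(seed=1, **overrides):
        kwargs = dict(
            tremor_freq_hz=5.0,
            base_amplitude=1.0,
            harmonic_ratios=(0.2, 0.1),
            noise_sd=0.0,
            axis_loading=(0.6, 0.48, 0.64),
            drift_sd=0.0,
            freq_jitter_sd=0.0,
            amp_jitter_sd=0.0,
            seed=seed,
        )
        kwargs.update(overrides)
        return SubjectSpec(**kwargs)

    def test_no_effect_gives_equal_mean_ra(self):
        session = generate_session(self._clean_subject(), EffectProfile.identity())
        df = session_features(session)
        means = df.groupby("state")["mean_ra"].mean()
        # harmonic phases are redrawn per interval, so state means wobble a
        # few percent even with zero noise; the null tolerance is +-5%
        assert means.max() / means.min() < 1.05

    def test_injected_attenuation_recovered(self):
        session = generate_session(self._clean_subject(), EffectProfile(during_scale=0.24))
        s = state_summary(session_features(session)).set_index("state")
        ratio = s.loc["during", "mean_ra"] / s.loc["pre", "mean_ra"]
        assert ratio == pytest.approx(0.24, abs=0.01)

    def test_noise_raises_apen(self):
        quiet = generate_session(self._clean_subject(), EffectProfile.identity())
        noisy = generate_session(
            self._clean_subject(noise_sd=0.3), EffectProfile.identity()
        )
        a_quiet = session_features(quiet)["apen"].mean()
        a_noisy = session_features(noisy)["apen"].mean()
        assert a_quiet < a_noisy

    def test_clean_tone_peak_frequency(self):
        session = generate_session(self._clean_subject(), EffectProfile.identity())
        df = session_features(session)
        fs = SessionSpec().fs_hz
        bin_hz = fs / (SessionSpec().interval_duration_s * fs)
        assert np.all(np.abs(df["peak_freq_hz"] - 5.0) <= bin_hz)

    def test_vector_spectrum_peak_is_rotation_invariant(self, rng):
        session = generate_session(self._clean_subject(noise_sd=0.1))
        rec = session.states["pre"][0]
        peak = vector_spectrum_peak(rec)
        rot = Rotation.random(rng=np.random.default_rng(0)).as_matrix()
        xyz = np.column_stack([rec.x, rec.y, rec.z]) @ rot.T
        rec2 = TriaxialRecording(rec.times, xyz[:, 0], xyz[:, 1], xyz[:, 2], rec.fs_hz)
        peak2 = vector_spectrum_peak(rec2)
        assert peak2.freq_hz == peak.freq_hz
        assert peak2.amplitude == pytest.approx(peak.amplitude, rel=1e-9)

    def test_missing_state_reported(self):
        session = generate_session(self._clean_subject())
        del session.states["during"]
        with pytest.raises(ValueError, match="during"):
            session_features(RecordingSession(session.subject, session.states))
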