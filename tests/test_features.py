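"""The 10 per-window COP / acceleration features."""

import numpy as np
import pytest

from fogmerge.core import CHANNEL_NAMES, Session
from fogmerge.features import (
    FEATURE_NAMES,
    N_FFT,
    cop_velocity,
    count_ap_reversals,
    dominant_fft_freq,
    extract_features,
    feature_matrix,
    wavelet_features,
)
from fogmerge.labeling import FOG, NONFOG, build_label_track
from fogmerge.synthio import CohortConfig, generate_session
from fogmerge.windowing import segment

FS = 100.0


def tone(freq, amp=1.0, n=100, fs=FS, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestCopVelocity:
    def test_constant_gives_zero(self):
        np.testing.assert_allclose(cop_velocity(np.full(50, 2.7), FS), 0.0)

    def test_ramp_slope_recovered(self):
        x = 3.0 * np.arange(100) / FS  # 3 cm/s
        np.testing.assert_allclose(cop_velocity(x, FS), 3.0)

    def test_differentiation_preserves_frequency(self):
        v = cop_velocity(tone(2.0, n=200), FS)
        assert dominant_fft_freq(v, FS) == pytest.approx(2.0, abs=FS / N_FFT)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cop_velocity([1.0], FS)


class TestDominantFFTFreq:
    def test_pure_tone_within_one_bin(self):
        assert dominant_fft_freq(tone(3.0), FS) == pytest.approx(3.0, abs=FS / N_FFT)

    def test_constant_maps_to_zero(self):
        assert dominant_fft_freq(np.full(100, 5.0), FS) == 0.0

    def test_larger_amplitude_tone_wins(self):
        x = tone(2.0, amp=1.0) + tone(7.0, amp=2.0)
        assert dominant_fft_freq(x, FS) == pytest.approx(7.0, abs=FS / N_FFT)

    def test_matches_dense_dft_scan(self):
        """Independent oracle: argmax of the explicitly computed DTFT
        magnitude over a dense frequency grid."""
        rng = np.random.default_rng(7)
        t = np.arange(100) / FS
        for _ in range(20):
            f = float(rng.uniform(1.0, 40.0))
            x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x0 = x - x.mean()
            grid = np.arange(0.05, 50.0, 0.01)
            mags = np.abs(np.exp(-2j * np.pi * np.outer(grid, t)) @ x0)
            oracle = grid[np.argmax(mags)]
            assert dominant_fft_freq(x, FS) == pytest.approx(oracle, abs=FS / N_FFT)

    def test_bounded_by_nyquist(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=100)
            assert 0.0 <= dominant_fft_freq(x, FS) <= FS / 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dominant_fft_freq([], FS)


class TestReversals:
    def test_monotone_ramp_has_none(self):
        assert count_ap_reversals(np.linspace(0, 5, 100)) == 0

    def test_full_sine_cycle_has_two(self):
        assert count_ap_reversals(tone(1.0, amp=2.0)) == 2

    def test_hysteresis_suppresses_noise(self):
        """With the guard well above the pairwise noise spread (6x the
        noise SD), the noisy count equals the brute-force turning-point
        count of the clean signal; without a guard it does not."""
        rng = np.random.default_rng(9)
        clean = tone(2.0, amp=1.0, n=200)
        d = np.sign(np.diff(clean))
        d = d[d != 0]
        oracle = int(np.sum(d[1:] != d[:-1]))
        assert oracle == 8  # 4 cycles x 2 turning points
        excess = 0
        for _ in range(10):
            noisy = clean + rng.normal(0, 0.033, size=clean.size)
            assert count_ap_reversals(noisy, hysteresis=0.2) == oracle
            excess += count_ap_reversals(noisy, hysteresis=1e-6) - oracle
        assert excess > 0  # raw sign-counting is degenerate on noise

    def test_subthreshold_wiggle_not_counted(self):
        assert count_ap_reversals(tone(5.0, amp=0.01), hysteresis=0.05) == 0


class TestWaveletFeatures:
    def test_zero_signal(self):
        assert wavelet_features(np.zeros(100)) == (0.0, 0.0, 0.0)

    def test_constant_gain_closed_form(self):
        # each analysis level scales a constant by sqrt(2): level 4 -> 4x
        c = 1.7
        energy, mean, detail_min = wavelet_features(np.full(100, c))
        assert mean == pytest.approx(4 * c, rel=1e-9)
        assert energy == pytest.approx(16 * c * c, rel=1e-9)
        assert detail_min == pytest.approx(0.0, abs=1e-9)

    def test_energy_nonnegative(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            energy, _, _ = wavelet_features(rng.normal(size=100))
            assert energy >= 0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            wavelet_features(np.ones(5))


@pytest.fixture(scope="module")
def session():
    return generate_session(
        CohortConfig(session_duration_s=60.0, episode_rate=6.0, seed=11),
        "PX", True, seed=11,
    )


class TestExtractFeatures:

    def test_deterministic(self, session):
        w = segment(session.duration_s, session.fs)[10]
        np.testing.assert_array_equal(
            extract_features(session, w), extract_features(session, w)
        )

    def test_missing_channel_named_in_error(self, session):
        broken = Session(
            "PY", session.fs,
            {k: v for k, v in session.channels.items() if k != "cop_ml_right"},
            session.episodes,
        )
        w = segment(broken.duration_s, broken.fs)[0]
        with pytest.raises(KeyError, match="cop_ml_right"):
            extract_features(broken, w)

    def test_constant_channels_give_zero_frequencies_and_reversals(self):
        channels = {name: np.full(600, 1.0) for name in CHANNEL_NAMES}
        s = Session("PZ", FS, channels)
        w = segment(s.duration_s, FS)[0]
        f = extract_features(s, w)
        np.testing.assert_allclose(f[:5], 0.0)
        np.testing.assert_allclose(f[6:8], 0.0)

    def test_batch_matches_per_window(self, session):
        windows = segment(session.duration_s, session.fs)[::17]
        batch = feature_matrix(session, windows)
        single = np.stack([extract_features(session, w) for w in windows])
        np.testing.assert_allclose(batch, single, rtol=1e-12, atol=1e-12)

    def test_translation_determinism(self):
        """Identical content at a shifted sample offset yields an
        identical vector (1 Hz content is periodic over 100 samples)."""
        t = np.arange(600) / FS
        channels = {
            name: np.sin(2 * np.pi * 1.0 * t + i) for i, name in enumerate(CHANNEL_NAMES)
        }
        s = Session("PT", FS, channels)
        windows = segment(s.duration_s, FS)
        w0 = windows[0]
        w5 = windows[5]  # start shifted by exactly one period (100 samples)
        np.testing.assert_allclose(
            extract_features(s, w0), extract_features(s, w5), atol=1e-9
        )

    def test_feature_vector_layout(self, session):
        assert len(FEATURE_NAMES) == 10
        w = segment(session.duration_s, session.fs)[0]
        assert extract_features(session, w).shape == (10,)


def test_fog_windows_separable_on_cop_ap_velocity_frequency():
    """On generator defaults, a single threshold on the dominant COP AP
    velocity frequency separates pure-FOG from pure-NonFOG windows with
    at least 90 % accuracy: the spectral floor downstream learning
    relies on."""
    cfg = CohortConfig(session_duration_s=120.0, episode_rate=5.0, seed=12)
    s = generate_session(cfg, "PS", True, seed=12)
    track = build_label_track(s.episodes, s.duration_s, s.fs)
    windows = segment(s.duration_s, s.fs)
    X = feature_matrix(s, windows)
    f2 = X[:, 1]
    pure_fog, pure_non = [], []
    for i, w in enumerate(windows):
        seg = track.labels[w.start_idx:w.stop_idx]
        if np.all(seg == FOG):
            pure_fog.append(f2[i])
        elif np.all(seg == NONFOG):
            pure_non.append(f2[i])
    assert len(pure_fog) > 10 and len(pure_non) > 10
    correct = np.sum(np.array(pure_fog) > 2.0) + np.sum(np.array(pure_non) <= 2.0)
    assert correct / (len(pure_fog) + len(pure_non)) >= 0.90
    # FOG spectra sit above NonFOG spectra on average
    assert np.mean(pure_fog) > np.mean(pure_non)
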