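"""The 10 per-window features computed from COP and thigh-acceleration
channels.

During normal stepping the centre of pressure oscillates in the
locomotor band (~1 Hz); during trembling freezes the dominant energy
moves to 3–8 Hz while forward progression is arrested. The feature set
captures this with dominant FFT frequencies of COP velocity and thigh
AP acceleration, wavelet approximation/detail summaries of COP AP
position (Daubechies-5, level 4 at 100 Hz: approximation band roughly
the 0–3 Hz locomotor band), and hysteresis-guarded counts of AP
direction reversals.
"""

from __future__ import annotations

import warnings
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pywt

from .core import (
    COP_AP_LEFT,
    COP_AP_RIGHT,
    COP_ML_RIGHT,
    THIGH_ACC_AP_LEFT,
    THIGH_ACC_AP_RIGHT,
    Session,
)

if TYPE_CHECKING:  # pragma: no cover
    from .windowing import Window

#: column order of the feature vector
FEATURE_NAMES = (
    "domfreq_copvel_ml_right",
    "domfreq_copvel_ap_right",
    "domfreq_copvel_ap_left",
    "domfreq_thighacc_ap_right",
    "domfreq_thighacc_ap_left",
    "wt_approx_mean_energy_cop_ap_right",
    "n_ap_reversals_right",
    "n_ap_reversals_left",
    "wt_approx_mean_cop_ap_right",
    "wt_detail_min_cop_ap_right",
)

#: zero-padded FFT length for dominant-frequency estimation (~0.39 Hz bins
#: for 1 s windows at 100 Hz)
N_FFT = 256

DEFAULT_WAVELET = "db5"
DEFAULT_LEVEL = 4
DEFAULT_HYSTERESIS = 0.05  # cm; noise guard for reversal counting

_AMP_EPS = 1e-12


def cop_velocity(cop_position: Sequence[float], fs: float) -> np.ndarray:
    """First-difference velocity estimate; output is one sample shorter."""
    x = np.asarray(cop_position, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.diff(x) * fs


def dominant_fft_freq(signal: Sequence[float], fs: float, n_fft: int = N_FFT) -> float:
    """Frequency of the largest-magnitude non-DC FFT bin.

    The mean is removed and the signal zero-padded to ``n_fft`` samples
    for finer peak localization. A (numerically) constant signal maps to
    0 Hz by convention.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    x = x - x.mean()
    if np.max(np.abs(x)) < _AMP_EPS:
        return 0.0
    n = max(n_fft, x.size)
    mag = np.abs(np.fft.rfft(x, n))
    k = int(np.argmax(mag[1:])) + 1
    return k * fs / n


def count_ap_reversals(
    cop_ap: Sequence[float], hysteresis: float = DEFAULT_HYSTERESIS
) -> int:
    """Direction reversals of the AP excursion, with a hysteresis guard.

    A reversal is counted when the signal retreats from its running
    extremum by more than ``hysteresis``; excursions smaller than the
    guard (sensor noise) are ignored. A monotone ramp has 0 reversals,
    one full large-amplitude sine cycle has 2.
    """
    x = np.asarray(cop_ap, dtype=float)
    count = 0
    direction = 0  # +1 rising, -1 falling, 0 undetermined
    extreme = x[0] if x.size else 0.0
    for v in x[1:]:
        if direction == 0:
            if v > extreme + hysteresis:
                direction = 1
                extreme = v
            elif v < extreme - hysteresis:
                direction = -1
                extreme = v
        elif direction == 1:
            if v > extreme:
                extreme = v
            elif v < extreme - hysteresis:
                count += 1
                direction = -1
                extreme = v
        else:
            if v < extreme:
                extreme = v
            elif v > extreme + hysteresis:
                count += 1
                direction = 1
                extreme = v
    return count


def _wavedec(x: np.ndarray, level: int, wavelet: str, axis: int = -1):
    # level 4 on 1 s windows exceeds pywt's no-boundary-effect level for
    # db5; symmetric extension handles the edges, silence the advisory.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning, module="pywt")
        return pywt.wavedec(x, wavelet, mode="symmetric", level=level, axis=axis)


def wavelet_features(
    cop_ap: Sequence[float],
    level: int = DEFAULT_LEVEL,
    wavelet_name: str = DEFAULT_WAVELET,
) -> tuple[float, float, float]:
    """(mean energy of approximation, mean approximation, min detail).

    Multilevel DWT with symmetric boundary extension; the approximation
    and detail coefficients are taken at the deepest level.
    """
    x = np.asarray(cop_ap, dtype=float)
    w = pywt.Wavelet(wavelet_name)
    if x.size < w.dec_len:
        raise ValueError(
            f"signal length {x.size} shorter than {wavelet_name} filter "
            f"support {w.dec_len}"
        )
    coeffs = _wavedec(x, level, wavelet_name)
    approx, detail = coeffs[0], coeffs[1]
    return float(np.mean(approx**2)), float(np.mean(approx)), float(np.min(detail))


def extract_features(
    session: Session,
    window: "Window",
    hysteresis: float = DEFAULT_HYSTERESIS,
    level: int = DEFAULT_LEVEL,
    wavelet_name: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """The 10-element feature vector for one window of one session.

    Order follows :data:`FEATURE_NAMES`. Raises ``KeyError`` naming the
    channel if one of the five required channels is absent.
    """
    sl = slice(window.start_idx, window.stop_idx)
    fs = session.fs
    ml_r = session.channel(COP_ML_RIGHT)[sl]
    ap_r = session.channel(COP_AP_RIGHT)[sl]
    ap_l = session.channel(COP_AP_LEFT)[sl]
    acc_r = session.channel(THIGH_ACC_AP_RIGHT)[sl]
    acc_l = session.channel(THIGH_ACC_AP_LEFT)[sl]

    energy, approx_mean, detail_min = wavelet_features(ap_r, level, wavelet_name)
    return np.array(
        [
            dominant_fft_freq(cop_velocity(ml_r, fs), fs),
            dominant_fft_freq(cop_velocity(ap_r, fs), fs),
            dominant_fft_freq(cop_velocity(ap_l, fs), fs),
            dominant_fft_freq(acc_r, fs),
            dominant_fft_freq(acc_l, fs),
            energy,
            float(count_ap_reversals(ap_r, hysteresis)),
            float(count_ap_reversals(ap_l, hysteresis)),
            approx_mean,
            detail_min,
        ]
    )


# ---------------------------------------------------------------------------
# batched extraction (vectorized FFT / DWT; identical output to the
# per-window functions, asserted in the test suite)

def _window_view(x: np.ndarray, windows: list["Window"]) -> np.ndarray:
    return np.stack([x[w.start_idx:w.stop_idx] for w in windows])


def _batch_domfreq(rows: np.ndarray, fs: float, n_fft: int = N_FFT) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    n = max(n_fft, rows.shape[1])
    mag = np.abs(np.fft.rfft(rows, n, axis=1))
    k = np.argmax(mag[:, 1:], axis=1) + 1
    freqs = k * fs / n
    freqs[np.max(np.abs(rows), axis=1) < _AMP_EPS] = 0.0
    return freqs


def feature_matrix(
    session: Session,
    windows: list["Window"],
    hysteresis: float = DEFAULT_HYSTERESIS,
    level: int = DEFAULT_LEVEL,
    wavelet_name: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Feature vectors for all windows at once (rows align with ``windows``)."""
    if not windows:
        return np.zeros((0, len(FEATURE_NAMES)))
    fs = session.fs
    ml_r = _window_view(session.channel(COP_ML_RIGHT), windows)
    ap_r = _window_view(session.channel(COP_AP_RIGHT), windows)
    ap_l = _window_view(session.channel(COP_AP_LEFT), windows)
    acc_r = _window_view(session.channel(THIGH_ACC_AP_RIGHT), windows)
    acc_l = _window_view(session.channel(THIGH_ACC_AP_LEFT), windows)

    X = np.empty((len(windows), len(FEATURE_NAMES)))
    X[:, 0] = _batch_domfreq(np.diff(ml_r, axis=1) * fs, fs)
    X[:, 1] = _batch_domfreq(np.diff(ap_r, axis=1) * fs, fs)
    X[:, 2] = _batch_domfreq(np.diff(ap_l, axis=1) * fs, fs)
    X[:, 3] = _batch_domfreq(acc_r, fs)
    X[:, 4] = _batch_domfreq(acc_l, fs)
    coeffs = _wavedec(ap_r, level, wavelet_name, axis=1)
    approx, detail = coeffs[0], coeffs[1]
    X[:, 5] = np.mean(approx**2, axis=1)
    X[:, 6] = [count_ap_reversals(row, hysteresis) for row in ap_r]
    X[:, 7] = [count_ap_reversals(row, hysteresis) for row in ap_l]
    X[:, 8] = np.mean(approx, axis=1)
    X[:, 9] = np.min(detail, axis=1)
    return X
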