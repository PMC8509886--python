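"""Sliding-window segmentation and task-specific window targets.

Sessions are cut into 1 s windows advanced in 0.2 s steps (80 %
overlap). Windows are *not* required to be homogeneous, so no FOG data
is discarded. Detection targets are windows containing any FOG sample;
prediction targets are windows whose *start* falls in the 2 s zone
immediately before an onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import FOGEpisode, Session
from .labeling import FOG, LabelTrack, build_label_track, merge_episodes

logger = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass(frozen=True)
class Window:
    """A fixed-length signal segment starting at ``start_s`` seconds."""

    start_s: float
    length_s: float
    start_idx: int
    n_samples: int

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s

    @property
    def stop_idx(self) -> int:
        return self.start_idx + self.n_samples


def segment(
    duration_s: float,
    fs: float,
    length_s: float = 1.0,
    shift_s: float = 0.2,
) -> list[Window]:
    """Windows at starts 0, shift, 2*shift, ... with the last start no
    later than ``duration_s - length_s``.

    Count = floor((duration - length)/shift) + 1. Sample spans use
    ``floor(start_s * fs)`` with a fixed sample count of
    ``round(length_s * fs)`` so segmentation is bit-stable.
    """
    if length_s <= 0 or not (0 < shift_s <= length_s):
        raise ValueError("require length_s > 0 and 0 < shift_s <= length_s")
    if duration_s < length_s:
        logger.warning(
            "duration %.3f s shorter than window length %.3f s: no windows",
            duration_s, length_s,
        )
        return []
    n_win = int(np.floor((duration_s - length_s) / shift_s + _TOL)) + 1
    n_samples = int(round(length_s * fs))
    windows = []
    for k in range(n_win):
        start_s = k * shift_s
        start_idx = int(np.floor(start_s * fs + _TOL))
        windows.append(Window(start_s, length_s, start_idx, n_samples))
    return windows


def assign_detection_label(window: Window, track: LabelTrack) -> bool:
    """Detection target: the window contains at least one FOG sample."""
    return bool(np.any(track.labels[window.start_idx:window.stop_idx] == FOG))


def assign_prediction_label(
    window: Window,
    episodes_merged: list[FOGEpisode],
    prefog_s: float = 2.0,
) -> bool:
    """Prediction target: the window *begins* during the ``prefog_s``
    seconds prior to some (merged) episode onset.

    The zone is closed on the left and open on the right:
    ``onset - prefog_s <= start < onset``. A window starting exactly at
    the onset (pure-FOG content) is a non-target.
    """
    s = window.start_s
    for ep in episodes_merged:
        if ep.onset_s - prefog_s - _TOL <= s < ep.onset_s - _TOL:
            return True
    return False


def detection_labels(windows: list[Window], track: LabelTrack) -> np.ndarray:
    """Vectorized detection targets for a window list."""
    if not windows:
        return np.zeros(0, dtype=bool)
    fog_cum = np.concatenate([[0], np.cumsum(track.labels == FOG)])
    starts = np.array([w.start_idx for w in windows])
    stops = np.minimum(np.array([w.stop_idx for w in windows]), len(track.labels))
    return (fog_cum[stops] - fog_cum[starts]) > 0


def prediction_labels(
    windows: list[Window],
    episodes_merged: list[FOGEpisode],
    prefog_s: float = 2.0,
) -> np.ndarray:
    starts = np.array([w.start_s for w in windows])
    out = np.zeros(len(windows), dtype=bool)
    for ep in episodes_merged:
        out |= (starts >= ep.onset_s - prefog_s - _TOL) & (starts < ep.onset_s - _TOL)
    return out


def build_window_table(
    session: Session,
    mt_s: float = 0.0,
    prefog_s: float = 2.0,
    length_s: float = 1.0,
    shift_s: float = 0.2,
):
    """Full per-window table for one session at one merging threshold.

    Returns a :class:`pandas.DataFrame` with window metadata, both task
    targets, and the 10 features (columns named after
    :data:`fogmerge.features.FEATURE_NAMES`).
    """
    import pandas as pd

    from .features import FEATURE_NAMES, feature_matrix

    merged = merge_episodes(session.episodes, mt_s)
    track = build_label_track(merged, session.duration_s, session.fs, prefog_s)
    windows = segment(session.duration_s, session.fs, length_s, shift_s)
    X = feature_matrix(session, windows)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "participant_id", session.participant_id)
    df.insert(1, "start_s", [w.start_s for w in windows])
    df.insert(2, "end_s", [w.end_s for w in windows])
    df.insert(3, "label_detection", detection_labels(windows, track).astype(int))
    df.insert(
        4, "label_prediction",
        prediction_labels(windows, merged, prefog_s).astype(int),
    )
    return df
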