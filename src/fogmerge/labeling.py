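"""Episode merging and ternary ground-truth label tracks.

Two successive freezes separated by less than a merging threshold
``mt`` are fused into one episode, with the intervening samples
relabeled as FOG; the per-sample ground truth distinguishes NonFOG,
PreFOG (the 2 s immediately before an onset) and FOG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FOGEpisode, validate_episodes

NONFOG = 0
PREFOG = 1
FOG = 2

LABEL_NAMES = {NONFOG: "NonFOG", PREFOG: "PreFOG", FOG: "FOG"}

#: tolerance for float time comparisons (well below one sample at 100 Hz)
_TOL = 1e-9


@dataclass
class LabelTrack:
    """Per-sample ternary labels (NonFOG=0 / PreFOG=1 / FOG=2) at ``fs`` Hz."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.labels)

    def fog_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of FOG samples as half-open index ranges."""
        is_fog = np.concatenate([[False], self.labels == FOG, [False]])
        edges = np.flatnonzero(np.diff(is_fog.astype(np.int8)))
        return list(zip(edges[0::2], edges[1::2]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sample_index": np.arange(len(self.labels)),
             "label": [LABEL_NAMES[v] for v in self.labels]}
        )


def merge_episodes(episodes: list[FOGEpisode], mt_s: float) -> list[FOGEpisode]:
    """Fuse successive episodes separated by a gap strictly less than ``mt_s``.

    A single left-to-right pass: whenever ``next.onset - prev.end < mt_s``
    the two freezes become one spanning the first onset to the last end
    (the gap is relabeled FOG downstream). A gap exactly equal to the
    threshold is *not* merged, and ``mt_s = 0`` is the identity (the
    unmerged, event-based condition). Merging a pair never changes the
    gap to the following episode, so one pass reaches the fixpoint.
    """
    if mt_s < 0:
        raise ValueError("merging threshold must be non-negative")
    validate_episodes(episodes)
    if not episodes or mt_s == 0:
        return list(episodes)
    merged: list[FOGEpisode] = [episodes[0]]
    for ep in episodes[1:]:
        prev = merged[-1]
        if ep.onset_s - prev.end_s < mt_s - _TOL:
            merged[-1] = FOGEpisode(prev.onset_s, ep.end_s)
        else:
            merged.append(ep)
    return merged


def count_reduction(episodes: list[FOGEpisode], mt_s: float) -> int:
    """How many episodes disappear when merging with threshold ``mt_s``."""
    return len(episodes) - len(merge_episodes(episodes, mt_s))


def build_label_track(
    episodes: list[FOGEpisode],
    duration_s: float,
    fs: float,
    prefog_s: float = 2.0,
) -> LabelTrack:
    """Ternary per-sample labels for a session of ``duration_s`` seconds.

    Sample ``i`` (time ``i/fs``) is FOG iff ``onset <= t < end`` for some
    episode; PreFOG iff ``onset - prefog_s <= t < onset`` and not FOG;
    NonFOG otherwise. FOG takes precedence, so a PreFOG zone is truncated
    at the session start and at a preceding episode's end.
    """
    validate_episodes(episodes)
    n = int(round(duration_s * fs))
    labels = np.full(n, NONFOG, dtype=np.int8)
    for ep in episodes:
        if ep.end_s > duration_s + _TOL or ep.onset_s < -_TOL:
            raise ValueError(
                f"episode ({ep.onset_s}, {ep.end_s}) outside [0, {duration_s}]"
            )
    for ep in episodes:
        start = int(np.ceil(ep.onset_s * fs - _TOL))
        stop = min(int(np.ceil(ep.end_s * fs - _TOL)), n)
        labels[start:stop] = FOG
    for ep in episodes:
        start = max(int(np.ceil((ep.onset_s - prefog_s) * fs - _TOL)), 0)
        stop = min(int(np.ceil(ep.onset_s * fs - _TOL)), n)
        zone = labels[start:stop]
        zone[zone == NONFOG] = PREFOG
    return LabelTrack(labels, fs)
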