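"""Core containers shared across the pipeline.

A recording session is a set of synchronized 100 Hz channels — foot
centre-of-pressure (COP) positions and thigh anterior-posterior (AP)
accelerations — plus an ordered list of annotated freezing-of-gait
(FOG) episodes delimited by event-based onset/end instants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Canonical channel names. COP positions are in cm, accelerations in g.
COP_AP_LEFT = "cop_ap_left"
COP_AP_RIGHT = "cop_ap_right"
COP_ML_RIGHT = "cop_ml_right"
THIGH_ACC_AP_LEFT = "thigh_acc_ap_left"
THIGH_ACC_AP_RIGHT = "thigh_acc_ap_right"

CHANNEL_NAMES = (
    COP_AP_LEFT,
    COP_AP_RIGHT,
    COP_ML_RIGHT,
    THIGH_ACC_AP_LEFT,
    THIGH_ACC_AP_RIGHT,
)


@dataclass(frozen=True, order=True)
class FOGEpisode:
    """One annotated freeze.

    ``onset_s`` is the instant the stepping foot fails to leave the
    ground despite a clear intention to step; ``end_s`` the instant an
    effective step begins or resumes.
    """

    onset_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_s < self.end_s):
            raise ValueError(
                f"invalid episode: require 0 <= onset < end, got "
                f"({self.onset_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


def as_episodes(pairs) -> list[FOGEpisode]:
    """Coerce an iterable of (onset, end) pairs / episodes to episodes."""
    out = []
    for p in pairs:
        if isinstance(p, FOGEpisode):
            out.append(p)
        else:
            onset, end = p
            out.append(FOGEpisode(float(onset), float(end)))
    return out


def validate_episodes(episodes: list[FOGEpisode]) -> None:
    """Require episodes sorted by onset and pairwise disjoint."""
    for prev, nxt in zip(episodes, episodes[1:]):
        if nxt.onset_s < prev.end_s:
            raise ValueError(
                f"episodes must be sorted and non-overlapping: "
                f"({prev.onset_s}, {prev.end_s}) then ({nxt.onset_s}, {nxt.end_s})"
            )


@dataclass
class Session:
    """One participant's continuous recording.

    Channels all share the sampling rate ``fs`` and an equal number of
    samples; ``episodes`` holds the (unmerged, event-based) FOG
    annotation. Participants with no episodes are valid non-freezers.
    """

    participant_id: str
    fs: float
    channels: dict[str, np.ndarray]
    episodes: list[FOGEpisode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        validate_episodes(self.episodes)
        for ep in self.episodes:
            if ep.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"episode ({ep.onset_s}, {ep.end_s}) exceeds session "
                    f"duration {self.duration_s}"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def is_freezer(self) -> bool:
        return len(self.episodes) > 0

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"session {self.participant_id!r} is missing channel {name!r}"
            ) from None

    def __eq__(self, other) -> bool:  # exact (bitwise) equality, for round-trips
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.fs == other.fs
            and set(self.channels) == set(other.channels)
            and all(np.array_equal(self.channels[k], other.channels[k]) for k in self.channels)
            and self.episodes == other.episodes
        )
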