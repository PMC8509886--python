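"""Seeded synthetic gait cohorts with annotated FOG episodes.

The generator emulates the statistical structure the downstream
analysis relies on, at nominal units and desk scale:

* ~1 Hz locomotor-band COP oscillation (stride-scale amplitude, cm)
  and thigh AP acceleration (g) during normal gait;
* 3–8 Hz trembling with arrested forward progression during a freeze;
* degraded gait (amplitude loss, frequency drift) over the 2 s
  pre-onset zone;
* heterogeneous episode counts across participants, including
  rapid-succession clusters, and a cohort containing both freezers and
  non-freezers (defaults: 11 participants, 7 of whom freeze).

Episode placement draws the per-session episode count from a Poisson
law matched to the configured rate, groups episodes into geometric
clusters with short intra-cluster gaps, and spreads the clusters over
the session with exponential spacings, so annotations are disjoint by
construction and the realized rate is unbiased.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .core import CHANNEL_NAMES, FOGEpisode, Session, validate_episodes


class ConfigError(ValueError):
    """Raised for an invalid cohort configuration."""


class ParseError(ValueError):
    """Raised when a stored session file is malformed."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference cohort shape (11 participants, 7
    freezers) at desk scale: 5-minute sessions and an episode rate of
    2 per minute per freezer (roughly the reference cohort's 362
    episodes over 241 minutes across 7 freezers). ``cluster_gap_dist``
    spans 0.3–2.5 s so merging thresholds of 1–3 s partition clusters
    nontrivially.
    """

    n_participants: int = 11
    n_freezers: int = 7
    session_duration_s: float = 300.0
    episode_rate: float = 2.0  # episodes / minute / freezer
    episode_duration_dist: tuple[float, float] = (2.0, 6.0)
    cluster_prob: float = 0.3
    cluster_gap_dist: tuple[float, float] = (0.3, 2.5)
    gait_freq_hz: float = 1.0
    fog_tremble_freq_hz: tuple[float, float] = (3.0, 8.0)
    prefog_degradation: float = 0.4
    noise_sd: float = 0.05
    fs: float = 100.0
    gait_amp_cm: float = 3.0
    tremble_amp_cm: float = 2.0
    acc_amp_g: float = 0.5
    tremble_acc_amp_g: float = 0.3
    quantize_30hz: bool = False  # optional 30 Hz annotation grid, off by default
    seed: int = 0

    def validate(self) -> None:
        if self.n_freezers > self.n_participants or self.n_freezers < 0:
            raise ConfigError("require 0 <= n_freezers <= n_participants")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        positive = {
            "session_duration_s": self.session_duration_s,
            "episode_rate": self.episode_rate,
            "gait_freq_hz": self.gait_freq_hz,
            "fs": self.fs,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        for name, dist in (
            ("episode_duration_dist", self.episode_duration_dist),
            ("cluster_gap_dist", self.cluster_gap_dist),
            ("fog_tremble_freq_hz", self.fog_tremble_freq_hz),
        ):
            lo, hi = dist
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi, got {dist}")
        if not (0 <= self.cluster_prob <= 1):
            raise ConfigError("cluster_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.prefog_degradation < 0:
            raise ConfigError("noise_sd and prefog_degradation must be >= 0")


# ---------------------------------------------------------------------------
# episode placement

_EDGE_MARGIN_S = 3.0  # keep episodes away from session edges


def _sample_episodes(rng: np.random.Generator, cfg: CohortConfig) -> list[FOGEpisode]:
    """Disjoint episode annotation with Poisson count and clustered structure."""
    duration = cfg.session_duration_s
    n = int(rng.poisson(cfg.episode_rate * duration / 60.0))
    n = max(n, 1)  # a freezer has at least one episode

    dlo, dhi = cfg.episode_duration_dist
    glo, ghi = cfg.cluster_gap_dist

    # partition the n episodes into clusters (geometric sizes)
    cluster_sizes: list[int] = []
    remaining = n
    while remaining > 0:
        size = 1
        while remaining - size > 0 and rng.random() < cfg.cluster_prob:
            size += 1
        cluster_sizes.append(size)
        remaining -= size

    durations = rng.uniform(dlo, dhi, size=n)
    intra_gaps = rng.uniform(glo, ghi, size=max(n - len(cluster_sizes), 0))

    # drop trailing clusters if the session cannot hold everything
    usable = duration - 2 * _EDGE_MARGIN_S
    while cluster_sizes:
        n_eff = sum(cluster_sizes)
        occupied = durations[:n_eff].sum() + intra_gaps[: n_eff - len(cluster_sizes)].sum()
        if occupied <= usable or len(cluster_sizes) == 1 and cluster_sizes[0] == 1:
            break
        if cluster_sizes[-1] > 1:
            cluster_sizes[-1] -= 1
        else:
            cluster_sizes.pop()
    n_eff = sum(cluster_sizes)
    durations = durations[:n_eff]
    intra_gaps = intra_gaps[: n_eff - len(cluster_sizes)]
    occupied = durations.sum() + intra_gaps.sum()

    free = max(usable - occupied, 0.0)
    spacers = rng.exponential(1.0, size=len(cluster_sizes) + 1)
    spacers = spacers / spacers.sum() * free

    episodes: list[FOGEpisode] = []
    t = _EDGE_MARGIN_S
    i = 0
    gi = 0
    for ci, size in enumerate(cluster_sizes):
        t += spacers[ci]
        for k in range(size):
            onset, end = t, t + durations[i]
            if cfg.quantize_30hz:
                onset = math.floor(onset * 30) / 30
                end = math.ceil(end * 30) / 30
            episodes.append(FOGEpisode(onset, end))
            t = t + durations[i]
            i += 1
            if k < size - 1:
                t += intra_gaps[gi]
                gi += 1
    validate_episodes(episodes)
    return episodes


# ---------------------------------------------------------------------------
# signal synthesis

_FOG_LOCOMOTOR_RESIDUAL = 0.05  # forward progression arrested during a freeze


def _synthesize_channels(
    rng: np.random.Generator, cfg: CohortConfig, episodes: list[FOGEpisode]
) -> dict[str, np.ndarray]:
    fs = cfg.fs
    n = int(round(cfg.session_duration_s * fs))
    t = np.arange(n) / fs

    scale = rng.uniform(0.8, 1.2)  # inter-participant amplitude variation
    phi = rng.uniform(0, 2 * np.pi)

    fog = np.zeros(n, dtype=bool)
    ramp = np.zeros(n)  # pre-onset degradation ramp, 0 -> 1 at onset
    trem_freq = np.zeros(n)
    for ep in episodes:
        fog |= (t >= ep.onset_s) & (t < ep.end_s)
        pre = (t >= ep.onset_s - 2.0) & (t < ep.onset_s)
        ramp[pre] = np.maximum(ramp[pre], (t[pre] - (ep.onset_s - 2.0)) / 2.0)
        f_ep = rng.uniform(*cfg.fog_tremble_freq_hz)
        trem_freq[(t >= ep.onset_s) & (t < ep.end_s)] = f_ep
    ramp[fog] = 0.0

    deg = cfg.prefog_degradation
    amp_env = (1.0 - deg * ramp) * np.where(fog, _FOG_LOCOMOTOR_RESIDUAL, 1.0)
    f_loco = cfg.gait_freq_hz * (1.0 + deg * ramp)
    phase_loco = 2 * np.pi * np.cumsum(f_loco) / fs + phi
    phase_trem = 2 * np.pi * np.cumsum(trem_freq) / fs + phi
    trem_env = np.where(fog, 1.0, 0.0)

    a_cop = cfg.gait_amp_cm * scale
    a_trem = cfg.tremble_amp_cm * scale
    a_acc = cfg.acc_amp_g * scale
    a_tacc = cfg.tremble_acc_amp_g * scale

    def noise(sd: float) -> np.ndarray:
        return rng.normal(0.0, sd, n)

    channels = {
        "cop_ap_right": a_cop * amp_env * np.sin(phase_loco)
        + a_trem * trem_env * np.sin(phase_trem)
        + noise(cfg.noise_sd),
        "cop_ap_left": a_cop * amp_env * np.sin(phase_loco + np.pi)
        + a_trem * trem_env * np.sin(phase_trem + np.pi)
        + noise(cfg.noise_sd),
        "cop_ml_right": 0.5 * a_cop * amp_env * np.sin(phase_loco + np.pi / 2)
        + 0.7 * a_trem * trem_env * np.sin(phase_trem + np.pi / 2)
        + noise(cfg.noise_sd),
        "thigh_acc_ap_right": a_acc * amp_env * np.sin(phase_loco + 0.4)
        + a_tacc * trem_env * np.sin(phase_trem + 0.4)
        + noise(cfg.noise_sd * 0.4),
        "thigh_acc_ap_left": a_acc * amp_env * np.sin(phase_loco + np.pi + 0.4)
        + a_tacc * trem_env * np.sin(phase_trem + np.pi + 0.4)
        + noise(cfg.noise_sd * 0.4),
    }
    return channels


def generate_session(
    config: CohortConfig,
    participant_id: str,
    is_freezer: bool,
    seed: int,
) -> Session:
    """One participant's synthetic session; bit-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    episodes = _sample_episodes(rng, config) if is_freezer else []
    channels = _synthesize_channels(rng, config, episodes)
    return Session(
        participant_id=participant_id,
        fs=config.fs,
        channels=channels,
        episodes=episodes,
    )


def generate_cohort(config: CohortConfig) -> list[Session]:
    """A full cohort; exactly ``n_freezers`` sessions carry episodes.

    Per-participant seeds are spawned from ``config.seed`` so any
    session can be regenerated independently.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    sessions = []
    for i, child in enumerate(children):
        pid = f"P{i + 1:02d}"
        is_freezer = i < config.n_freezers
        seed = int(child.generate_state(1)[0])
        sessions.append(generate_session(config, pid, is_freezer, seed))
    return sessions


# ---------------------------------------------------------------------------
# plain-text persistence

_FLOAT_FMT = "%.17g"  # lossless round-trip for IEEE doubles


def write_session(session: Session, directory: str | Path) -> Path:
    """Store one session as delimited text plus a JSON sidecar.

    Files: ``<pid>_signals.csv`` (one row per sample, columns named
    after channels), ``<pid>_episodes.csv`` and ``<pid>_meta.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = session.participant_id
    names = [c for c in CHANNEL_NAMES if c in session.channels]
    names += sorted(set(session.channels) - set(names))
    data = np.column_stack([session.channels[c] for c in names])
    np.savetxt(
        directory / f"{pid}_signals.csv",
        data,
        fmt=_FLOAT_FMT,
        delimiter=",",
        header=",".join(names),
        comments="",
    )
    with open(directory / f"{pid}_episodes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "onset_s", "end_s"])
        for ep in session.episodes:
            w.writerow([pid, _FLOAT_FMT % ep.onset_s, _FLOAT_FMT % ep.end_s])
    meta = {
        "participant_id": pid,
        "fs": session.fs,
        "n_samples": session.n_samples,
        "duration_s": session.duration_s,
        "channels": names,
    }
    with open(directory / f"{pid}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return directory


def read_session(directory: str | Path, participant_id: str) -> Session:
    """Load a stored session; inverse of :func:`write_session`."""
    directory = Path(directory)
    pid = participant_id
    try:
        with open(directory / f"{pid}_meta.json") as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as e:
        raise ParseError(f"{pid}_meta.json: line {e.lineno}: {e.msg}") from None

    sig_path = directory / f"{pid}_signals.csv"
    with open(sig_path) as fh:
        header = fh.readline().strip().split(",")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.strip().split(",")
            if len(parts) != len(header):
                raise ParseError(
                    f"{sig_path.name}: line {lineno}: expected "
                    f"{len(header)} columns, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(
                    f"{sig_path.name}: line {lineno}: non-numeric value"
                ) from None
    data = np.array(rows)
    channels = {name: np.ascontiguousarray(data[:, j]) for j, name in enumerate(header)}

    episodes = read_annotations(directory / f"{pid}_episodes.csv").get(pid, [])
    return Session(
        participant_id=pid, fs=float(meta["fs"]), channels=channels, episodes=episodes
    )


def read_annotations(path: str | Path) -> dict[str, list[FOGEpisode]]:
    """Episode annotation CSV -> episodes per participant.

    Malformed rows (wrong arity, non-numeric, onset >= end) raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    out: dict[str, list[FOGEpisode]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                continue  # header
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path.name}: line {lineno}: expected 3 columns")
            pid, onset_str, end_str = row
            try:
                onset, end = float(onset_str), float(end_str)
            except ValueError:
                raise ParseError(
                    f"{path.name}: line {lineno}: non-numeric onset/end"
                ) from None
            if not (0 <= onset < end):
                raise ParseError(
                    f"{path.name}: line {lineno}: require 0 <= onset_s < end_s, "
                    f"got ({onset}, {end})"
                )
            out.setdefault(pid, []).append(FOGEpisode(onset, end))
    for pid, eps in out.items():
        try:
            validate_episodes(eps)
        except ValueError as e:
            raise ParseError(f"{path.name}: participant {pid}: {e}") from None
    return out


def write_cohort(sessions: list[Session], directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        write_session(s, directory)
    with open(directory / "cohort.json", "w") as fh:
        json.dump(
            {"participants": [s.participant_id for s in sessions]},
            fh,
            indent=1,
            sort_keys=True,
        )
    return directory


def read_cohort(directory: str | Path) -> list[Session]:
    directory = Path(directory)
    manifest = directory / "cohort.json"
    if manifest.exists():
        with open(manifest) as fh:
            pids = json.load(fh)["participants"]
    else:
        pids = sorted(p.name[: -len("_meta.json")] for p in directory.glob("*_meta.json"))
    if not pids:
        raise ParseError(f"no sessions found in {directory}")
    return [read_session(directory, pid) for pid in pids]


def clustered_config(**overrides) -> CohortConfig:
    """A configuration whose episodes arrive in tight rapid-succession
    clusters (all intra-cluster gaps below 1 s), useful for studying the
    merging thresholds."""
    base = CohortConfig(
        episode_rate=6.0,
        episode_duration_dist=(1.0, 3.0),
        cluster_prob=0.7,
        cluster_gap_dist=(0.3, 0.8),
    )
    return replace(base, **overrides)
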