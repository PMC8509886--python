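"""Two-level model evaluation.

Window level: sensitivity and specificity of the per-window
classifications against the ternary ground truth's task targets.

Episode level: three consecutive positive window classifications emit a
model trigger decision (MTD) at the end of the third window. An MTD is
a true positive when it falls inside some episode's target zone — from
2 s before onset through the episode end — and a false positive
otherwise. An episode counts as identified when at least one MTD lands
in its zone; the identification delay is the earliest in-zone MTD minus
the onset (negative = predicted before the freeze started). Precision
is TP/(TP+FP)x100 over MTDs. A hypothetical cueing protocol adds a
2.5 s refractory ("no-cue") interval after each delivered cue during
which further MTDs are ignored; an episode beginning inside an open
interval is credited as identified since it follows a cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FOGEpisode

_TOL = 1e-9


@dataclass(frozen=True)
class MTDEvent:
    """A classified trigger instant."""

    instant_s: float
    status: str  # "TP" or "FP"
    matched_episode: int | None = None


@dataclass(frozen=True)
class EpisodeResult:
    identified: bool
    identification_delay_s: float  # NaN when not identified


def window_metrics(predictions, truths) -> tuple[float, float]:
    """(sensitivity %, specificity %) of binary window classifications.

    A metric whose denominator is empty (no positive / no negative
    truth) is returned as NaN so callers can exclude it from means.
    """
    p = np.asarray(predictions, dtype=bool)
    t = np.asarray(truths, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("predictions and truths must be equal length")
    tp = np.sum(p & t)
    fn = np.sum(~p & t)
    tn = np.sum(~p & ~t)
    fp = np.sum(p & ~t)
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else float("nan")
    return sens, spec


def generate_mtds(
    window_predictions,
    window_end_times,
    k: int = 3,
    per_run: bool = False,
) -> np.ndarray:
    """Trigger instants from a time-ordered window prediction sequence.

    Every window that is the ``k``-th or later member of a maximal run
    of consecutive positives emits an MTD at its end time, so a run of
    length L >= k yields L - k + 1 MTDs (the grouped trigger clusters
    characteristic of heavily overlapped windows). With
    ``per_run=True`` only the first trigger of each run is kept.
    """
    preds = np.asarray(window_predictions, dtype=bool)
    ends = np.asarray(window_end_times, dtype=float)
    if preds.shape != ends.shape:
        raise ValueError("predictions and end times must align")
    mtds = []
    streak = 0
    for i, p in enumerate(preds):
        streak = streak + 1 if p else 0
        if streak >= k and (not per_run or streak == k):
            mtds.append(ends[i])
    return np.asarray(mtds)


def target_zones(
    episodes: list[FOGEpisode], prefog_s: float = 2.0
) -> list[tuple[float, float]]:
    """Per-episode MTD target zones: [onset - prefog_s, end], clipped at 0."""
    return [(max(ep.onset_s - prefog_s, 0.0), ep.end_s) for ep in episodes]


def classify_mtds(
    mtds, zones: list[tuple[float, float]]
) -> list[MTDEvent]:
    """TP/FP status of each trigger (closed-interval zone membership).

    When zones overlap, a trigger is matched to the earliest zone that
    contains it.
    """
    events = []
    for m in np.asarray(mtds, dtype=float):
        matched = None
        for j, (lo, hi) in enumerate(zones):
            if lo - _TOL <= m <= hi + _TOL:
                matched = j
                break
        events.append(
            MTDEvent(float(m), "TP" if matched is not None else "FP", matched)
        )
    return events


def precision(tp: int, fp: int) -> float:
    """100 * TP / (TP + FP); NaN when no triggers were emitted."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return float("nan")
    return 100.0 * tp / (tp + fp)


def episode_identification(
    episodes: list[FOGEpisode],
    mtds,
    prefog_s: float = 2.0,
) -> tuple[list[EpisodeResult], float]:
    """Per-episode identification flags and the identified percentage.

    An episode is identified when at least one trigger lies in its
    target zone; its delay is the earliest in-zone trigger minus the
    onset. With no episodes the percentage is NaN.
    """
    mtds = np.asarray(mtds, dtype=float)
    results = []
    for ep, (lo, hi) in zip(episodes, target_zones(episodes, prefog_s)):
        in_zone = mtds[(mtds >= lo - _TOL) & (mtds <= hi + _TOL)]
        if in_zone.size:
            results.append(EpisodeResult(True, float(in_zone.min() - ep.onset_s)))
        else:
            results.append(EpisodeResult(False, float("nan")))
    if not episodes:
        return results, float("nan")
    pct = 100.0 * sum(r.identified for r in results) / len(results)
    return results, pct


@dataclass
class NoCueResult:
    """Outcome of the refractory cueing protocol."""

    surviving_mtds: np.ndarray
    events: list[MTDEvent]
    episode_results: list[EpisodeResult]
    episodes_identified_pct: float
    tp: int
    fp: int

    @property
    def precision(self) -> float:
        return precision(self.tp, self.fp)


def apply_no_cue(
    mtds,
    episodes: list[FOGEpisode],
    interval_s: float = 2.5,
    prefog_s: float = 2.0,
) -> NoCueResult:
    """Greedy left-to-right refractory filter over trigger instants.

    The first trigger survives (a cue is delivered) and opens a no-cue
    interval ``(t, t + interval_s]``; triggers inside an open interval
    are discarded; the next trigger after it survives and opens a new
    one. TP/FP and precision are recomputed on survivors only. An
    episode whose onset falls inside an open interval is credited as
    identified even without a surviving in-zone trigger (it follows a
    delivered cue); such credited episodes contribute no identification
    delay.
    """
    mtds = np.sort(np.asarray(mtds, dtype=float))
    survivors = []
    open_until = -np.inf
    for m in mtds:
        if m > open_until + _TOL:
            survivors.append(m)
            open_until = m + interval_s
    survivors = np.asarray(survivors)

    events = classify_mtds(survivors, target_zones(episodes, prefog_s))
    results, _ = episode_identification(episodes, survivors, prefog_s)

    credited = []
    for ep, res in zip(episodes, results):
        if res.identified:
            credited.append(res)
            continue
        in_interval = any(
            s + _TOL < ep.onset_s <= s + interval_s + _TOL for s in survivors
        )
        credited.append(EpisodeResult(in_interval, float("nan")))
    pct = (
        100.0 * sum(r.identified for r in credited) / len(credited)
        if credited
        else float("nan")
    )
    tp = sum(e.status == "TP" for e in events)
    fp = sum(e.status == "FP" for e in events)
    return NoCueResult(survivors, events, credited, pct, tp, fp)


def aggregate_report(
    per_participant: pd.DataFrame,
    count_cols: tuple[str, ...] = (),
) -> dict[str, pd.Series]:
    """Cohort summary of a per-participant metric table.

    Means and SDs are unweighted across participants (one row each,
    regardless of episode count) with undefined (NaN) entries excluded;
    the SD is the population SD. Count columns are summed into totals.
    """
    if len(per_participant) == 0:
        raise ValueError("need at least one participant row")
    num = per_participant.select_dtypes(include=[np.number])
    metric_cols = [c for c in num.columns if c not in count_cols]
    out = {
        "mean": num[metric_cols].mean(),
        "sd": num[metric_cols].std(ddof=0),
    }
    if count_cols:
        out["total"] = num[list(count_cols)].sum()
    return out
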