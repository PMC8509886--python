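import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fogmerge.core import FOGEpisode, Session
from fogmerge.synthio import CohortConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def random_episode_list(rng: np.random.Generator, max_eps: int = 8) -> list[FOGEpisode]:
    """Random sorted, disjoint episode list with gaps spanning 0–4 s."""
    n = int(rng.integers(0, max_eps + 1))
    t = float(rng.uniform(0, 3))
    eps = []
    for _ in range(n):
        dur = float(rng.uniform(0.2, 4.0))
        eps.append(FOGEpisode(round(t, 3), round(t + dur, 3)))
        t += dur + float(rng.uniform(0.05, 4.0))
    return eps


@pytest.fixture(scope="session")
def fig_layout_session() -> Session:
    """A session laid out like the canonical windowing diagram.

    One episode with onset 3.5 s and end 5.2 s in a 6 s session. With
    1 s windows shifted by 0.2 s, the first 19 windows split into:
    W1–W3 pure NonFOG, W4–W8 NonFOG+PreFOG, W9–W13 pure PreFOG,
    W14–W18 PreFOG+FOG, W19 pure FOG.
    """
    fs = 100.0
    n = int(6.0 * fs)
    t = np.arange(n) / fs
    channels = {
        name: np.sin(2 * np.pi * t + i)
        for i, name in enumerate(
            ["cop_ap_left", "cop_ap_right", "cop_ml_right",
             "thigh_acc_ap_left", "thigh_acc_ap_right"]
        )
    }
    return Session("FIG", fs, channels, [FOGEpisode(3.5, 5.2)])


@pytest.fixture(scope="session")
def tiny_cohort() -> list[Session]:
    """Small, quick cohort: 4 participants, 3 freezers, 90 s sessions."""
    cfg = CohortConfig(
        n_participants=4, n_freezers=3, session_duration_s=90.0,
        episode_rate=4.0, seed=42,
    )
    return generate_cohort(cfg)
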