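"""Shared fixtures: small hand-built traces and session-scoped synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from migdetect import DailyPresence, GeneratorConfig, build_daily_presence, generate_cohort
from migdetect.evaluation import detect_cohort


def make_presence(user_id: str, by_location: dict[str, list[int]]) -> DailyPresence:
    """Build a DailyPresence from {location: [appearance days]}."""
    presence: dict[int, set[str]] = {}
    for loc, days in by_location.items():
        for d in days:
            presence.setdefault(d, set()).add(loc)
    return DailyPresence(user_id=user_id, presence={d: frozenset(s) for d, s in presence.items()})


@pytest.fixture
def overlap_presence() -> DailyPresence:
    """The worked overlapping-segments trace: A dense to day 39 with stragglers
    on 41 and 45; B sparse from 43 and dense from 51."""
    return make_presence(
        "u1",
        {
            "A": list(range(1, 40)) + [41, 45],
            "B": [43, 47, 49, 50] + list(range(51, 91)),
        },
    )


def random_presence(rng: np.random.Generator, n_days: int = 60, n_locs: int = 4) -> DailyPresence:
    """A random sparse multi-location trace for oracle comparisons."""
    n_locs = int(rng.integers(1, n_locs + 1))
    locs = [f"L{i}" for i in range(n_locs)]
    by_loc: dict[str, list[int]] = {}
    for loc in locs:
        p = rng.uniform(0.1, 0.9)
        days = [d for d in range(1, n_days + 1) if rng.random() < p]
        if days:
            by_loc[loc] = days
    if not by_loc:
        by_loc = {locs[0]: [int(rng.integers(1, n_days + 1))]}
    return make_presence("u", by_loc)


MIXED_MIX = {"migrant": 0.5, "stayer": 0.25, "commuter": 0.15, "tripper": 0.10}


@pytest.fixture(scope="session")
def mixed_cohort():
    """The reference study cohort: 500 users over a 400-day panel at 70%%
    daily observation and 10%% noise, half of them migrants."""
    cfg = GeneratorConfig(n_users=500, n_days=400, p_obs=0.7, p_noise=0.1, seed=2024)
    records, truth = generate_cohort(cfg, MIXED_MIX)
    presences = build_daily_presence(records)
    return {"config": cfg, "records": records, "truth": truth, "presences": presences}


@pytest.fixture(scope="session")
def mixed_cohort_events(mixed_cohort):
    return detect_cohort(mixed_cohort["presences"])


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort for tuning/monotonicity tests."""
    cfg = GeneratorConfig(n_users=80, n_days=400, p_obs=0.7, p_noise=0.1, seed=11)
    records, truth = generate_cohort(cfg, MIXED_MIX)
    presences = build_daily_presence(records)
    return {"config": cfg, "records": records, "truth": truth, "presences": presences}
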