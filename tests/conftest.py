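"""Shared fixtures: small random analysis sets with ties, and hand-built units."""

from __future__ import annotations

import numpy as np
import pytest

from aerisk import AnalysisSet, Outcome


def make_set(times, outcomes, trial="T1", arm="E", ae_type="AE1") -> AnalysisSet:
    times = np.asarray(times, dtype=float)
    return AnalysisSet(
        trial_id=trial,
        arm=arm,
        ae_type=ae_type,
        subject_ids=np.array([f"s{i}" for i in range(len(times))], dtype=object),
        times=times,
        outcomes=np.asarray(outcomes, dtype=np.int64),
    )


def random_set(rng: np.random.Generator, n_max: int = 12, n_min: int = 1) -> AnalysisSet:
    """Random small analysis set; half the draws use an integer time grid to
    force tied event/censoring times, the tricky case for risk-set logic."""
    n = int(rng.integers(n_min, n_max + 1))
    if rng.random() < 0.5:
        times = rng.integers(1, 7, size=n).astype(float)
    else:
        times = rng.uniform(0.5, 10.0, size=n)
    outcomes = rng.choice(
        [int(Outcome.CENSORED), int(Outcome.AE), int(Outcome.DEATH_BEFORE_AE), int(Outcome.OTHER_CE)],
        size=n,
        p=[0.3, 0.3, 0.2, 0.2],
    )
    return make_set(times, outcomes)


def counts_set(n_ae: int, n_death: int, n_other: int, n_cens: int) -> AnalysisSet:
    """A unit with prescribed event counts: events spread over early times,
    censorings at the end of follow-up."""
    times, outcomes = [], []
    t = 1.0
    for count, code in [
        (n_ae, Outcome.AE),
        (n_death, Outcome.DEATH_BEFORE_AE),
        (n_other, Outcome.OTHER_CE),
    ]:
        for _ in range(count):
            times.append(t)
            outcomes.append(int(code))
            t += 1.0
    for _ in range(n_cens):
        times.append(t)
        outcomes.append(int(Outcome.CENSORED))
        t += 1.0
    return make_set(times, outcomes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def hand_unit() -> AnalysisSet:
    """CE at day 1, AE at day 2, censoring at day 3."""
    return make_set([1.0, 2.0, 3.0], [int(Outcome.OTHER_CE), int(Outcome.AE), int(Outcome.CENSORED)])
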