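"""Per-patient data model for time-to-first-adverse-event analyses.

Every patient contributes exactly one record per adverse-event (AE) type:
a follow-up time and the state observed at that time. Four states are
possible -- the AE of interest, death before the AE, another competing
event (CE; e.g. disease- or safety-related end of AE recording such as
treatment discontinuation), or censoring (end of observation without any
event, so only a minimum event-free time is known).

Two competing-event schemes are supported. Under the all-CE scheme every
non-AE event is competing; under the death-only scheme only death before
AE competes and other CEs are recoded as censoring. The scheme choice
changes what the downstream cumulative-incidence estimators converge to,
which is exactly the sensitivity the pipeline quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "Outcome",
    "CeScheme",
    "SubjectRecord",
    "AnalysisSet",
    "EventCounts",
    "apply_ce_scheme",
    "count_events",
]


class Outcome(IntEnum):
    """Observed state at end of a patient's follow-up for one AE type.

    Integer values are the on-disk codes used by the CSV reader/writer.
    """

    CENSORED = 0
    AE = 1
    DEATH_BEFORE_AE = 2
    OTHER_CE = 3


class CeScheme(str, Enum):
    """Which observed events are treated as competing.

    ALL_CE: death before AE and any other CE compete with the AE.
    DEATH_ONLY: only death competes; other CEs are recoded to censoring.
    """

    ALL_CE = "all"
    DEATH_ONLY = "death-only"


@dataclass(frozen=True)
class SubjectRecord:
    """One patient's follow-up time and first-event outcome for one AE type."""

    subject_id: str
    time: float
    outcome: Outcome

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: time must be strictly positive "
                f"and finite, got {self.time!r}"
            )
        object.__setattr__(self, "outcome", Outcome(self.outcome))


@dataclass(frozen=True)
class AnalysisSet:
    """All records for one (trial, arm, AE type) unit.

    Times and outcomes are stored as parallel numpy arrays so estimators and
    the bootstrap can resample without per-record Python overhead.
    """

    trial_id: str
    arm: str
    ae_type: str
    subject_ids: np.ndarray  # dtype=object, unique
    times: np.ndarray  # float, strictly positive and finite
    outcomes: np.ndarray  # int, values in Outcome

    def __post_init__(self) -> None:
        ids = np.asarray(self.subject_ids, dtype=object)
        times = np.asarray(self.times, dtype=float)
        outcomes = np.asarray(self.outcomes, dtype=np.int64)
        if not (len(ids) == len(times) == len(outcomes)):
            raise ValueError("subject_ids, times and outcomes must be equal length")
        if len(times) < 1:
            raise ValueError("an analysis set needs at least one record")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("all times must be strictly positive and finite")
        valid = {int(o) for o in Outcome}
        if not set(np.unique(outcomes)).issubset(valid):
            raise ValueError(f"outcome codes must be in {sorted(valid)}")
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique within an analysis set")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "outcomes", outcomes)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def max_time(self) -> float:
        return float(self.times.max())

    def records(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(str(s), float(t), Outcome(int(o)))
            for s, t, o in zip(self.subject_ids, self.times, self.outcomes)
        ]

    @classmethod
    def from_records(
        cls, trial_id: str, arm: str, ae_type: str, records: list[SubjectRecord]
    ) -> "AnalysisSet":
        return cls(
            trial_id=trial_id,
            arm=arm,
            ae_type=ae_type,
            subject_ids=np.array([r.subject_id for r in records], dtype=object),
            times=np.array([r.time for r in records], dtype=float),
            outcomes=np.array([int(r.outcome) for r in records], dtype=np.int64),
        )

    def replace_arrays(self, times=None, outcomes=None, subject_ids=None) -> "AnalysisSet":
        return AnalysisSet(
            trial_id=self.trial_id,
            arm=self.arm,
            ae_type=self.ae_type,
            subject_ids=self.subject_ids if subject_ids is None else subject_ids,
            times=self.times if times is None else times,
            outcomes=self.outcomes if outcomes is None else outcomes,
        )

    def resample(self, rng: np.random.Generator) -> "AnalysisSet":
        """Bootstrap resample of patients (with replacement, same n).

        Resampled subject ids are suffixed with the draw index so the
        uniqueness invariant still holds.
        """
        idx = rng.integers(0, self.n, size=self.n)
        ids = np.array(
            [f"{self.subject_ids[i]}#{k}" for k, i in enumerate(idx)], dtype=object
        )
        return self.replace_arrays(
            subject_ids=ids, times=self.times[idx], outcomes=self.outcomes[idx]
        )


@dataclass(frozen=True)
class EventCounts:
    """Classification of every record in a set on the window [0, tau]."""

    n_ae: int
    n_death: int
    n_other_ce: int
    n_censored: int

    @property
    def n(self) -> int:
        return self.n_ae + self.n_death + self.n_other_ce + self.n_censored

    @property
    def n_ce(self) -> int:
        return self.n_death + self.n_other_ce

    def proportions(self) -> dict[str, float]:
        n = self.n
        return {
            "ae": self.n_ae / n,
            "death": self.n_death / n,
            "other_ce": self.n_other_ce / n,
            "censored": self.n_censored / n,
        }


def apply_ce_scheme(aset: AnalysisSet, scheme: CeScheme) -> AnalysisSet:
    """Return a copy of *aset* with outcomes recoded under *scheme*.

    DEATH_ONLY turns every OTHER_CE into CENSORED at the same time; ALL_CE
    is the identity. Both are idempotent.
    """
    scheme = CeScheme(scheme)
    if scheme is CeScheme.ALL_CE:
        return aset.replace_arrays(outcomes=aset.outcomes.copy())
    out = aset.outcomes.copy()
    out[out == int(Outcome.OTHER_CE)] = int(Outcome.CENSORED)
    return aset.replace_arrays(outcomes=out)


def count_events(aset: AnalysisSet, tau: float) -> EventCounts:
    """Classify each record by its observed state on the closed window [0, tau].

    A record whose time exceeds tau is administratively truncated and counts
    as censored at tau regardless of its eventual outcome; a record with time
    exactly tau keeps its observed event.
    """
    if not (np.isfinite(tau) and tau > 0):
        raise ValueError(f"evaluation time tau must be > 0, got {tau!r}")
    within = aset.times <= tau
    out = aset.outcomes
    n_ae = int(np.sum(within & (out == int(Outcome.AE))))
    n_death = int(np.sum(within & (out == int(Outcome.DEATH_BEFORE_AE))))
    n_other = int(np.sum(within & (out == int(Outcome.OTHER_CE))))
    n_cens = aset.n - n_ae - n_death - n_other
    return EventCounts(n_ae=n_ae, n_death=n_death, n_other_ce=n_other, n_censored=n_cens)
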