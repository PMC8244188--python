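r"""One-sample estimators of the cumulative adverse-event probability.

Six estimators of :math:`P(\text{AE by } \tau)` in a time-to-first-event
analysis with competing events (CEs) and right censoring:

``ip``
    Incidence proportion: observed AEs on :math:`[0,\tau]` divided by the
    group size :math:`n`. Ignores censoring; implicitly accounts for CEs.
``ptid-ignore-ce``
    Probability transform of the AE incidence density,
    :math:`1-\exp(-ID(\tau)\,\tau)` with
    :math:`ID(\tau)=\#\text{AE}/\sum_i \min(t_i,\tau)`. A constant-hazard
    model that ignores CEs.
``1-km``
    One minus Kaplan-Meier, with the AE as the sole event type and
    everything else censored. Accounts for censoring but not for CEs, so
    it is bound to overestimate the AE risk in their presence.
``ptid-acc-ce``
    Probability transform using both the AE and the competing incidence
    density: with :math:`a=ID(\tau)` and :math:`b=\overline{ID}(\tau)`,
    :math:`\frac{a}{a+b}\bigl(1-e^{-\tau(a+b)}\bigr)`. The constant-hazard
    analogue of the Aalen-Johansen estimator.
``aje-death-only``
    Aalen-Johansen treating only death before AE as competing (other CEs
    recoded as censoring).
``aje``
    The Aalen-Johansen estimator of the AE cumulative incidence function
    with the full CE definition -- the nonparametric gold standard, valid
    under censoring, non-constant hazards, and CEs.

All estimators are evaluated on the closed window :math:`[0,\tau]`: an
event recorded exactly at :math:`\tau` counts as observed. At tied times,
events are processed before censorings, and tied AEs and CEs share the
same risk set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np

from .event_model import (
    AnalysisSet,
    CeScheme,
    EventCounts,
    Outcome,
    apply_ce_scheme,
    count_events,
)

__all__ = [
    "StepCurve",
    "EstimateResult",
    "TauRule",
    "ESTIMATOR_NAMES",
    "incidence_proportion",
    "incidence_density",
    "ce_incidence_density",
    "prob_transform_id_ignoring_ce",
    "prob_transform_id_accounting_ce",
    "one_minus_kaplan_meier",
    "aalen_johansen",
    "aje_ce_incidence",
    "evaluation_time",
    "compute_estimate",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function (survival or cumulative incidence)."""

    times: np.ndarray  # sorted, strictly increasing jump times
    values: np.ndarray  # value right of each jump
    initial: float  # value before the first jump

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have the same shape")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t: float) -> float:
        """Value at time *t*: the value after the largest jump <= t."""
        i = int(np.searchsorted(self.times, t, side="right"))
        return self.initial if i == 0 else float(self.values[i - 1])

    def left_limit(self, t: float) -> float:
        """Value just before *t* (left limit)."""
        i = int(np.searchsorted(self.times, t, side="left"))
        return self.initial if i == 0 else float(self.values[i - 1])


@dataclass(frozen=True)
class EstimateResult:
    """Point estimate of the cumulative AE probability at tau, with context."""

    estimator_name: str
    tau: float
    estimate: float
    counts: EventCounts
    patient_time: float  # sum_i min(t_i, tau), days
    ae_incidence_density: float  # AEs per patient-day at risk
    ce_incidence_density: float  # CEs per patient-day at risk
    curve: StepCurve | None = None


class TauRule(str, Enum):
    """How the evaluation time tau is derived from the observed times."""

    MAX_FOLLOW_UP = "max"
    Q100 = "q100"
    Q90 = "q90"
    Q60 = "q60"
    Q30 = "q30"

    @property
    def quantile(self) -> float | None:
        return {"max": None, "q100": 1.0, "q90": 0.9, "q60": 0.6, "q30": 0.3}[self.value]


def _nearest_rank_quantile(times: np.ndarray, q: float) -> float:
    """Ceiling nearest-rank empirical quantile: the ceil(q*n)-th order statistic."""
    s = np.sort(np.asarray(times, dtype=float))
    k = max(1, math.ceil(q * len(s)))
    return float(s[k - 1])


def evaluation_time(
    sets_by_arm: Mapping[str, AnalysisSet] | Sequence[AnalysisSet] | AnalysisSet,
    rule: TauRule | str,
) -> float:
    """Evaluation time tau under *rule* for one or several arms.

    ``max`` returns the maximum observed time pooled over arms. A quantile
    rule returns the minimum over arms of the nearest-rank empirical
    quantile of each arm's observed times, so with two arms the comparison
    time never extends beyond the shorter follow-up.
    """
    rule = TauRule(rule)
    if isinstance(sets_by_arm, AnalysisSet):
        arms: list[AnalysisSet] = [sets_by_arm]
    elif isinstance(sets_by_arm, Mapping):
        arms = list(sets_by_arm.values())
    else:
        arms = list(sets_by_arm)
    if not arms:
        raise ValueError("need at least one non-empty arm")
    q = rule.quantile
    if q is None:
        return max(a.max_time for a in arms)
    return min(_nearest_rank_quantile(a.times, q) for a in arms)


def _patient_time(aset: AnalysisSet, tau: float) -> float:
    return float(np.minimum(aset.times, tau).sum())


def _densities(aset: AnalysisSet, tau: float) -> tuple[float, float, float]:
    """(AE density, CE density, patient-time) on [0, tau]."""
    pt = _patient_time(aset, tau)
    if pt <= 0:
        raise ValueError("total patient-time at risk is zero")
    c = count_events(aset, tau)
    return c.n_ae / pt, c.n_ce / pt, pt


def _check_tau(tau: float) -> None:
    if not (np.isfinite(tau) and tau > 0):
        raise ValueError(f"evaluation time tau must be > 0, got {tau!r}")


def _result(
    name: str,
    aset: AnalysisSet,
    tau: float,
    estimate: float,
    curve: StepCurve | None = None,
) -> EstimateResult:
    pt = _patient_time(aset, tau)
    counts = count_events(aset, tau)
    ae_id = counts.n_ae / pt if pt > 0 else float("nan")
    ce_id = counts.n_ce / pt if pt > 0 else float("nan")
    return EstimateResult(
        estimator_name=name,
        tau=float(tau),
        estimate=float(estimate),
        counts=counts,
        patient_time=pt,
        ae_incidence_density=ae_id,
        ce_incidence_density=ce_id,
        curve=curve,
    )


def incidence_proportion(aset: AnalysisSet, tau: float) -> EstimateResult:
    """Observed AEs on [0, tau] divided by the number of patients."""
    _check_tau(tau)
    c = count_events(aset, tau)
    return _result("ip", aset, tau, c.n_ae / aset.n)


def incidence_density(aset: AnalysisSet, tau: float) -> float:
    """AE incidence density: AEs on [0, tau] per patient-day at risk."""
    _check_tau(tau)
    a, _, _ = _densities(aset, tau)
    return a


def ce_incidence_density(aset: AnalysisSet, tau: float) -> float:
    """Competing-event incidence density on [0, tau]."""
    _check_tau(tau)
    _, b, _ = _densities(aset, tau)
    return b


def prob_transform_id_ignoring_ce(aset: AnalysisSet, tau: float) -> EstimateResult:
    """1 - exp(-ID * tau): incidence density transformed to a probability,
    ignoring competing events."""
    _check_tau(tau)
    a, _, _ = _densities(aset, tau)
    return _result("ptid-ignore-ce", aset, tau, 1.0 - math.exp(-a * tau))


def prob_transform_id_accounting_ce(aset: AnalysisSet, tau: float) -> EstimateResult:
    """Two-density probability transform: a/(a+b) * (1 - exp(-tau(a+b))).

    With no competing events (b = 0) this reduces exactly to the transform
    ignoring CEs; with no events at all the estimate is 0 by convention.
    """
    _check_tau(tau)
    a, b, _ = _densities(aset, tau)
    s = a + b
    if s == 0:
        return _result("ptid-acc-ce", aset, tau, 0.0)
    return _result("ptid-acc-ce", aset, tau, (a / s) * (1.0 - math.exp(-tau * s)))


def _risk_table(times: np.ndarray, is_event: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct event times t_j with event counts d_j and at-risk counts Y_j.

    Y_j counts every record with time >= t_j; records censored exactly at
    t_j remain in the risk set (events before censorings at ties).
    """
    ev_times, d = np.unique(times[is_event], return_counts=True)
    order = np.sort(times)
    # at risk: n minus the number with time strictly below t_j
    y = len(times) - np.searchsorted(order, ev_times, side="left")
    return ev_times, d.astype(float), y.astype(float)


def _km_survival(times: np.ndarray, is_event: np.ndarray) -> StepCurve:
    t, d, y = _risk_table(times, is_event)
    surv = np.cumprod(1.0 - d / y)
    return StepCurve(times=t, values=surv, initial=1.0)


def one_minus_kaplan_meier(aset: AnalysisSet, tau: float) -> EstimateResult:
    """Product-limit estimator with the AE as the only event type.

    Competing events and censorings are both treated as censored
    observations, which redistributes their mass onto later AE times.
    """
    _check_tau(tau)
    is_ae = (aset.outcomes == int(Outcome.AE)) & (aset.times <= tau)
    surv = _km_survival(aset.times, is_ae)
    cif = StepCurve(times=surv.times, values=1.0 - surv.values, initial=0.0)
    return _result("1-km", aset, tau, cif(tau), curve=cif)


def _aj_cif(
    aset: AnalysisSet, tau: float, cause_is_ae: bool
) -> StepCurve:
    """Aalen-Johansen cumulative incidence curve for one cause.

    Increment at each event time: S(t-) * d_cause / Y, where S is the
    Kaplan-Meier survival of the time to any first event (AE or CE).
    """
    is_ce = np.isin(aset.outcomes, (int(Outcome.DEATH_BEFORE_AE), int(Outcome.OTHER_CE)))
    is_ae = aset.outcomes == int(Outcome.AE)
    any_event = (is_ae | is_ce) & (aset.times <= tau)
    surv = _km_survival(aset.times, any_event)
    cause = (is_ae if cause_is_ae else is_ce) & (aset.times <= tau)
    t_all, _, y_all = _risk_table(aset.times, any_event)
    d_cause = np.zeros(len(t_all))
    ct, cc = np.unique(aset.times[cause], return_counts=True)
    d_cause[np.searchsorted(t_all, ct)] = cc
    s_left = np.concatenate(([1.0], surv.values[:-1]))
    cif_vals = np.cumsum(s_left * d_cause / y_all)
    return StepCurve(times=t_all, values=cif_vals, initial=0.0)


def aalen_johansen(
    aset: AnalysisSet, tau: float, scheme: CeScheme | str = CeScheme.ALL_CE
) -> EstimateResult:
    """Aalen-Johansen estimate of the cumulative AE probability at tau.

    The competing-event scheme is applied first: under DEATH_ONLY other
    CEs become censorings, so the estimator converges to a larger quantity
    whenever other CEs exist. The ALL_CE variant is the gold standard.
    """
    _check_tau(tau)
    scheme = CeScheme(scheme)
    recoded = apply_ce_scheme(aset, scheme)
    curve = _aj_cif(recoded, tau, cause_is_ae=True)
    name = "aje" if scheme is CeScheme.ALL_CE else "aje-death-only"
    return _result(name, recoded, tau, curve(tau), curve=curve)


def aje_ce_incidence(
    aset: AnalysisSet, tau: float, scheme: CeScheme | str = CeScheme.ALL_CE
) -> float:
    """Aalen-Johansen cumulative incidence of the competing event at tau."""
    _check_tau(tau)
    recoded = apply_ce_scheme(aset, CeScheme(scheme))
    return _aj_cif(recoded, tau, cause_is_ae=False)(tau)


_PLAIN: dict[str, Callable[[AnalysisSet, float], EstimateResult]] = {
    "ip": incidence_proportion,
    "ptid-ignore-ce": prob_transform_id_ignoring_ce,
    "ptid-acc-ce": prob_transform_id_accounting_ce,
    "1-km": one_minus_kaplan_meier,
}

ESTIMATOR_NAMES: tuple[str, ...] = (
    "ip",
    "ptid-ignore-ce",
    "1-km",
    "ptid-acc-ce",
    "aje-death-only",
    "aje",
)


def compute_estimate(aset: AnalysisSet, tau: float, name: str) -> EstimateResult:
    """Dispatch an estimator by registry name (see ESTIMATOR_NAMES)."""
    if name in _PLAIN:
        return _PLAIN[name](aset, tau)
    if name == "aje":
        return aalen_johansen(aset, tau, CeScheme.ALL_CE)
    if name == "aje-death-only":
        return aalen_johansen(aset, tau, CeScheme.DEATH_ONLY)
    raise KeyError(f"unknown estimator {name!r}; choose from {ESTIMATOR_NAMES}")
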