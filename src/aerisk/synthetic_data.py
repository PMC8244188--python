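"""Synthetic competing-risks trial data with known truth.

Generates per-patient time-to-first-event records for one analysis unit
or a whole portfolio of trials, emulating the safety analysis set of a
randomized clinical trial: cause-specific hazards for the adverse event
(AE) and the competing event (CE), a death/other split of the CE hazard,
administrative censoring at trial closure, and optional independent
random censoring. Hazards are constant (exponential) or Weibull.

Simulation draws independent latent cause times; the observed (minimum,
cause) pair then has exactly the specified cause-specific hazards. For
constant hazards the true AE cumulative incidence has the closed form
``alpha/(alpha+beta) * (1 - exp(-(alpha+beta) * tau))``, which serves as
the analytic oracle in tests.

Portfolio defaults are calibrated to an oncology-heavy collection of
completed trials: a few hundred to a few thousand patients per trial,
follow-up on the order of 2-3 years, roughly half of the patients ending
follow-up with a competing event (mostly non-death CEs such as treatment
discontinuation), about a third censored, and between-trial heterogeneity
on the log-hazard scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .event_model import AnalysisSet, Outcome

__all__ = [
    "HazardSpec",
    "TrialSpec",
    "simulate_unit",
    "true_cumulative_incidence",
    "simulate_portfolio",
]


@dataclass(frozen=True)
class HazardSpec:
    """Cause-specific hazards of the AE and the CE.

    family="constant": ae_rate and ce_rate are hazards per day.
    family="weibull": per-cause shape/scale parameterisation with hazard
    h(t) = (shape/scale) * (t/scale)**(shape-1); shape 1 recovers the
    constant family with rate 1/scale.
    """

    family: str = "constant"
    ae_rate: float = 2.5e-4
    ce_rate: float = 9.0e-4
    ae_shape: float = 1.0
    ae_scale: float = 4000.0
    ce_shape: float = 1.0
    ce_scale: float = 1100.0
    death_fraction: float = 0.25  # share of CEs that are deaths

    def __post_init__(self) -> None:
        if self.family not in ("constant", "weibull"):
            raise ValueError(f"unknown hazard family {self.family!r}")
        if self.family == "constant":
            if self.ae_rate < 0 or self.ce_rate < 0 or self.ae_rate + self.ce_rate <= 0:
                raise ValueError("constant hazards must be >= 0 and not both zero")
        else:
            for v in (self.ae_shape, self.ae_scale, self.ce_shape, self.ce_scale):
                if v <= 0:
                    raise ValueError("Weibull shapes and scales must be > 0")
        if not (0.0 <= self.death_fraction <= 1.0):
            raise ValueError("death_fraction must lie in [0, 1]")

    def scaled(self, ae_factor: float, ce_factor: float) -> "HazardSpec":
        """Multiply the AE and CE hazards by positive factors.

        For the Weibull family a hazard factor f corresponds to dividing
        the scale by f**(1/shape).
        """
        if self.family == "constant":
            return replace(self, ae_rate=self.ae_rate * ae_factor,
                           ce_rate=self.ce_rate * ce_factor)
        return replace(
            self,
            ae_scale=self.ae_scale / ae_factor ** (1.0 / self.ae_shape),
            ce_scale=self.ce_scale / ce_factor ** (1.0 / self.ce_shape),
        )


@dataclass(frozen=True)
class TrialSpec:
    """One simulated trial (or a template for a portfolio of trials)."""

    n: int = 500                      # patients per arm
    hazard: HazardSpec = field(default_factory=HazardSpec)
    admin_censoring_time: float = 1000.0  # days to trial closure
    random_censoring_rate: float = 5.0e-5  # exponential drop-out hazard, 0 = none
    n_ae_types: int = 8
    heterogeneity_sd: float = 0.3     # SD of between-trial log-hazard shifts
    ae_type_sd: float = 0.5           # SD of between-AE-type log-hazard shifts
    n_range: tuple[int, int] | None = (200, 7000)  # per-trial size draw (log-uniform)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.admin_censoring_time <= 0:
            raise ValueError("administrative censoring time must be > 0")
        if self.random_censoring_rate < 0:
            raise ValueError("random censoring rate must be >= 0")
        if self.heterogeneity_sd < 0 or self.ae_type_sd < 0:
            raise ValueError("heterogeneity SDs must be >= 0")
        if self.n_ae_types < 1:
            raise ValueError("n_ae_types must be >= 1")


def _latent_times(hazard: HazardSpec, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independent latent AE and CE times with the spec's cause-specific hazards."""
    if hazard.family == "constant":
        t_ae = (rng.exponential(1.0 / hazard.ae_rate, n)
                if hazard.ae_rate > 0 else np.full(n, np.inf))
        t_ce = (rng.exponential(1.0 / hazard.ce_rate, n)
                if hazard.ce_rate > 0 else np.full(n, np.inf))
    else:
        t_ae = hazard.ae_scale * rng.weibull(hazard.ae_shape, n)
        t_ce = hazard.ce_scale * rng.weibull(hazard.ce_shape, n)
    return t_ae, t_ce


def simulate_unit(
    spec: TrialSpec,
    seed: int | np.random.Generator,
    trial_id: str = "T1",
    arm: str = "E",
    ae_type: str = "AE1",
) -> AnalysisSet:
    """Simulate one (trial, arm, AE-type) analysis unit of spec.n patients.

    Each patient's record is the earliest of the latent AE time, the
    latent CE time (split into death / other CE), the administrative
    censoring time and, if configured, an independent random censoring
    time. A tie between event and censoring counts as the event (closed
    observation window).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n
    t_ae, t_ce = _latent_times(spec.hazard, n, rng)
    t_event = np.minimum(t_ae, t_ce)
    is_ae = t_ae <= t_ce
    is_death = rng.random(n) < spec.hazard.death_fraction
    cens = np.full(n, spec.admin_censoring_time)
    if spec.random_censoring_rate > 0:
        cens = np.minimum(cens, rng.exponential(1.0 / spec.random_censoring_rate, n))
    time = np.minimum(t_event, cens)
    outcome = np.where(
        t_event <= cens,
        np.where(is_ae, int(Outcome.AE),
                 np.where(is_death, int(Outcome.DEATH_BEFORE_AE), int(Outcome.OTHER_CE))),
        int(Outcome.CENSORED),
    )
    # guard the strictly-positive-time invariant (prob-0 event for continuous draws)
    time = np.maximum(time, np.finfo(float).tiny)
    ids = np.array([f"{trial_id}-{arm}-{i:05d}" for i in range(n)], dtype=object)
    return AnalysisSet(
        trial_id=trial_id, arm=arm, ae_type=ae_type,
        subject_ids=ids, times=time, outcomes=outcome.astype(np.int64),
    )


def true_cumulative_incidence(alpha: float, beta: float, tau: float) -> float:
    """Closed-form AE cumulative incidence under constant hazards.

    alpha and beta are the AE and CE cause-specific hazards; returns
    alpha/(alpha+beta) * (1 - exp(-(alpha+beta) * tau)).
    """
    if alpha < 0 or beta < 0 or alpha + beta <= 0:
        raise ValueError("need alpha, beta >= 0 and not both zero")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    s = alpha + beta
    return (alpha / s) * (1.0 - math.exp(-s * tau))


def simulate_portfolio(
    spec: TrialSpec,
    n_trials: int,
    seed: int,
) -> tuple[list[AnalysisSet], pd.DataFrame]:
    """Simulate a portfolio of trials, each with several AE types.

    Per trial, both log-hazards receive a shared Normal(0, heterogeneity_sd)
    shift and the trial size is drawn log-uniformly from n_range (if set);
    per AE type, the AE log-hazard receives an additional
    Normal(0, ae_type_sd) shift, so AE frequencies vary across types the
    way they do across MedDRA terms. Randomness flows through a seed
    hierarchy (portfolio -> trial -> unit) so any unit is reproducible
    from the portfolio seed.

    Returns the analysis units and a truth table with the realised
    per-unit hazard factors and, for the constant family, the true AE
    cumulative incidence at trial closure.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    root = np.random.SeedSequence(seed)
    trial_seeds = root.spawn(n_trials)
    units: list[AnalysisSet] = []
    truth_rows = []
    for t, tseed in enumerate(trial_seeds):
        trial_id = f"T{t + 1:03d}"
        trng = np.random.default_rng(tseed)
        shift = trng.normal(0.0, spec.heterogeneity_sd) if spec.heterogeneity_sd > 0 else 0.0
        if spec.n_range is not None:
            lo, hi = spec.n_range
            n_trial = int(round(math.exp(trng.uniform(math.log(lo), math.log(hi)))))
        else:
            n_trial = spec.n
        for a in range(spec.n_ae_types):
            type_shift = trng.normal(0.0, spec.ae_type_sd) if spec.ae_type_sd > 0 else 0.0
            ae_factor = math.exp(shift + type_shift)
            ce_factor = math.exp(shift)
            hz = spec.hazard.scaled(ae_factor, ce_factor)
            unit_spec = replace(spec, n=n_trial, hazard=hz)
            unit = simulate_unit(
                unit_spec, np.random.default_rng(tseed.spawn(1)[0]),
                trial_id=trial_id, ae_type=f"AE{a + 1:02d}",
            )
            units.append(unit)
            row = {
                "trial_id": trial_id,
                "ae_type": f"AE{a + 1:02d}",
                "n": n_trial,
                "ae_hazard_factor": ae_factor,
                "ce_hazard_factor": ce_factor,
            }
            if hz.family == "constant":
                row["true_ae_rate"] = hz.ae_rate
                row["true_ce_rate"] = hz.ce_rate
                row["true_cif_at_closure"] = true_cumulative_incidence(
                    hz.ae_rate, hz.ce_rate, spec.admin_censoring_time
                )
            truth_rows.append(row)
    return units, pd.DataFrame(truth_rows)
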