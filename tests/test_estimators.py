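"""Estimator correctness: hand examples, algebraic identities, independent oracles."""

import math

import numpy as np
import pytest

from aerisk import (
    CeScheme,
    Outcome,
    TauRule,
    aalen_johansen,
    aje_ce_incidence,
    evaluation_time,
    incidence_density,
    incidence_proportion,
    one_minus_kaplan_meier,
    prob_transform_id_accounting_ce,
    prob_transform_id_ignoring_ce,
)
from aerisk.estimators import StepCurve

from conftest import counts_set, make_set, random_set

AE, CE, CEN, DEATH = int(Outcome.AE), int(Outcome.OTHER_CE), int(Outcome.CENSORED), int(Outcome.DEATH_BEFORE_AE)


# ---------------------------------------------------------------- oracles

def brute_one_minus_km(records, tau):
    """O(n^2) product-limit over explicit risk sets; AE is the only event."""
    surv = 1.0
    for tj in sorted({t for t, c in records if c == AE and t <= tau}):
        d = sum(1 for t, c in records if c == AE and t == tj)
        y = sum(1 for t, _ in records if t >= tj)
        surv *= 1.0 - d / y
    return 1.0 - surv


def brute_aj(records, tau, cause_ae=True):
    """O(n^2) Aalen-Johansen: S(t-) * d_cause / Y accumulated over event times."""
    surv, cif = 1.0, 0.0
    for tj in sorted({t for t, c in records if c in (AE, CE, DEATH) and t <= tau}):
        y = sum(1 for t, _ in records if t >= tj)
        d_all = sum(1 for t, c in records if c in (AE, CE, DEATH) and t == tj)
        want = (AE,) if cause_ae else (CE, DEATH)
        d_cause = sum(1 for t, c in records if c in want and t == tj)
        cif += surv * d_cause / y
        surv *= 1.0 - d_all / y
    return cif


# ---------------------------------------------------------- hand examples

class TestHandExamples:
    def test_one_minus_km(self, hand_unit):
        # CE at 1 censored, AE at 2 among 2 at risk: S = 1/2
        assert one_minus_kaplan_meier(hand_unit, 3.0).estimate == pytest.approx(0.5, abs=1e-12)

    def test_aalen_johansen(self, hand_unit):
        # S(2-) = 2/3, AE increment (2/3)(1/2) = 1/3
        assert aalen_johansen(hand_unit, 3.0).estimate == pytest.approx(1 / 3, abs=1e-12)

    def test_ce_incidence(self, hand_unit):
        # S(1-) = 1, CE increment 1/3
        assert aje_ce_incidence(hand_unit, 3.0) == pytest.approx(1 / 3, abs=1e-12)

    def test_incidence_proportion_printed_counts(self):
        assert incidence_proportion(counts_set(3, 17, 180, 74), 300.0).estimate == pytest.approx(
            0.011, abs=5e-4
        )
        assert incidence_proportion(counts_set(44, 137, 95, 476), 800.0).estimate == pytest.approx(
            0.059, abs=5e-4
        )

    def test_incidence_density_single_patient(self):
        s = make_set([10.0], [AE])
        assert incidence_density(s, 10.0) == pytest.approx(0.1, abs=1e-15)
        assert prob_transform_id_ignoring_ce(s, 10.0).estimate == pytest.approx(
            1 - math.exp(-1), abs=1e-12
        )

    def test_no_ae_gives_zero_everywhere(self):
        s = make_set([1.0, 2.0, 3.0], [CEN, CE, DEATH])
        tau = 3.0
        for f in (incidence_proportion, prob_transform_id_ignoring_ce,
                  prob_transform_id_accounting_ce, one_minus_kaplan_meier):
            assert f(s, tau).estimate == 0.0
        assert aalen_johansen(s, tau).estimate == 0.0

    def test_acc_ce_zero_when_no_events(self):
        s = make_set([4.0, 5.0], [CEN, CEN])
        assert prob_transform_id_accounting_ce(s, 5.0).estimate == 0.0


# ------------------------------------------------------------- identities

class TestIdentities:
    def test_acc_ce_reduces_to_ignore_ce_without_ces(self, rng):
        for _ in range(100):
            s = random_set(rng)
            keep = ~np.isin(s.outcomes, (CE, DEATH))
            if not keep.any():
                continue
            s2 = make_set(s.times[keep], s.outcomes[keep])
            tau = float(s2.times.max())
            a = prob_transform_id_accounting_ce(s2, tau).estimate
            b = prob_transform_id_ignoring_ce(s2, tau).estimate
            assert a == pytest.approx(b, abs=1e-12)

    def test_aje_equals_km_without_ces(self, rng):
        for _ in range(100):
            s = random_set(rng)
            out = s.outcomes.copy()
            out[np.isin(out, (CE, DEATH))] = CEN
            s2 = make_set(s.times, out)
            for tau in (1.0, 3.0, s2.max_time):
                assert aalen_johansen(s2, tau).estimate == pytest.approx(
                    one_minus_kaplan_meier(s2, tau).estimate, abs=1e-12
                )

    def test_aje_equals_ip_without_censoring(self, rng):
        for _ in range(100):
            s = random_set(rng)
            out = s.outcomes.copy()
            out[out == CEN] = CE
            s2 = make_set(s.times, out)
            tau = s2.max_time
            assert aalen_johansen(s2, tau).estimate == pytest.approx(
                incidence_proportion(s2, tau).estimate, abs=1e-12
            )

    def test_cif_decomposition(self, rng):
        # AE-CIF + CE-CIF = 1 - all-event KM at every tau
        for _ in range(100):
            s = random_set(rng)
            out = s.outcomes.copy()
            composite = out.copy()
            composite[np.isin(composite, (CE, DEATH))] = AE
            s_comp = make_set(s.times, composite)
            for tau in (1.0, 2.5, s.max_time):
                lhs = aalen_johansen(s, tau).estimate + aje_ce_incidence(s, tau)
                rhs = one_minus_kaplan_meier(s_comp, tau).estimate
                assert lhs == pytest.approx(rhs, abs=1e-12)


# -------------------------------------------------------------- orderings

class TestOrderings:
    def test_km_geq_aje_geq_ip(self, rng):
        for _ in range(200):
            s = random_set(rng)
            for tau in (1.0, 3.0, s.max_time):
                km = one_minus_kaplan_meier(s, tau).estimate
                aj = aalen_johansen(s, tau).estimate
                ip = incidence_proportion(s, tau).estimate
                assert km >= aj - 1e-12
                assert aj >= ip - 1e-12

    def test_death_only_geq_all_ce(self, rng):
        for _ in range(200):
            s = random_set(rng)
            tau = s.max_time
            d = aalen_johansen(s, tau, CeScheme.DEATH_ONLY).estimate
            a = aalen_johansen(s, tau, CeScheme.ALL_CE).estimate
            assert d >= a - 1e-12
            if not np.any((s.outcomes == CE) & (s.times <= tau)):
                assert d == pytest.approx(a, abs=1e-12)


# ------------------------------------------------ brute-force equivalence

class TestOracleEquivalence:
    def test_agrees_with_brute_force_enumeration(self, rng):
        for _ in range(200):
            s = random_set(rng, n_max=8)
            recs = list(zip(s.times.tolist(), s.outcomes.tolist()))
            for tau in (1.0, 2.0, 4.0, s.max_time):
                assert one_minus_kaplan_meier(s, tau).estimate == pytest.approx(
                    brute_one_minus_km(recs, tau), abs=1e-12
                )
                assert aalen_johansen(s, tau).estimate == pytest.approx(
                    brute_aj(recs, tau, cause_ae=True), abs=1e-12
                )
                assert aje_ce_incidence(s, tau) == pytest.approx(
                    brute_aj(recs, tau, cause_ae=False), abs=1e-12
                )

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for seed in range(10):
            r = np.random.default_rng(seed)
            s = random_set(r, n_max=40, n_min=10)
            # continuous times: lifelines' Aalen-Johansen jitters ties
            s = make_set(r.uniform(0.5, 10.0, s.n), s.outcomes)
            tau = s.max_time
            kmf = lifelines.KaplanMeierFitter().fit(
                s.times, (s.outcomes == AE).astype(int)
            )
            assert one_minus_kaplan_meier(s, tau).estimate == pytest.approx(
                1.0 - float(kmf.survival_function_at_times(tau).iloc[0]), abs=1e-10
            )
            events = np.where(np.isin(s.outcomes, (CE, DEATH)), 2, s.outcomes)
            if not np.any(events == 1):
                continue
            ajf = lifelines.AalenJohansenFitter(calculate_variance=False).fit(
                s.times, events, event_of_interest=1
            )
            ours = aalen_johansen(s, tau).estimate
            theirs = float(ajf.cumulative_density_.iloc[-1, 0])
            assert ours == pytest.approx(theirs, abs=1e-10)


# -------------------------------------------------------- evaluation time

class TestEvaluationTime:
    def test_quantile_one_is_maximum(self):
        s = make_set([1.0, 2.0, 3.0], [AE, CEN, CEN])
        assert evaluation_time(s, TauRule.Q100) == 3.0
        assert evaluation_time(s, TauRule.MAX_FOLLOW_UP) == 3.0

    def test_two_arm_minimum(self):
        a = make_set(np.arange(1.0, 101.0), [CEN] * 100)
        b = make_set(np.arange(1.0, 81.0), [CEN] * 80)
        assert evaluation_time({"E": a, "C": b}, TauRule.Q100) == 80.0

    def test_nearest_rank_quantile(self):
        s = make_set(np.arange(10.0, 101.0, 10.0), [CEN] * 10)
        assert evaluation_time(s, TauRule.Q90) == 90.0
        assert evaluation_time(s, TauRule.Q60) == 60.0
        assert evaluation_time(s, TauRule.Q30) == 30.0


# --------------------------------------------------------------- plumbing

class TestStepCurve:
    def test_evaluation_and_left_limit(self):
        c = StepCurve(times=np.array([1.0, 3.0]), values=np.array([0.2, 0.7]), initial=0.0)
        assert c(0.5) == 0.0
        assert c(1.0) == 0.2
        assert c(2.9) == 0.2
        assert c(3.0) == 0.7
        assert c.left_limit(3.0) == 0.2
        assert c.left_limit(1.0) == 0.0

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            StepCurve(times=np.array([2.0, 1.0]), values=np.array([0.1, 0.2]), initial=0.0)
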