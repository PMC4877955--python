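"""Markov engine: trends, rate conversion, transitions, cohort runs."""

import math

import numpy as np
import pytest

from saltsim.interventions import DO_NOTHING, get_scenario
from saltsim.markov_engine import (ALIVE, CHD_LATER, CHD_Y1, DEAD_CVD,
                                   DEAD_OTHER, HEALTHY, N_STATES, STROKE_LATER,
                                   STROKE_Y1, rate_to_prob, run_cohort,
                                   transition_matrix, transition_probabilities,
                                   trended_rate)
from saltsim.strata import StratumKey

from conftest import make_uniform_inputs


class TestTrendedRate:
    def test_closed_form_decline(self):
        assert trended_rate(0.01, -0.02, 2016, 2011, 2026) == pytest.approx(
            0.01 * 0.98 ** 5, rel=1e-12)

    def test_frozen_after_trend_end(self):
        frozen = 0.01 * 0.98 ** 15
        assert trended_rate(0.01, -0.02, 2040, 2011, 2026) == pytest.approx(frozen, rel=1e-12)
        assert (trended_rate(0.01, -0.02, 2026, 2011, 2026)
                == trended_rate(0.01, -0.02, 2035, 2011, 2026))

    def test_zero_trend_identity(self):
        assert trended_rate(0.123, 0.0, 2050, 2011, 2026) == 0.123


class TestRateToProb:
    def test_values_and_bounds(self):
        assert rate_to_prob(0.0) == 0.0
        assert rate_to_prob(0.01) == pytest.approx(1 - math.exp(-0.01), rel=1e-12)
        assert 0.9999 < rate_to_prob(10.0) < 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.1)


def _oracle_matrix(i_chd, i_str, bg, cf_chd, cf_str):
    """Independent enumeration of the exponential competing-risk formulas."""
    P = np.zeros((N_STATES, N_STATES))
    R = i_chd + i_str + bg
    p_exit = 1 - math.exp(-R)
    P[HEALTHY, CHD_Y1] = p_exit * i_chd / R
    P[HEALTHY, STROKE_Y1] = p_exit * i_str / R
    P[HEALTHY, DEAD_OTHER] = p_exit * bg / R
    P[HEALTHY, HEALTHY] = math.exp(-R)
    for y1, later, cf in ((CHD_Y1, CHD_LATER, cf_chd), (STROKE_Y1, STROKE_LATER, cf_str)):
        Rd = cf + bg
        pd_exit = 1 - math.exp(-Rd)
        for origin in (y1, later):
            P[origin, DEAD_CVD] = pd_exit * cf / Rd
            P[origin, DEAD_OTHER] = pd_exit * bg / Rd
            P[origin, later] = math.exp(-Rd)
    P[DEAD_CVD, DEAD_CVD] = P[DEAD_OTHER, DEAD_OTHER] = 1.0
    return P


class TestTransitionMatrix:
    def test_matches_independent_enumeration(self):
        rates = (0.01, 0.005, 0.02, 0.05, 0.08)
        np.testing.assert_allclose(transition_matrix(*rates),
                                   _oracle_matrix(*rates), rtol=0, atol=1e-15)

    def test_rows_sum_to_one_on_random_rates(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rates = rng.uniform(0, 0.5, size=5)
            P = transition_matrix(*rates)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert ((P >= 0) & (P <= 1)).all()

    def test_zero_rates_identity_for_survivors(self):
        P = transition_matrix(0, 0, 0, 0, 0)
        assert P[HEALTHY, HEALTHY] == 1.0
        assert P[CHD_Y1, CHD_LATER] == 1.0  # tunnel to subsequent-year state

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-0.01, 0, 0, 0, 0)


class TestTransitionProbabilities:
    def test_multiplier_affects_only_healthy_exits(self, inputs1):
        stratum = StratumKey("male", "maori", 60)
        base = transition_probabilities(stratum, 2020, inputs1)
        scaled = transition_probabilities(stratum, 2020, inputs1,
                                          {"chd": 0.8, "stroke": 0.8})
        diff = np.abs(base - scaled)
        assert diff[HEALTHY].max() > 0
        assert diff[CHD_Y1:].max() == 0  # disease and dead rows unchanged

    def test_rows_sum_to_one(self, inputs1):
        P = transition_probabilities(StratumKey("female", "non_maori", 80), 2035, inputs1)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestRunCohort:
    def test_matrix_power_oracle(self):
        """Constant rates, no trend: occupancy equals occ0 @ P^k to 1e-12."""
        inputs = make_uniform_inputs(chd_prevalence=0.04, stroke_prevalence=0.02)
        traj = run_cohort(inputs, DO_NOTHING)
        P = _oracle_matrix(0.01, 0.005, 0.02, 0.05, 0.08)
        occ0 = np.zeros(N_STATES)
        occ0[CHD_LATER], occ0[STROKE_LATER] = 0.04, 0.02
        occ0[HEALTHY] = 1 - 0.06
        c = int(np.argmin(traj.start_age))  # youngest cohort, longest horizon
        Pk = np.eye(N_STATES)
        for t in range(20):
            Pk = Pk @ P
            np.testing.assert_allclose(traj.occ[t, c], occ0 @ Pk, rtol=0, atol=1e-12)

    def test_determinism(self, inputs1):
        a = run_cohort(inputs1, get_scenario("subst25"))
        b = run_cohort(inputs1, get_scenario("subst25"))
        assert np.array_equal(a.occ, b.occ)

    def test_occupancy_conservation(self, inputs1):
        traj = run_cohort(inputs1, get_scenario("subst59"))
        np.testing.assert_allclose(traj.occ.sum(axis=2), 1.0, atol=1e-9)

    def test_dead_fraction_monotone(self, inputs1):
        traj = run_cohort(inputs1, DO_NOTHING)
        dead = traj.occ[:, :, DEAD_CVD] + traj.occ[:, :, DEAD_OTHER]
        assert (np.diff(dead, axis=0) >= -1e-12).all()

    def test_everyone_dead_by_age_100(self, inputs1):
        traj = run_cohort(inputs1, DO_NOTHING)
        final = traj.occ[-1]
        np.testing.assert_allclose(final[:, ALIVE].sum(axis=1), 0.0, atol=1e-12)

    def test_prevalence_seeds_subsequent_year_states(self, inputs1):
        traj = run_cohort(inputs1, DO_NOTHING)
        # first-cycle first-year occupancy comes only from incident cases
        assert (traj.occ[0, :, CHD_Y1] < traj.occ[0, :, CHD_LATER]).mean() > 0.9

    def test_intervention_ordering_of_healthy_occupancy(self, inputs1):
        occ = {name: run_cohort(inputs1, get_scenario(name)).occ[:, :, HEALTHY]
               for name in ("do_nothing", "subst25", "subst59")}
        assert (occ["subst59"] >= occ["subst25"] - 1e-15).all()
        assert (occ["subst25"] >= occ["do_nothing"] - 1e-15).all()

    def test_ages_advance_one_year_per_cycle(self, inputs1):
        traj = run_cohort(inputs1, DO_NOTHING)
        assert (np.diff(traj.ages, axis=0) == 1).all()
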