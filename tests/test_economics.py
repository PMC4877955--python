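"""Economics: utilities, discounting, costs, accrual, incremental logic."""

import numpy as np
import pytest

import saltsim
from saltsim.economics import (CostScaleups, DiscountSpec, accrue, classify,
                               discount_factor, incremental, per_capita,
                               state_cost, utility_weight)
from saltsim.interventions import DO_NOTHING, InterventionSpec
from saltsim.markov_engine import run_cohort


class TestUtilityWeight:
    def test_state_utilities(self):
        assert utility_weight("dead_cvd", 0.05, 0.081, 0.226) == 0.0
        assert utility_weight("dead_other", 0.05, 0.081, 0.226) == 0.0
        assert utility_weight("healthy", 0.05, 0.081, 0.226) == pytest.approx(0.95)
        assert utility_weight("chd_later", 0.05, 0.081, 0.226) == pytest.approx(0.869)
        assert utility_weight("stroke_later", 0.05, 0.081, 0.226) == pytest.approx(0.724)

    def test_negative_utility_rejected(self):
        with pytest.raises(ValueError):
            utility_weight("stroke_year1", 0.9, 0.081, 0.226)


class TestDiscounting:
    def test_closed_form_factors(self):
        spec = DiscountSpec(rate=0.03)
        assert discount_factor(2011, spec) == 1.0
        assert discount_factor(2021, spec) == pytest.approx(1.03 ** -10, rel=1e-12)
        assert discount_factor(2050, DiscountSpec(rate=0.0)) == 1.0

    def test_pre_reference_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(2010, DiscountSpec())

    def test_accrual_matches_closed_form_reweighting(self, inputs1):
        """Discounted accrual == undiscounted rows x closed-form factors."""
        traj = run_cohort(inputs1, DO_NOTHING)
        led0 = accrue(traj, inputs1, DiscountSpec(rate=0.0))
        led3 = accrue(traj, inputs1, DiscountSpec(rate=0.03))
        factors = 1.03 ** -(led0.years - 2011).astype(float)
        np.testing.assert_allclose(led3.total_qalys,
                                   (led0.qalys_tc * factors[:, None]).sum(),
                                   rtol=1e-12)
        assert led0.total_qalys >= led3.total_qalys
        assert led0.total_costs >= led3.total_costs


class TestStateCost:
    def test_anchor_costs_with_public_share_scaleup(self, inputs1):
        assert state_cost("chd_year1", "female", 62, inputs1) == pytest.approx(
            16258 * 1.2)
        assert state_cost("healthy", "female", 62, inputs1) == pytest.approx(2381 * 1.2)
        assert state_cost("dead_cvd", "female", 62, inputs1) == 0.0

    @pytest.mark.parametrize("age,mult", [(64, 1.0), (65, 1.1), (74, 1.1),
                                          (75, 1.2), (84, 1.2), (85, 1.3), (99, 1.3)])
    def test_old_age_multipliers(self, inputs1, age, mult):
        got = state_cost("chd_later", "male", age, inputs1)
        assert got == pytest.approx(5395 * 1.2 * mult)

    def test_scaleups_all_at_least_one(self):
        s = CostScaleups()
        assert s.public_share_factor >= 1
        assert all(m >= 1 for _, m in s.old_age_multipliers)


class TestAccrue:
    def test_single_cohort_hand_arithmetic(self, uniform_inputs):
        """One cohort, first cycles, checked against explicit hand sums."""
        traj = run_cohort(uniform_inputs, DO_NOTHING)
        led = accrue(traj, uniform_inputs, DiscountSpec(rate=0.03))
        c = 0  # first cohort: male maori starting age 35, pop 200
        occ = traj.occ[:, c, :]
        pyld = 0.05 + 0.0  # uniform background pYLD
        util = np.array([1 - 0.05, 1 - 0.05 - 0.081, 1 - 0.05 - 0.081,
                         1 - 0.05 - 0.226, 1 - 0.05 - 0.226, 0, 0])
        del pyld
        expected_q0 = (occ[0] * util).sum() * traj.pop[c]
        assert led.qalys_tc[0, c] == pytest.approx(expected_q0, rel=1e-12)
        cost = np.array([2381.0, 16258, 5395, 20553, 5991, 0, 0]) * 1.2
        expected_c1 = (occ[1] * cost).sum() * traj.pop[c]
        assert led.costs_tc[1, c] == pytest.approx(expected_c1, rel=1e-12)

    def test_stratum_ledgers_sum_to_totals(self, inputs1, comparator_ledger):
        led = comparator_ledger
        assert led.total_qalys == pytest.approx(led.qalys_tc_disc.sum(), rel=1e-12)
        assert led.total_costs == pytest.approx(
            led.costs_tc_disc.sum() + led.one_off_cost, rel=1e-12)

    def test_qalys_bounded_by_alive_person_years(self, inputs1, comparator_ledger):
        traj = run_cohort(inputs1, DO_NOTHING)
        alive_py = (traj.occ[:, :, :5].sum(axis=2) * traj.pop[None, :])
        assert (comparator_ledger.qalys_tc <= alive_py + 1e-9).all()

    def test_mismatched_inputs_rejected(self, inputs1):
        other = saltsim.generate_inputs(2)
        traj = run_cohort(inputs1, DO_NOTHING)
        with pytest.raises(ValueError, match="different inputs"):
            accrue(traj, other)


class TestIncremental:
    def test_null_scenario_yields_exact_zero_deltas(self, inputs1, comparator_ledger):
        null = InterventionSpec("null", 0.0, phase_in_years=1, one_off_cost=0.0)
        led = accrue(run_cohort(inputs1, null), inputs1)
        res = incremental(led, comparator_ledger)
        assert res.delta_qalys == 0.0
        assert res.delta_costs == 0.0
        assert res.classification != "dominant"

    def test_comparator_against_itself(self, comparator_ledger):
        res = incremental(comparator_ledger, comparator_ledger)
        assert res.delta_qalys == 0.0 and res.delta_costs == 0.0

    def test_classification_matches_defining_inequalities(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            dq, dc = rng.normal(size=2)
            cls, icer = classify(dq, dc)
            if dq > 0 and dc < 0:
                assert cls == "dominant" and icer is None
            elif dq < 0 and dc > 0:
                assert cls == "dominated" and icer is None
            else:
                assert cls == "icer"
                if dq > 0 and dc > 0:
                    assert icer == pytest.approx(dc / dq)

    def test_mismatched_fingerprints_rejected(self, inputs1, comparator_ledger):
        other = saltsim.generate_inputs(3)
        led = accrue(run_cohort(other, DO_NOTHING), other)
        with pytest.raises(ValueError, match="different model inputs"):
            incremental(led, comparator_ledger)


class TestPerCapita:
    def test_whole_cohort_quotient(self, central_results):
        res = central_results["subst59"]
        dq, dc = per_capita(res)
        assert dq == pytest.approx(res.delta_qalys / res.pop.sum())
        assert dc == pytest.approx(res.delta_costs / res.pop.sum())

    def test_partition_weighted_mean_identity(self, central_results):
        """Ethnic per-capita values, population-weighted, recover the total."""
        res = central_results["subst25"]
        whole_q, whole_c = per_capita(res)
        maori = res.eth_idx == 0
        q_m, c_m = per_capita(res, maori)
        q_n, c_n = per_capita(res, ~maori)
        pm, pn = res.pop[maori].sum(), res.pop[~maori].sum()
        assert (q_m * pm + q_n * pn) / (pm + pn) == pytest.approx(whole_q, rel=1e-12)
        assert (c_m * pm + c_n * pn) / (pm + pn) == pytest.approx(whole_c, rel=1e-12)

    def test_empty_group_rejected(self, central_results):
        res = central_results["subst25"]
        with pytest.raises(ValueError, match="no population"):
            per_capita(res, np.zeros_like(res.pop, dtype=bool))
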