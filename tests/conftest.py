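"""Shared fixtures: default synthetic inputs, central runs, toy instances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import saltsim
from saltsim.strata import AGE_BAND_STARTS, ETHNICITIES, SEXES
from saltsim.synthetic_inputs import (DEFAULT_BP_RESPONSE, ModelInputs,
                                      SodiumBaseline, TrendSpec,
                                      default_hazard_ratios)


@pytest.fixture(scope="session")
def inputs1() -> ModelInputs:
    """Default synthetic parameter set at the pinned seed."""
    return saltsim.generate_inputs(1)


@pytest.fixture(scope="session")
def comparator_ledger(inputs1):
    traj = saltsim.run_cohort(inputs1, saltsim.DO_NOTHING)
    return saltsim.accrue(traj, inputs1)


@pytest.fixture(scope="session")
def central_results(inputs1, comparator_ledger):
    """Incremental results for all four built-ins at 3% discounting."""
    results = {}
    for name, spec in saltsim.BUILTIN_SCENARIOS.items():
        if name == "do_nothing":
            continue
        ledger = saltsim.accrue(saltsim.run_cohort(inputs1, spec), inputs1)
        results[name] = saltsim.incremental(ledger, comparator_ledger)
    return results


def make_uniform_inputs(*, chd_incidence=0.01, stroke_incidence=0.005,
                        chd_case_fatality=0.05, stroke_case_fatality=0.08,
                        background_mortality=0.02, chd_prevalence=0.0,
                        stroke_prevalence=0.0, background_pyld=0.05,
                        count=1000.0, trend: TrendSpec | None = None) -> ModelInputs:
    """A parameter set with identical rates in every stratum.

    With zero trends and a zero-dose scenario the chain is homogeneous in
    time, so occupancies admit an exact matrix-power solution.
    """
    idx = pd.MultiIndex.from_product(
        [SEXES, ETHNICITIES, AGE_BAND_STARTS], names=["sex", "ethnicity", "age_band"])
    epi = pd.DataFrame({
        "chd_incidence": chd_incidence,
        "stroke_incidence": stroke_incidence,
        "chd_case_fatality": chd_case_fatality,
        "stroke_case_fatality": stroke_case_fatality,
        "chd_prevalence": chd_prevalence,
        "stroke_prevalence": stroke_prevalence,
        "background_mortality": background_mortality,
    }, index=idx)
    morbidity = pd.DataFrame({
        "background_pyld": background_pyld,
        "dw_chd": 0.081, "dw_chd_lo": 0.05, "dw_chd_hi": 0.11,
        "dw_stroke": 0.226, "dw_stroke_lo": 0.11, "dw_stroke_hi": 0.23,
    }, index=idx)
    cost_idx = pd.MultiIndex.from_product([SEXES, AGE_BAND_STARTS],
                                          names=["sex", "age_band"])
    costs = pd.DataFrame({"healthy_annual_cost": 2381.0}, index=cost_idx)
    return ModelInputs(
        population=pd.DataFrame({"count": count}, index=idx),
        epi=epi,
        morbidity=morbidity,
        costs=costs,
        disease_costs={"chd": {"first_year": 16258.0, "subsequent_year": 5395.0},
                       "stroke": {"first_year": 20553.0, "subsequent_year": 5991.0}},
        trend=trend or TrendSpec(incidence_apc=0.0, case_fatality_apc=0.0,
                                 background_mortality_apc_non_maori=0.0,
                                 background_mortality_apc_maori=0.0),
        sodium=SodiumBaseline(),
        bp_response=dict(DEFAULT_BP_RESPONSE),
        hazard_ratios=default_hazard_ratios(),
        generator_seed=None,
    )


@pytest.fixture()
def uniform_inputs() -> ModelInputs:
    return make_uniform_inputs()
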