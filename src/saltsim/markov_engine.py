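"""Annual-cycle closed-cohort Markov macro-simulation.

The cohort (ages 35+ at the 2011 baseline) is advanced through annual
cycles until death or age 100.  States: healthy, first-year CHD,
subsequent-year CHD, first-year stroke, subsequent-year stroke, CVD
death, other-cause death.  The first-year/subsequent-year split is a
tunnel refinement carrying the first-year cost (and, if supplied, a
distinct first-year case fatality); occupants move deterministically to
the subsequent-year state after one cycle unless they die.

Competing risks within a cycle are resolved jointly through the
exponential formula: total exit probability 1 - exp(-sum of rates),
apportioned among causes proportionally to their rates.  Five-year input
bands are expanded to single-year starting ages (the band value applies
to each constituent age), and each single-age cohort ages one year per
cycle.  No half-cycle correction is applied: state membership is
evaluated at cycle end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import risk_pathway
from .interventions import InterventionSpec
from .strata import (AGE_BAND_STARTS, AGE_BAND_WIDTH, ETHNICITIES, MAX_AGE,
                     SEXES, StratumKey, all_strata, band_for_age)
from .synthetic_inputs import ModelInputs

# state indices
HEALTHY, CHD_Y1, CHD_LATER, STROKE_Y1, STROKE_LATER, DEAD_CVD, DEAD_OTHER = range(7)
STATES = ("healthy", "chd_year1", "chd_later", "stroke_year1", "stroke_later",
          "dead_cvd", "dead_other")
N_STATES = len(STATES)
ALIVE = slice(0, 5)


def trended_rate(base_rate: float, apc: float, year: int, baseline_year: int,
                 trend_end_year: int) -> float:
    """Rate after applying an annual percentage change, frozen at trend end.

    base_rate x (1 + apc) ^ min(year - baseline, trend_end - baseline).
    """
    years = min(year - baseline_year, trend_end_year - baseline_year)
    return base_rate * (1.0 + apc) ** years


def rate_to_prob(rate: float) -> float:
    """Annual event probability for a constant hazard: 1 - exp(-rate)."""
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return -math.expm1(-rate)


def transition_matrix(i_chd: float, i_stroke: float, bg_mort: float,
                      cf_chd: float, cf_stroke: float) -> np.ndarray:
    """Single-cycle 7x7 transition matrix from annual rates.

    Rates are competing within each origin state: the healthy state exits
    to first-year disease or other-cause death; disease states exit to
    CVD death (case fatality) or other-cause death, with first-year
    survivors tunnelling into the subsequent-year state.
    """
    for name, r in (("chd incidence", i_chd), ("stroke incidence", i_stroke),
                    ("background mortality", bg_mort), ("chd case fatality", cf_chd),
                    ("stroke case fatality", cf_stroke)):
        if r < 0:
            raise ValueError(f"{name} rate must be non-negative, got {r}")
    P = np.zeros((N_STATES, N_STATES))

    R = i_chd + i_stroke + bg_mort
    p_exit = rate_to_prob(R)
    w = p_exit / R if R > 0 else 0.0
    P[HEALTHY, CHD_Y1] = i_chd * w
    P[HEALTHY, STROKE_Y1] = i_stroke * w
    P[HEALTHY, DEAD_OTHER] = bg_mort * w
    P[HEALTHY, HEALTHY] = 1.0 - p_exit

    for y1, later, cf in ((CHD_Y1, CHD_LATER, cf_chd), (STROKE_Y1, STROKE_LATER, cf_stroke)):
        Rd = cf + bg_mort
        p_exit_d = rate_to_prob(Rd)
        wd = p_exit_d / Rd if Rd > 0 else 0.0
        for origin in (y1, later):
            P[origin, DEAD_CVD] = cf * wd
            P[origin, DEAD_OTHER] = bg_mort * wd
            P[origin, later] = 1.0 - p_exit_d

    P[DEAD_CVD, DEAD_CVD] = 1.0
    P[DEAD_OTHER, DEAD_OTHER] = 1.0
    return P


def transition_probabilities(stratum: StratumKey, year: int, inputs: ModelInputs,
                             multipliers: dict[str, float] | None = None) -> np.ndarray:
    """Transition matrix for one stratum and calendar year.

    Applies secular trends to the base rates and the scenario's incidence
    multipliers (healthy-state exits only).  Row sums are 1 by
    construction of the competing-risk formulas.
    """
    multipliers = multipliers or {"chd": 1.0, "stroke": 1.0}
    t = inputs.trend
    key = (stratum.sex, stratum.ethnicity, stratum.age_band)
    row = inputs.epi.loc[key]
    bg_apc = (t.background_mortality_apc_maori if stratum.ethnicity == "maori"
              else t.background_mortality_apc_non_maori)
    i_chd = trended_rate(row["chd_incidence"], t.incidence_apc, year,
                         t.baseline_year, t.trend_end_year) * multipliers["chd"]
    i_str = trended_rate(row["stroke_incidence"], t.incidence_apc, year,
                         t.baseline_year, t.trend_end_year) * multipliers["stroke"]
    cf_chd = trended_rate(row["chd_case_fatality"], t.case_fatality_apc, year,
                          t.baseline_year, t.trend_end_year)
    cf_str = trended_rate(row["stroke_case_fatality"], t.case_fatality_apc, year,
                          t.baseline_year, t.trend_end_year)
    bg = trended_rate(row["background_mortality"], bg_apc, year,
                      t.baseline_year, t.trend_end_year)
    return transition_matrix(i_chd, i_str, bg, cf_chd, cf_str)


@dataclass
class Trajectory:
    """Per-cohort, per-cycle state occupancies for one scenario run.

    ``occ[t, c, s]`` is the fraction of cohort ``c`` in state ``s`` at the
    end of cycle year ``years[t]``; ``ages[t, c]`` is the cohort's age
    during that cycle.  Cohorts are single starting ages expanded from the
    5-year input bands; metadata arrays give each cohort's sex/ethnicity
    index, starting age and person count.
    """

    years: np.ndarray          # (T,)
    occ: np.ndarray            # (T, C, N_STATES)
    ages: np.ndarray           # (T, C)
    sex_idx: np.ndarray        # (C,) 0=male, 1=female
    eth_idx: np.ndarray        # (C,) 0=maori, 1=non_maori
    start_age: np.ndarray      # (C,)
    pop: np.ndarray            # (C,) persons
    scenario: InterventionSpec
    inputs_fingerprint: str

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (stratum, year, age, state, fraction)."""
        T, C, S = self.occ.shape
        recs = []
        for c in range(C):
            sex = SEXES[self.sex_idx[c]]
            eth = ETHNICITIES[self.eth_idx[c]]
            for t in range(T):
                age = int(self.ages[t, c])
                for s in range(S):
                    recs.append((sex, eth, int(self.start_age[c]), self.years[t],
                                 age, STATES[s], self.occ[t, c, s]))
        return pd.DataFrame(recs, columns=["sex", "ethnicity", "start_age", "year",
                                           "age", "state", "fraction"])


def _cohort_arrays(inputs: ModelInputs):
    """Expand 5-year bands into single-age cohorts with equal pop splits."""
    sex_idx, eth_idx, start_age, pop = [], [], [], []
    prev_chd, prev_str = [], []
    for s in all_strata():
        count = inputs.population.loc[(s.sex, s.ethnicity, s.age_band), "count"]
        row = inputs.epi.loc[(s.sex, s.ethnicity, s.age_band)]
        for off in range(AGE_BAND_WIDTH):
            sex_idx.append(SEXES.index(s.sex))
            eth_idx.append(ETHNICITIES.index(s.ethnicity))
            start_age.append(s.age_band + off)
            pop.append(count / AGE_BAND_WIDTH)
            prev_chd.append(row["chd_prevalence"])
            prev_str.append(row["stroke_prevalence"])
    return (np.array(sex_idx), np.array(eth_idx), np.array(start_age),
            np.array(pop, dtype=float), np.array(prev_chd), np.array(prev_str))


def _epi_cube(inputs: ModelInputs) -> dict[str, np.ndarray]:
    """Base rates as (sex, ethnicity, band) arrays for fast gathering."""
    cube = {}
    epi = inputs.epi.sort_index()
    for col in ("chd_incidence", "stroke_incidence", "chd_case_fatality",
                "stroke_case_fatality", "background_mortality"):
        arr = np.zeros((len(SEXES), len(ETHNICITIES), len(AGE_BAND_STARTS)))
        for si, sex in enumerate(SEXES):
            for ei, eth in enumerate(ETHNICITIES):
                arr[si, ei, :] = epi.loc[(sex, eth), col].reindex(AGE_BAND_STARTS).to_numpy()
        cube[col] = arr
    return cube


def run_cohort(inputs: ModelInputs, scenario: InterventionSpec,
               hazard_ratios: pd.DataFrame | None = None,
               effect_scale: float = 1.0) -> Trajectory:
    """Run the full closed-cohort simulation under one scenario.

    Deterministic given its arguments.  Baseline disease-state occupancy
    is seeded from prevalence into the subsequent-year states (prevalent
    cases are predominantly non-incident); the remainder starts healthy.
    At age 100 any remaining alive occupancy is absorbed into other-cause
    death and nothing further accrues.
    """
    trend = inputs.trend
    baseline_year = trend.baseline_year
    sex_idx, eth_idx, start_age, pop, prev_chd, prev_str = inputs.cached(
        "cohort_arrays", lambda: _cohort_arrays(inputs))
    cube = inputs.cached("epi_cube", lambda: _epi_cube(inputs))
    C = len(pop)
    T = MAX_AGE - int(start_age.min()) + 1  # cycles + final absorption row

    cur = np.zeros((C, N_STATES))
    cur[:, CHD_LATER] = prev_chd
    cur[:, STROKE_LATER] = prev_str
    cur[:, HEALTHY] = 1.0 - prev_chd - prev_str

    occ = np.zeros((T, C, N_STATES))
    ages = np.zeros((T, C), dtype=int)
    years = baseline_year + np.arange(T)
    trend_cap = trend.trend_end_year - baseline_year
    bg_apc = np.where(eth_idx == 0, trend.background_mortality_apc_maori,
                      trend.background_mortality_apc_non_maori)

    for t in range(T):
        age = start_age + t
        # terminal absorption: anyone reaching age 100 moves to other-cause death
        done = age >= MAX_AGE
        if done.any():
            alive = cur[done, ALIVE].sum(axis=1)
            cur[done, DEAD_OTHER] += alive
            cur[done, ALIVE] = 0.0
        act = ~done
        if act.any():
            a = age[act]
            band = np.clip((a - 35) // 5, 0, len(AGE_BAND_STARTS) - 1)
            si, ei = sex_idx[act], eth_idx[act]
            tf = min(t, trend_cap)
            inc_f = (1.0 + trend.incidence_apc) ** tf
            cf_f = (1.0 + trend.case_fatality_apc) ** tf
            bg_f = (1.0 + bg_apc[act]) ** tf
            mult = risk_pathway.multiplier_surface(
                scenario, inputs, int(years[t]), a, si,
                hazard_ratios=hazard_ratios, effect_scale=effect_scale)
            i_chd = cube["chd_incidence"][si, ei, band] * inc_f * mult["chd"]
            i_str = cube["stroke_incidence"][si, ei, band] * inc_f * mult["stroke"]
            cf_chd = cube["chd_case_fatality"][si, ei, band] * cf_f
            cf_str = cube["stroke_case_fatality"][si, ei, band] * cf_f
            bg = cube["background_mortality"][si, ei, band] * bg_f

            x = cur[act]
            R = i_chd + i_str + bg
            p_exit = -np.expm1(-R)
            w = np.divide(p_exit, R, out=np.zeros_like(R), where=R > 0)
            Rc = cf_chd + bg
            p_exit_c = -np.expm1(-Rc)
            wc = np.divide(p_exit_c, Rc, out=np.zeros_like(Rc), where=Rc > 0)
            Rs = cf_str + bg
            p_exit_s = -np.expm1(-Rs)
            ws = np.divide(p_exit_s, Rs, out=np.zeros_like(Rs), where=Rs > 0)

            h = x[:, HEALTHY]
            chd_all = x[:, CHD_Y1] + x[:, CHD_LATER]
            str_all = x[:, STROKE_Y1] + x[:, STROKE_LATER]
            new = np.empty_like(x)
            new[:, HEALTHY] = h * (1.0 - p_exit)
            new[:, CHD_Y1] = h * i_chd * w
            new[:, STROKE_Y1] = h * i_str * w
            new[:, CHD_LATER] = chd_all * (1.0 - p_exit_c)
            new[:, STROKE_LATER] = str_all * (1.0 - p_exit_s)
            new[:, DEAD_CVD] = x[:, DEAD_CVD] + chd_all * cf_chd * wc + str_all * cf_str * ws
            new[:, DEAD_OTHER] = (x[:, DEAD_OTHER] + h * bg * w
                                  + chd_all * bg * wc + str_all * bg * ws)
            cur[act] = new
        occ[t] = cur
        ages[t] = age

    return Trajectory(years=years, occ=occ, ages=ages, sex_idx=sex_idx,
                      eth_idx=eth_idx, start_age=start_age, pop=pop,
                      scenario=scenario, inputs_fingerprint=inputs.fingerprint())
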