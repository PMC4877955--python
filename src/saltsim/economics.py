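"""Discounted QALY and health-system cost accrual, and incremental results.

QALYs weight each year of state occupancy by a utility: 1 minus the
stratum's background morbidity decrement (prevalent YLD per capita),
minus the disease's disability weight in disease states; death scores 0.
Costs attach an annual health-system cost to each alive state — the
healthy-state cost is net of the CVD-attributable component to avoid
double counting — scaled up by the public-share factor (1.2) everywhere
and by old-age residential-care multipliers (1.1 / 1.2 / 1.3 at ages
65-74 / 75-84 / 85+).  Both streams are discounted at a constant annual
rate referenced to the baseline year; a scenario's one-off legislation
cost is charged once, undiscounted, at the baseline year.

Every scenario is evaluated incrementally against the "do nothing"
comparator run on identical inputs: an intervention is *dominant* when it
gains QALYs and saves costs; otherwise an incremental cost-effectiveness
ratio (ICER, NZ$ per QALY gained) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov_engine import (ALIVE, CHD_LATER, CHD_Y1, DEAD_CVD, DEAD_OTHER,
                            HEALTHY, N_STATES, STATES, STROKE_LATER, STROKE_Y1,
                            Trajectory)
from .strata import AGE_BAND_STARTS, ETHNICITIES, SEXES
from .synthetic_inputs import ModelInputs


@dataclass(frozen=True)
class DiscountSpec:
    """Constant annual discount rate referenced to the baseline year."""

    rate: float = 0.03
    reference_year: int = 2011

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"discount rate must be non-negative, got {self.rate}")


@dataclass(frozen=True)
class CostScaleups:
    """Multiplicative cost adjustments for data-coverage gaps."""

    public_share_factor: float = 1.2  # 1 / 0.83 public share of health spending
    old_age_multipliers: tuple[tuple[int, float], ...] = ((65, 1.1), (75, 1.2), (85, 1.3))

    def old_age_factor(self, age: int) -> float:
        factor = 1.0
        for threshold, mult in self.old_age_multipliers:
            if age >= threshold:
                factor = mult
        return factor


def discount_factor(year: int, spec: DiscountSpec) -> float:
    """(1 + rate) ^ -(year - reference_year); 1 in the reference year."""
    if year < spec.reference_year:
        raise ValueError(f"year {year} precedes reference {spec.reference_year}")
    return (1.0 + spec.rate) ** -(year - spec.reference_year)


def utility_weight(state: str, background_pyld: float, dw_chd: float,
                   dw_stroke: float) -> float:
    """Utility for one state: healthy 1-pYLD, disease 1-pYLD-DW, dead 0."""
    if state == "healthy":
        u = 1.0 - background_pyld
    elif state in ("chd_year1", "chd_later"):
        u = 1.0 - background_pyld - dw_chd
    elif state in ("stroke_year1", "stroke_later"):
        u = 1.0 - background_pyld - dw_stroke
    elif state in ("dead_cvd", "dead_other"):
        return 0.0
    else:
        raise ValueError(f"unknown state {state!r}")
    if u < 0:
        raise ValueError(f"negative utility for {state}: pYLD {background_pyld} "
                         f"+ DW leaves {u}")
    return u


def state_cost(state: str, sex: str, age: int, inputs: ModelInputs,
               scaleups: CostScaleups | None = None) -> float:
    """Annual health-system cost (NZ$/person-year) for one state.

    Base cost by state (healthy annual; first-year disease cost in the
    first-year tunnel states; subsequent-year cost afterwards) times the
    public-share factor and the old-age multiplier for the current age.
    """
    scaleups = scaleups or CostScaleups()
    if state in ("dead_cvd", "dead_other"):
        return 0.0
    band = min(AGE_BAND_STARTS[-1], max(AGE_BAND_STARTS[0], (age - 35) // 5 * 5 + 35))
    if state == "healthy":
        base = inputs.costs.loc[(sex, band), "healthy_annual_cost"]
    elif state == "chd_year1":
        base = inputs.disease_costs["chd"]["first_year"]
    elif state == "chd_later":
        base = inputs.disease_costs["chd"]["subsequent_year"]
    elif state == "stroke_year1":
        base = inputs.disease_costs["stroke"]["first_year"]
    elif state == "stroke_later":
        base = inputs.disease_costs["stroke"]["subsequent_year"]
    else:
        raise ValueError(f"unknown state {state!r}")
    return float(base) * scaleups.public_share_factor * scaleups.old_age_factor(age)


@dataclass
class Ledger:
    """Per-cohort, per-cycle QALY and cost accrual for one scenario run.

    ``qalys_tc`` / ``costs_tc`` are undiscounted person-weighted totals
    per (cycle, cohort); discounted analogues apply the closed-form
    factor per cycle year.  The one-off intervention cost sits only in
    the grand totals (and in population-share per-capita figures), not in
    the per-cohort matrices.
    """

    years: np.ndarray
    ages: np.ndarray           # (T, C)
    qalys_tc: np.ndarray       # (T, C) undiscounted
    costs_tc: np.ndarray       # (T, C) undiscounted, health-system only
    disc: np.ndarray           # (T,) discount factors
    sex_idx: np.ndarray
    eth_idx: np.ndarray
    start_age: np.ndarray
    pop: np.ndarray
    one_off_cost: float
    scenario_name: str
    inputs_fingerprint: str

    @property
    def qalys_tc_disc(self) -> np.ndarray:
        return self.qalys_tc * self.disc[:, None]

    @property
    def costs_tc_disc(self) -> np.ndarray:
        return self.costs_tc * self.disc[:, None]

    @property
    def total_qalys(self) -> float:
        return float(self.qalys_tc_disc.sum())

    @property
    def total_costs(self) -> float:
        """Discounted health-system costs plus the one-off intervention cost."""
        return float(self.costs_tc_disc.sum() + self.one_off_cost)

    @property
    def total_qalys_undiscounted(self) -> float:
        return float(self.qalys_tc.sum())

    @property
    def total_costs_undiscounted(self) -> float:
        return float(self.costs_tc.sum() + self.one_off_cost)


def _morbidity_arrays(inputs: ModelInputs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pyld, dw_chd, dw_stroke) as (sex, eth, band) arrays."""
    shape = (len(SEXES), len(ETHNICITIES), len(AGE_BAND_STARTS))
    pyld = np.zeros(shape)
    dwc = np.zeros(shape)
    dws = np.zeros(shape)
    morb = inputs.morbidity.sort_index()
    for si, sex in enumerate(SEXES):
        for ei, eth in enumerate(ETHNICITIES):
            block = morb.loc[(sex, eth)].reindex(AGE_BAND_STARTS)
            pyld[si, ei] = block["background_pyld"].to_numpy()
            dwc[si, ei] = block["dw_chd"].to_numpy()
            dws[si, ei] = block["dw_stroke"].to_numpy()
    return pyld, dwc, dws


def _utility_cube(pyld: np.ndarray, dw_chd: np.ndarray, dw_stroke: np.ndarray
                  ) -> np.ndarray:
    """(sex, eth, band, state) utility weights from morbidity arrays."""
    cube = np.zeros(pyld.shape + (N_STATES,))
    cube[..., HEALTHY] = 1.0 - pyld
    cube[..., CHD_Y1] = cube[..., CHD_LATER] = 1.0 - pyld - dw_chd
    cube[..., STROKE_Y1] = cube[..., STROKE_LATER] = 1.0 - pyld - dw_stroke
    if (cube[..., ALIVE] < 0).any():
        raise ValueError("background pYLD plus disability weight exceeds 1 "
                         "in some stratum (negative utility)")
    return cube


def accrue(trajectory: Trajectory, inputs: ModelInputs,
           discount: DiscountSpec | None = None,
           scaleups: CostScaleups | None = None,
           dw_overrides: dict[str, float] | None = None,
           cost_scales: dict[str, float] | None = None) -> Ledger:
    """Turn a trajectory into a discounted QALY/cost ledger.

    Full-year accrual on end-of-cycle occupancy (consistent with the
    engine's no-half-cycle convention).  ``dw_overrides`` replaces the
    central disability weights and ``cost_scales`` multiplies cost
    components ("healthy", "chd_first", ...) — both are hooks for the
    probabilistic sensitivity analysis.
    """
    discount = discount or DiscountSpec()
    scaleups = scaleups or CostScaleups()
    if trajectory.inputs_fingerprint != inputs.fingerprint():
        raise ValueError("trajectory was produced from different inputs")

    pyld, dwc, dws = inputs.cached("morbidity_arrays", lambda: _morbidity_arrays(inputs))
    if dw_overrides:
        if "chd" in dw_overrides:
            dwc = np.full_like(dwc, dw_overrides["chd"])
        if "stroke" in dw_overrides:
            dws = np.full_like(dws, dw_overrides["stroke"])
    util_cube = _utility_cube(pyld, dwc, dws)

    cs = cost_scales or {}
    costs_sorted = inputs.costs.sort_index()
    healthy_base = inputs.cached("healthy_cost_array", lambda: np.stack(
        [costs_sorted.loc[sex, "healthy_annual_cost"].reindex(AGE_BAND_STARTS).to_numpy()
         for sex in SEXES]))
    healthy_cost = healthy_base * cs.get("healthy", 1.0)
    dcost = {
        CHD_Y1: inputs.disease_costs["chd"]["first_year"] * cs.get("chd_first", 1.0),
        CHD_LATER: inputs.disease_costs["chd"]["subsequent_year"] * cs.get("chd_subsequent", 1.0),
        STROKE_Y1: inputs.disease_costs["stroke"]["first_year"] * cs.get("stroke_first", 1.0),
        STROKE_LATER: inputs.disease_costs["stroke"]["subsequent_year"] * cs.get("stroke_subsequent", 1.0),
    }

    T, C, S = trajectory.occ.shape
    band_idx = np.clip((trajectory.ages - 35) // 5, 0, len(AGE_BAND_STARTS) - 1)
    si = trajectory.sex_idx[None, :].repeat(T, axis=0)
    ei = trajectory.eth_idx[None, :].repeat(T, axis=0)

    util = util_cube[si, ei, band_idx]                     # (T, C, S)
    qalys_tc = (trajectory.occ * util).sum(axis=2) * trajectory.pop[None, :]

    oam = np.ones_like(trajectory.ages, dtype=float)
    for threshold, mult in scaleups.old_age_multipliers:
        oam[trajectory.ages >= threshold] = mult
    cost_state = np.zeros((T, C, S))
    cost_state[:, :, HEALTHY] = healthy_cost[si, band_idx]
    for s, base in dcost.items():
        cost_state[:, :, s] = base
    cost_state *= scaleups.public_share_factor * oam[:, :, None]
    cost_state[:, :, DEAD_CVD] = 0.0
    cost_state[:, :, DEAD_OTHER] = 0.0
    costs_tc = (trajectory.occ * cost_state).sum(axis=2) * trajectory.pop[None, :]

    disc = np.array([discount_factor(int(y), discount) for y in trajectory.years])
    return Ledger(
        years=trajectory.years, ages=trajectory.ages, qalys_tc=qalys_tc,
        costs_tc=costs_tc, disc=disc, sex_idx=trajectory.sex_idx,
        eth_idx=trajectory.eth_idx, start_age=trajectory.start_age,
        pop=trajectory.pop, one_off_cost=trajectory.scenario.one_off_cost,
        scenario_name=trajectory.scenario.name,
        inputs_fingerprint=trajectory.inputs_fingerprint,
    )


@dataclass
class IncrementalResult:
    """Discounted deltas of a scenario against the do-nothing comparator."""

    scenario_name: str
    delta_qalys: float
    delta_costs: float            # includes the one-off intervention cost delta
    classification: str           # "dominant" | "dominated" | "icer"
    icer: float | None            # NZ$ per QALY gained, when defined
    delta_qalys_tc: np.ndarray = field(repr=False)    # (T, C) discounted
    delta_costs_tc: np.ndarray = field(repr=False)    # (T, C) discounted, no one-off
    one_off_cost_delta: float = 0.0
    years: np.ndarray = field(default=None, repr=False)
    ages: np.ndarray = field(default=None, repr=False)
    sex_idx: np.ndarray = field(default=None, repr=False)
    eth_idx: np.ndarray = field(default=None, repr=False)
    start_age: np.ndarray = field(default=None, repr=False)
    pop: np.ndarray = field(default=None, repr=False)


def classify(delta_qalys: float, delta_costs: float) -> tuple[str, float | None]:
    """Cost-effectiveness classification from its defining inequalities.

    dominant iff more QALYs and lower costs; dominated iff fewer QALYs
    and higher costs; otherwise an ICER (reported only when both deltas
    are positive — elsewhere the ratio is not meaningful and is None).
    """
    if delta_qalys > 0 and delta_costs < 0:
        return "dominant", None
    if delta_qalys < 0 and delta_costs > 0:
        return "dominated", None
    icer = delta_costs / delta_qalys if delta_qalys > 0 and delta_costs > 0 else None
    return "icer", icer


def incremental(scenario_ledger: Ledger, comparator_ledger: Ledger) -> IncrementalResult:
    """Incremental result of a scenario versus the do-nothing comparator."""
    if scenario_ledger.inputs_fingerprint != comparator_ledger.inputs_fingerprint:
        raise ValueError("ledgers come from different model inputs")
    dq = scenario_ledger.total_qalys - comparator_ledger.total_qalys
    dc = scenario_ledger.total_costs - comparator_ledger.total_costs
    cls, icer = classify(dq, dc)
    return IncrementalResult(
        scenario_name=scenario_ledger.scenario_name,
        delta_qalys=dq, delta_costs=dc, classification=cls, icer=icer,
        delta_qalys_tc=scenario_ledger.qalys_tc_disc - comparator_ledger.qalys_tc_disc,
        delta_costs_tc=scenario_ledger.costs_tc_disc - comparator_ledger.costs_tc_disc,
        one_off_cost_delta=scenario_ledger.one_off_cost - comparator_ledger.one_off_cost,
        years=scenario_ledger.years, ages=scenario_ledger.ages,
        sex_idx=scenario_ledger.sex_idx, eth_idx=scenario_ledger.eth_idx,
        start_age=scenario_ledger.start_age, pop=scenario_ledger.pop,
    )


def per_capita(result: IncrementalResult, cohort_mask: np.ndarray | None = None
               ) -> tuple[float, float]:
    """Per-adult (QALYs gained, net cost NZ$) for a cohort subgroup.

    The subgroup's health-system cost delta is combined with its
    population share of the one-off intervention cost, then divided by
    the subgroup's 2011 population.
    """
    if cohort_mask is None:
        cohort_mask = np.ones_like(result.pop, dtype=bool)
    group_pop = float(result.pop[cohort_mask].sum())
    if group_pop <= 0:
        raise ValueError("per-capita group selects no population")
    total_pop = float(result.pop.sum())
    dq = float(result.delta_qalys_tc[:, cohort_mask].sum())
    dc = float(result.delta_costs_tc[:, cohort_mask].sum()
               + result.one_off_cost_delta * group_pop / total_pop)
    return dq / group_pop, dc / group_pop
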