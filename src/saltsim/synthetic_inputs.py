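"""Synthetic model inputs: generation, validation and on-disk round-trip.

The real study inputs are per-stratum epidemiological surfaces (CHD and
stroke incidence, case fatality, prevalence; background non-CVD mortality)
and health-system cost schedules derived from linked administrative data
that is not public.  This module generates a parameter set with the same
statistical structure — Gompertz-like age gradients (log-rate linear in
age), higher rates for Maori than non-Maori and for men than women, and
cost schedules pinned exactly to the published worked anchor values — so
that every downstream stage of the simulator is testable without any
external data.

Anchors reproduced exactly at their stated stratum (a 60-year-old woman,
before cost scale-ups): healthy-state annual cost NZ$2381; CHD first /
subsequent year NZ$16,258 / NZ$5,395; stroke NZ$20,553 / NZ$5,991.
Baseline sodium intakes: 4013 mg/d (men), 3115 mg/d (women), 3544 mg/d
(average adult).  All rates are annual; all costs are 2011 NZ$.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import AGE_BAND_STARTS, ETHNICITIES, SEXES, StratumKey, all_strata

logger = logging.getLogger(__name__)

STRATUM_COLS = ["sex", "ethnicity", "age_band"]

# Default systolic-BP response (mmHg per 100 mmol/day sodium change) by
# decade of age; the published regression-derived table ends at 60-69 and
# the oldest value is carried forward to 70+.
DEFAULT_BP_RESPONSE: dict[int, float] = {30: 5.5, 40: 6.6, 50: 9.2, 60: 10.3}

# Hazard-ratio ranges (per 20 mmHg systolic BP reduction) by disease; the
# most protective value applies at the youngest ages, attenuating with age.
HR_RANGE = {"chd": (0.49, 0.67), "stroke": (0.38, 0.67)}


class InputValidationError(ValueError):
    """Raised when a parameter set violates a structural invariant."""


@dataclass(frozen=True)
class TrendSpec:
    """Background secular trends as annual percentage changes (fractions).

    Trends apply from ``baseline_year`` to ``trend_end_year`` and are zero
    afterwards (rates frozen).
    """

    incidence_apc: float = -0.020
    case_fatality_apc: float = -0.020
    background_mortality_apc_non_maori: float = -0.0175
    background_mortality_apc_maori: float = -0.0225
    trend_end_year: int = 2026
    baseline_year: int = 2011


@dataclass(frozen=True)
class SodiumBaseline:
    """Baseline daily sodium intake (mg/day) and dietary source shares."""

    intake_male: float = 4013.0
    intake_female: float = 3115.0
    intake_average_adult: float = 3544.0
    share_processed_food: float = 0.72
    share_table_salt: float = 0.15
    share_other: float = 0.13
    share_bread: float = 0.206  # of total intake; subset of processed food

    def intake_for(self, sex: str) -> float:
        if sex == "male":
            return self.intake_male
        if sex == "female":
            return self.intake_female
        if sex == "average":
            return self.intake_average_adult
        raise ValueError(f"unknown sex {sex!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Anchor values and gradient strengths for the synthetic generator.

    Rate curves are log-linear in age: rate(age) = level_at_60 *
    exp(slope * (age - 60)) for the non-Maori female reference, scaled by
    multiplicative Maori and male ratios.  Small seed-controlled lognormal
    perturbations are applied to levels, slopes and ratios so distinct
    seeds give distinct surfaces while every structural invariant
    (age-monotonicity, Maori >= non-Maori) holds by construction.
    """

    total_population: float = 2_300_000.0
    # reference (non-Maori female) annual rates at age 60 and log-slopes
    chd_incidence_at60: float = 0.0030
    chd_incidence_slope: float = 0.070
    stroke_incidence_at60: float = 0.0020
    stroke_incidence_slope: float = 0.085
    chd_case_fatality_at60: float = 0.030
    chd_case_fatality_slope: float = 0.040
    stroke_case_fatality_at60: float = 0.050
    stroke_case_fatality_slope: float = 0.045
    background_mortality_at60: float = 0.0040
    background_mortality_slope: float = 0.095
    # ethnic and sex rate ratios (multiplicative)
    maori_ratio_chd: float = 2.0
    maori_ratio_stroke: float = 1.8
    maori_ratio_case_fatality: float = 1.5
    maori_ratio_background_mortality: float = 1.6
    min_maori_incidence_ratio: float = 1.5
    male_ratio_chd: float = 1.8
    male_ratio_stroke: float = 1.25
    male_ratio_case_fatality: float = 1.1
    male_ratio_background_mortality: float = 1.2
    # prevalence approximated as incidence x mean duration, capped
    chd_prevalence_duration: float = 7.0
    chd_prevalence_cap: float = 0.30
    stroke_prevalence_duration: float = 5.0
    stroke_prevalence_cap: float = 0.20
    # morbidity
    background_pyld_at35: float = 0.030
    background_pyld_per_year: float = 0.0032
    maori_pyld_ratio: float = 1.15
    dw_chd: float = 0.081
    dw_chd_lo: float = 0.05
    dw_chd_hi: float = 0.11
    dw_stroke: float = 0.226
    dw_stroke_lo: float = 0.11
    dw_stroke_hi: float = 0.23
    # cost anchors (2011 NZ$, before public-share and old-age scale-ups)
    healthy_cost_anchor: float = 2381.0  # female, 60-64 band
    healthy_cost_age_slope: float = 0.022  # log-cost per year of band start
    healthy_cost_male_ratio: float = 0.92
    chd_first_year_cost: float = 16_258.0
    chd_subsequent_year_cost: float = 5_395.0
    stroke_first_year_cost: float = 20_553.0
    stroke_subsequent_year_cost: float = 5_991.0
    # perturbation scales (SD of lognormal noise)
    level_noise_sd: float = 0.05
    slope_noise_sd: float = 0.03
    ratio_noise_sd: float = 0.03
    population_noise_sd: float = 0.01
    sodium: SodiumBaseline = field(default_factory=SodiumBaseline)
    trend: TrendSpec = field(default_factory=TrendSpec)

    def validate(self) -> None:
        checks = [
            ("chd_subsequent_year_cost", self.chd_subsequent_year_cost < self.chd_first_year_cost,
             "subsequent-year CHD cost must be below first-year cost"),
            ("stroke_subsequent_year_cost", self.stroke_subsequent_year_cost < self.stroke_first_year_cost,
             "subsequent-year stroke cost must be below first-year cost"),
            ("dw_chd", 0 <= self.dw_chd < 1, "disability weight must be in [0, 1)"),
            ("dw_stroke", 0 <= self.dw_stroke < 1, "disability weight must be in [0, 1)"),
            ("healthy_cost_anchor", self.healthy_cost_anchor >= 0, "costs must be non-negative"),
            ("total_population", self.total_population > 0, "population must be positive"),
        ]
        share_sum = (self.sodium.share_processed_food + self.sodium.share_table_salt
                     + self.sodium.share_other)
        checks.append(("sodium.shares", abs(share_sum - 1.0) < 1e-9,
                       "sodium source shares must sum to 1"))
        checks.append(("sodium.share_bread",
                       self.sodium.share_bread <= self.sodium.share_processed_food,
                       "bread share cannot exceed processed-food share"))
        for name, ok, msg in checks:
            if not ok:
                raise InputValidationError(f"{name}: {msg}")


def default_hazard_ratios() -> pd.DataFrame:
    """Hazard ratios per 20 mmHg systolic-BP reduction, by age band.

    Log-linearly interpolated between the most protective value at the
    youngest bands (up to 40-44) and the least protective (0.67) from 85+,
    so every value lies inside the published range and attenuates with age.
    """
    rows = {}
    for band in AGE_BAND_STARTS:
        row = {}
        for disease, (lo, hi) in HR_RANGE.items():
            if band <= 40:
                hr = lo
            elif band >= 85:
                hr = hi
            else:
                frac = (band - 40) / (85 - 40)
                hr = float(np.exp(np.log(lo) + frac * (np.log(hi) - np.log(lo))))
            row[disease] = hr
        rows[band] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "age_band"
    return df


@dataclass
class ModelInputs:
    """The complete parameter set consumed by the simulator.

    population : DataFrame indexed by (sex, ethnicity, age_band), column
        ``count`` (persons).
    epi : DataFrame with the same index; columns ``chd_incidence``,
        ``stroke_incidence``, ``chd_case_fatality``,
        ``stroke_case_fatality``, ``chd_prevalence``,
        ``stroke_prevalence``, ``background_mortality`` (all annual).
    morbidity : DataFrame with the same index; ``background_pyld`` and
        central disability weights with 95% bounds.
    costs : DataFrame indexed by (sex, age_band); ``healthy_annual_cost``.
    disease_costs : first/subsequent-year annual costs per disease.
    bp_response : mmHg per 100 mmol/day sodium, keyed by decade of age.
    hazard_ratios : per age band and disease, HR per 20 mmHg reduction.
    """

    population: pd.DataFrame
    epi: pd.DataFrame
    morbidity: pd.DataFrame
    costs: pd.DataFrame
    disease_costs: dict
    trend: TrendSpec
    sodium: SodiumBaseline
    bp_response: dict
    hazard_ratios: pd.DataFrame
    generator_seed: int | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelInputs):
            return NotImplemented
        return (
            self.population.equals(other.population)
            and self.epi.equals(other.epi)
            and self.morbidity.equals(other.morbidity)
            and self.costs.equals(other.costs)
            and self.disease_costs == other.disease_costs
            and self.trend == other.trend
            and self.sodium == other.sodium
            and self.bp_response == other.bp_response
            and self.hazard_ratios.equals(other.hazard_ratios)
            and self.generator_seed == other.generator_seed
        )

    def fingerprint(self) -> str:
        """Stable content hash used to guard incremental comparisons.

        Cached on first call; inputs are treated as immutable once built.
        """
        cached = self.__dict__.get("_fingerprint")
        if cached is not None:
            return cached
        h = hashlib.sha256()
        for frame in (self.population, self.epi, self.morbidity, self.costs,
                      self.hazard_ratios):
            h.update(frame.round(12).to_csv().encode())
        h.update(json.dumps(self.disease_costs, sort_keys=True).encode())
        h.update(json.dumps(dataclasses.asdict(self.trend), sort_keys=True).encode())
        h.update(json.dumps(dataclasses.asdict(self.sodium), sort_keys=True).encode())
        h.update(json.dumps({str(k): v for k, v in self.bp_response.items()},
                            sort_keys=True).encode())
        digest = h.hexdigest()
        self.__dict__["_fingerprint"] = digest
        return digest

    def cached(self, key: str, build):
        """Memoise derived arrays on the (immutable) inputs object."""
        store = self.__dict__.setdefault("_derived_cache", {})
        if key not in store:
            store[key] = build()
        return store[key]


def _stratum_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [(s.sex, s.ethnicity, s.age_band) for s in all_strata()], names=STRATUM_COLS
    )


def _rate_surface(rng: np.random.Generator, cfg: GeneratorConfig, *, level: float,
                  slope: float, maori_ratio: float, male_ratio: float,
                  floor_maori_ratio: float = 1.0) -> pd.Series:
    """One age x sex x ethnicity rate surface with seeded perturbations.

    Noise enters through the curve parameters only, so age-monotonicity
    (positive slope) and the Maori >= non-Maori ordering are preserved for
    every seed.
    """
    lvl = level * float(np.exp(rng.normal(0.0, cfg.level_noise_sd)))
    slp = slope * float(np.exp(rng.normal(0.0, cfg.slope_noise_sd)))
    m_ratio = max(floor_maori_ratio, maori_ratio * float(np.exp(rng.normal(0.0, cfg.ratio_noise_sd))))
    s_ratio = max(1.0, male_ratio * float(np.exp(rng.normal(0.0, cfg.ratio_noise_sd))))
    values = {}
    for sex in SEXES:
        for eth in ETHNICITIES:
            for band in AGE_BAND_STARTS:
                mid_age = band + 2  # band midpoint
                rate = lvl * np.exp(slp * (mid_age - 60))
                if eth == "maori":
                    rate *= m_ratio
                if sex == "male":
                    rate *= s_ratio
                values[(sex, eth, band)] = rate
    return pd.Series(values).reindex(_stratum_index())


def generate_inputs(seed: int, config: GeneratorConfig | None = None) -> ModelInputs:
    """Generate a complete, valid parameter set from ``(seed, config)``.

    Pure function of its arguments: identical inputs give identical
    output.  Anchor values (costs, disability weights, sodium intakes) are
    reproduced exactly; only the population counts and epidemiological
    rate surfaces carry seed-controlled perturbations.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    idx = _stratum_index()

    # --- population: exponential age decay, Maori younger and ~10% share
    weights = {}
    for sex in SEXES:
        for eth in ETHNICITIES:
            for band in AGE_BAND_STARTS:
                if eth == "non_maori":
                    w = np.exp(-0.045 * (band - 35))
                else:
                    w = 0.13 * np.exp(-0.085 * (band - 35))
                female_frac = min(0.65, 0.50 + 0.004 * (band - 35))
                w *= female_frac if sex == "female" else (1 - female_frac)
                weights[(sex, eth, band)] = w
    wser = pd.Series(weights).reindex(idx)
    noise = np.exp(rng.normal(0.0, cfg.population_noise_sd, size=len(wser)))
    counts = wser * noise
    counts = counts / counts.sum() * cfg.total_population
    population = pd.DataFrame({"count": counts}, index=idx)

    # --- epidemiological rate surfaces
    chd_inc = _rate_surface(rng, cfg, level=cfg.chd_incidence_at60,
                            slope=cfg.chd_incidence_slope,
                            maori_ratio=cfg.maori_ratio_chd,
                            male_ratio=cfg.male_ratio_chd,
                            floor_maori_ratio=cfg.min_maori_incidence_ratio)
    stroke_inc = _rate_surface(rng, cfg, level=cfg.stroke_incidence_at60,
                               slope=cfg.stroke_incidence_slope,
                               maori_ratio=cfg.maori_ratio_stroke,
                               male_ratio=cfg.male_ratio_stroke,
                               floor_maori_ratio=cfg.min_maori_incidence_ratio)
    chd_cf = _rate_surface(rng, cfg, level=cfg.chd_case_fatality_at60,
                           slope=cfg.chd_case_fatality_slope,
                           maori_ratio=cfg.maori_ratio_case_fatality,
                           male_ratio=cfg.male_ratio_case_fatality)
    stroke_cf = _rate_surface(rng, cfg, level=cfg.stroke_case_fatality_at60,
                              slope=cfg.stroke_case_fatality_slope,
                              maori_ratio=cfg.maori_ratio_case_fatality,
                              male_ratio=cfg.male_ratio_case_fatality)
    bg_mort = _rate_surface(rng, cfg, level=cfg.background_mortality_at60,
                            slope=cfg.background_mortality_slope,
                            maori_ratio=cfg.maori_ratio_background_mortality,
                            male_ratio=cfg.male_ratio_background_mortality)
    epi = pd.DataFrame({
        "chd_incidence": chd_inc,
        "stroke_incidence": stroke_inc,
        "chd_case_fatality": chd_cf,
        "stroke_case_fatality": stroke_cf,
        "chd_prevalence": (chd_inc * cfg.chd_prevalence_duration).clip(upper=cfg.chd_prevalence_cap),
        "stroke_prevalence": (stroke_inc * cfg.stroke_prevalence_duration).clip(upper=cfg.stroke_prevalence_cap),
        "background_mortality": bg_mort,
    }, index=idx)

    # --- morbidity (deterministic; anchors are published central values)
    pyld = {}
    for sex in SEXES:
        for eth in ETHNICITIES:
            for band in AGE_BAND_STARTS:
                v = cfg.background_pyld_at35 + cfg.background_pyld_per_year * (band + 2 - 35)
                if eth == "maori":
                    v *= cfg.maori_pyld_ratio
                pyld[(sex, eth, band)] = v
    morbidity = pd.DataFrame({
        "background_pyld": pd.Series(pyld).reindex(idx),
        "dw_chd": cfg.dw_chd,
        "dw_chd_lo": cfg.dw_chd_lo,
        "dw_chd_hi": cfg.dw_chd_hi,
        "dw_stroke": cfg.dw_stroke,
        "dw_stroke_lo": cfg.dw_stroke_lo,
        "dw_stroke_hi": cfg.dw_stroke_hi,
    }, index=idx)

    # --- healthy-state costs per sex x age band, anchored exactly at the
    # female 60-64 cell (costs carry no seed noise so anchors stay exact)
    cost_idx = pd.MultiIndex.from_product([SEXES, AGE_BAND_STARTS], names=["sex", "age_band"])
    healthy = {}
    for sex in SEXES:
        for band in AGE_BAND_STARTS:
            c = cfg.healthy_cost_anchor * np.exp(cfg.healthy_cost_age_slope * (band - 60))
            if sex == "male":
                c *= cfg.healthy_cost_male_ratio
            healthy[(sex, band)] = c
    healthy[("female", 60)] = cfg.healthy_cost_anchor  # exact anchor
    costs = pd.DataFrame({"healthy_annual_cost": pd.Series(healthy).reindex(cost_idx)},
                         index=cost_idx)

    disease_costs = {
        "chd": {"first_year": cfg.chd_first_year_cost,
                "subsequent_year": cfg.chd_subsequent_year_cost},
        "stroke": {"first_year": cfg.stroke_first_year_cost,
                   "subsequent_year": cfg.stroke_subsequent_year_cost},
    }

    return ModelInputs(
        population=population,
        epi=epi,
        morbidity=morbidity,
        costs=costs,
        disease_costs=disease_costs,
        trend=cfg.trend,
        sodium=cfg.sodium,
        bp_response=dict(DEFAULT_BP_RESPONSE),
        hazard_ratios=default_hazard_ratios(),
        generator_seed=seed,
    )


# ---------------------------------------------------------------------------
# validation


def validate_inputs(inputs: ModelInputs) -> list[str]:
    """Check every structural invariant; return violations (empty if valid).

    Total function: never raises, each violation names the table, stratum
    and field concerned.
    """
    v: list[str] = []
    idx = _stratum_index()

    if not inputs.population.index.equals(idx):
        missing = idx.difference(inputs.population.index)
        for key in missing:
            v.append(f"population: missing stratum {key}")
    for key, count in inputs.population["count"].items():
        if not count > 0:
            v.append(f"population: stratum {key} count must be > 0 (got {count})")

    if not inputs.epi.index.equals(idx):
        for key in idx.difference(inputs.epi.index):
            v.append(f"epi: missing stratum {key}")
    else:
        for col in inputs.epi.columns:
            neg = inputs.epi[col] < 0
            for key in inputs.epi.index[neg]:
                v.append(f"epi: {col} at stratum {key} is negative")
        for col in ("chd_prevalence", "stroke_prevalence"):
            bad = ~((inputs.epi[col] >= 0) & (inputs.epi[col] < 1))
            for key in inputs.epi.index[bad]:
                v.append(f"epi: {col} at stratum {key} outside [0, 1)")
        # age-monotonicity of incidence and background mortality
        epi_sorted = inputs.epi.sort_index()
        for col in ("chd_incidence", "stroke_incidence", "background_mortality"):
            for sex in SEXES:
                for eth in ETHNICITIES:
                    series = epi_sorted.loc[(sex, eth), col]
                    diffs = series.diff().dropna()
                    for band, d in diffs.items():
                        if d < -1e-12:
                            v.append(
                                f"epi: {col} decreases with age at ({sex}, {eth}, {band})")
        # Maori >= non-Maori at every age
        for col in ("chd_incidence", "stroke_incidence", "background_mortality"):
            for sex in SEXES:
                maori = epi_sorted.loc[(sex, "maori"), col]
                nonm = epi_sorted.loc[(sex, "non_maori"), col]
                for band in AGE_BAND_STARTS:
                    if maori[band] < nonm[band] - 1e-12:
                        v.append(
                            f"epi: {col} for maori below non_maori at ({sex}, {band})")

    for key, row in inputs.morbidity.iterrows():
        for dw_col in ("dw_chd", "dw_stroke"):
            if not (0 <= row[dw_col] < 1):
                v.append(f"morbidity: {dw_col} at stratum {key} outside [0, 1)")
        if row["background_pyld"] + max(row["dw_chd"], row["dw_stroke"]) >= 1:
            v.append(f"morbidity: background_pyld + max(dw) >= 1 at stratum {key}")
        if not (0 <= row["background_pyld"] < 1):
            v.append(f"morbidity: background_pyld at stratum {key} outside [0, 1)")

    for key, c in inputs.costs["healthy_annual_cost"].items():
        if c < 0:
            v.append(f"costs: healthy_annual_cost at {key} is negative")
    for disease, dc in inputs.disease_costs.items():
        if dc["first_year"] < 0 or dc["subsequent_year"] < 0:
            v.append(f"costs: {disease} cost is negative")
        if not dc["first_year"] > dc["subsequent_year"]:
            v.append(f"costs: {disease} first_year cost must exceed subsequent_year cost")

    share_sum = (inputs.sodium.share_processed_food + inputs.sodium.share_table_salt
                 + inputs.sodium.share_other)
    if abs(share_sum - 1.0) > 1e-9:
        v.append("sodium: source shares do not sum to 1")
    if inputs.sodium.share_bread > inputs.sodium.share_processed_food:
        v.append("sodium: bread share exceeds processed-food share")

    bp_items = sorted(inputs.bp_response.items())
    for (a1, v1), (a2, v2) in zip(bp_items, bp_items[1:]):
        if v2 < v1:
            v.append(f"bp_response: value at decade {a2} below decade {a1}")
    for a, val in bp_items:
        if val <= 0:
            v.append(f"bp_response: non-positive value at decade {a}")

    for disease, (lo, hi) in HR_RANGE.items():
        series = inputs.hazard_ratios[disease]
        for band, hr in series.items():
            if not (lo - 1e-12 <= hr <= hi + 1e-12):
                v.append(f"hazard_ratios: {disease} at band {band} outside [{lo}, {hi}]")
        if (series.diff().dropna() < -1e-12).any():
            v.append(f"hazard_ratios: {disease} not non-decreasing in age")

    return v


# ---------------------------------------------------------------------------
# on-disk format: long CSV for per-stratum tables + JSON header for scalars

CSV_NAME = "inputs.csv"
JSON_NAME = "inputs.json"
_CSV_COLUMNS = ["sex", "ethnicity", "age_band", "quantity", "disease", "value"]

_EPI_QUANTITIES = {
    ("incidence", "chd"): "chd_incidence",
    ("incidence", "stroke"): "stroke_incidence",
    ("case_fatality", "chd"): "chd_case_fatality",
    ("case_fatality", "stroke"): "stroke_case_fatality",
    ("prevalence", "chd"): "chd_prevalence",
    ("prevalence", "stroke"): "stroke_prevalence",
}
_MORB_QUANTITIES = {
    ("dw", "chd"): "dw_chd", ("dw_lo", "chd"): "dw_chd_lo", ("dw_hi", "chd"): "dw_chd_hi",
    ("dw", "stroke"): "dw_stroke", ("dw_lo", "stroke"): "dw_stroke_lo",
    ("dw_hi", "stroke"): "dw_stroke_hi",
}


def write_inputs(inputs: ModelInputs, path: str | os.PathLike) -> None:
    """Write ``inputs.csv`` (long format) and ``inputs.json`` under ``path``."""
    os.makedirs(path, exist_ok=True)
    rows = []
    for (sex, eth, band), count in inputs.population["count"].items():
        rows.append((sex, eth, band, "population", "", count))
    for (quantity, disease), col in _EPI_QUANTITIES.items():
        for (sex, eth, band), val in inputs.epi[col].items():
            rows.append((sex, eth, band, quantity, disease, val))
    for (sex, eth, band), val in inputs.epi["background_mortality"].items():
        rows.append((sex, eth, band, "background_mortality", "", val))
    for (sex, eth, band), val in inputs.morbidity["background_pyld"].items():
        rows.append((sex, eth, band, "background_pyld", "", val))
    for (quantity, disease), col in _MORB_QUANTITIES.items():
        for (sex, eth, band), val in inputs.morbidity[col].items():
            rows.append((sex, eth, band, quantity, disease, val))
    for (sex, band), val in inputs.costs["healthy_annual_cost"].items():
        rows.append((sex, "all", band, "healthy_annual_cost", "", val))
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    # repr gives the shortest digit string that round-trips binary64 exactly
    frame.to_csv(os.path.join(path, CSV_NAME), index=False,
                 float_format=lambda v: repr(float(v)))

    header = {
        "trend": dataclasses.asdict(inputs.trend),
        "sodium": dataclasses.asdict(inputs.sodium),
        "disease_costs": inputs.disease_costs,
        "bp_response": {str(k): v for k, v in inputs.bp_response.items()},
        "hazard_ratios": {str(band): {"chd": row["chd"], "stroke": row["stroke"]}
                          for band, row in inputs.hazard_ratios.iterrows()},
        "generator_seed": inputs.generator_seed,
    }
    with open(os.path.join(path, JSON_NAME), "w") as fh:
        json.dump(header, fh, indent=1)


def read_inputs(path: str | os.PathLike) -> ModelInputs:
    """Read a parameter set written by :func:`write_inputs`.

    Unknown CSV columns are tolerated with a logged warning; a missing
    stratum raises a parse error naming the stratum.
    """
    csv_path = os.path.join(path, CSV_NAME)
    json_path = os.path.join(path, JSON_NAME)
    frame = pd.read_csv(csv_path, keep_default_na=False, float_precision="round_trip",
                        dtype={"sex": str, "ethnicity": str, "quantity": str, "disease": str})
    extra = [c for c in frame.columns if c not in _CSV_COLUMNS]
    if extra:
        logger.warning("ignoring unknown columns in %s: %s", csv_path, extra)
        frame = frame.drop(columns=extra)
    missing_cols = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise InputValidationError(f"{csv_path}: missing required columns {missing_cols}")
    frame["age_band"] = frame["age_band"].astype(int)
    frame["value"] = frame["value"].astype(float)

    idx = _stratum_index()

    def stratum_series(quantity: str, disease: str = "") -> pd.Series:
        sel = frame[(frame["quantity"] == quantity) & (frame["disease"] == disease)]
        ser = sel.set_index(STRATUM_COLS)["value"]
        ser = ser[~ser.index.duplicated()]
        missing = idx.difference(ser.index)
        if len(missing):
            key = tuple(missing[0])
            raise InputValidationError(
                f"{csv_path}: quantity {quantity!r} (disease={disease!r}) "
                f"missing stratum {StratumKey(*key)}")
        return ser.reindex(idx)

    population = pd.DataFrame({"count": stratum_series("population")}, index=idx)
    epi = pd.DataFrame(
        {col: stratum_series(q, d) for (q, d), col in _EPI_QUANTITIES.items()}
        | {"background_mortality": stratum_series("background_mortality")}, index=idx)
    epi = epi[["chd_incidence", "stroke_incidence", "chd_case_fatality",
               "stroke_case_fatality", "chd_prevalence", "stroke_prevalence",
               "background_mortality"]]
    morbidity = pd.DataFrame(
        {"background_pyld": stratum_series("background_pyld")}
        | {col: stratum_series(q, d) for (q, d), col in _MORB_QUANTITIES.items()}, index=idx)
    morbidity = morbidity[["background_pyld", "dw_chd", "dw_chd_lo", "dw_chd_hi",
                           "dw_stroke", "dw_stroke_lo", "dw_stroke_hi"]]

    cost_sel = frame[frame["quantity"] == "healthy_annual_cost"]
    cost_idx = pd.MultiIndex.from_product([SEXES, AGE_BAND_STARTS], names=["sex", "age_band"])
    cost_ser = cost_sel.set_index(["sex", "age_band"])["value"]
    missing = cost_idx.difference(cost_ser.index)
    if len(missing):
        raise InputValidationError(
            f"{csv_path}: healthy_annual_cost missing cell {tuple(missing[0])}")
    costs = pd.DataFrame({"healthy_annual_cost": cost_ser.reindex(cost_idx)}, index=cost_idx)

    with open(json_path) as fh:
        header = json.load(fh)
    try:
        trend = TrendSpec(**header["trend"])
        sodium = SodiumBaseline(**header["sodium"])
        disease_costs = header["disease_costs"]
        bp_response = {int(k): float(v) for k, v in header["bp_response"].items()}
        hr = pd.DataFrame.from_dict(
            {int(k): v for k, v in header["hazard_ratios"].items()}, orient="index")
        hr = hr.sort_index()[["chd", "stroke"]]
        hr.index.name = "age_band"
    except (KeyError, TypeError) as exc:
        raise InputValidationError(f"{json_path}: malformed header ({exc})") from exc

    return ModelInputs(
        population=population, epi=epi, morbidity=morbidity, costs=costs,
        disease_costs=disease_costs, trend=trend, sodium=sodium,
        bp_response=bp_response, hazard_ratios=hr,
        generator_seed=header.get("generator_seed"),
    )
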