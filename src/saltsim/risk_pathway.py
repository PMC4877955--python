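"""Sodium -> systolic blood pressure -> CVD incidence risk chain.

A daily sodium reduction (mmol/day) maps linearly to an age-specific
systolic-BP reduction (mmHg per 100 mmol/day, from published regression
models), which scales CHD and stroke incidence multiplicatively through a
log-linear BP-risk relation: multiplier = HR_20 ^ (delta_sBP / 20), where
HR_20 is the hazard ratio for a 20 mmHg systolic-BP reduction.

Effects apply to incidence among the healthy state only — the modelled
chain links blood pressure to first-event probability, not to case
fatality, background mortality or recurrence among prevalent cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import interventions as iv
from .strata import band_for_age
from .synthetic_inputs import DEFAULT_BP_RESPONSE, ModelInputs, default_hazard_ratios

DISEASES = ("chd", "stroke")


def bp_reduction(mmol_reduction: float, age: int,
                 bp_response: dict[int, float] | None = None) -> float:
    """Systolic-BP reduction (mmHg) for a sodium dose at a given age.

    Linear in dose: (mmol / 100) x tabulated mmHg-per-100-mmol value for
    the person's decade of age.  The table's youngest row (30-39) covers
    ages 35-39 and its oldest tabulated value is carried forward to 70+.
    """
    if mmol_reduction < 0:
        raise ValueError(f"sodium reduction must be non-negative, got {mmol_reduction}")
    table = bp_response or DEFAULT_BP_RESPONSE
    decade = int(age) // 10 * 10
    decade = min(max(decade, min(table)), max(table))
    return mmol_reduction / 100.0 * table[decade]


def rate_multiplier(delta_sbp: float, hr_per_20mmHg: float) -> float:
    """Incidence multiplier for a systolic-BP reduction of ``delta_sbp``.

    Equals 1 at zero dose and decreases strictly with dose (for HR < 1):
    HR ^ (delta_sbp / 20).
    """
    if delta_sbp < 0:
        raise ValueError(f"BP reduction must be non-negative, got {delta_sbp}")
    return float(hr_per_20mmHg ** (delta_sbp / 20.0))


def incidence_multiplier(spec: iv.InterventionSpec, sex: str, age: int, year: int,
                         disease: str, inputs: ModelInputs | None = None) -> float:
    """Compose the full chain for one person-type: dose -> BP -> multiplier."""
    sodium = inputs.sodium if inputs is not None else None
    bp_table = inputs.bp_response if inputs is not None else None
    hr_table = inputs.hazard_ratios if inputs is not None else default_hazard_ratios()
    baseline_year = inputs.trend.baseline_year if inputs is not None else iv.BASELINE_YEAR
    mg = iv.sodium_reduction_mg(spec, sex, year, sodium, baseline_year)
    dsbp = bp_reduction(iv.mg_to_mmol(mg), age, bp_table)
    hr = float(hr_table.loc[band_for_age(age), disease])
    return rate_multiplier(dsbp, hr)


def incidence_multipliers(spec: iv.InterventionSpec, sex: str, year: int,
                          inputs: ModelInputs) -> pd.DataFrame:
    """Per-age-band CHD and stroke incidence multipliers for one sex/year."""
    hr = inputs.hazard_ratios
    rows = {band: {d: incidence_multiplier(spec, sex, band + 2, year, d, inputs)
                   for d in DISEASES}
            for band in hr.index}
    out = pd.DataFrame.from_dict(rows, orient="index")[list(DISEASES)]
    out.index.name = "age_band"
    return out


def multiplier_surface(spec: iv.InterventionSpec, inputs: ModelInputs, year: int,
                       ages: np.ndarray, sexes: np.ndarray,
                       hazard_ratios: pd.DataFrame | None = None,
                       effect_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Vectorised multipliers for cohort arrays (used by the engine).

    ``ages`` and ``sexes`` are parallel arrays (sex index 0=male,
    1=female).  ``effect_scale`` perturbs the intervention effect size
    (probabilistic sensitivity analysis); ``hazard_ratios`` overrides the
    input table.  A zero-dose scenario returns exact ones.
    """
    hr_table = hazard_ratios if hazard_ratios is not None else inputs.hazard_ratios
    baseline_year = inputs.trend.baseline_year
    phase = iv.phase_in_fraction(spec, year, baseline_year)
    dose_frac = spec.reduction_fraction * effect_scale * phase
    mg = np.where(sexes == 0,
                  min(dose_frac, 1.0) * inputs.sodium.intake_male,
                  min(dose_frac, 1.0) * inputs.sodium.intake_female)
    mmol = mg / iv.SODIUM_MG_PER_MMOL

    bp_table = inputs.bp_response
    decades = np.clip(ages // 10 * 10, min(bp_table), max(bp_table))
    bp_per_100 = np.array([bp_table[int(d)] for d in decades])
    dsbp = mmol / 100.0 * bp_per_100

    band_idx = np.clip((ages - 35) // 5, 0, len(hr_table.index) - 1).astype(int)
    out = {}
    for disease in DISEASES:
        hr = hr_table[disease].to_numpy()[band_idx]
        out[disease] = hr ** (dsbp / 20.0)
    return out
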