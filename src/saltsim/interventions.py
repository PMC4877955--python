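"""Sodium-reduction intervention scenarios and their dose arithmetic.

Four built-in interventions are modelled against a "do nothing"
comparator: legally mandated salt substitution in processed foods and
table salt at the 59% and 25% levels, and maximum sodium limits in
commercial bread of 280 and 400 mg/100 g.  Each scenario is summarised by
the fraction of total daily sodium intake removed at full implementation
(for the average adult), a phase-in period of equal annual steps, and a
one-off legislation cost.

The average-adult reduction fraction is rescaled to each sex by the ratio
of that sex's baseline intake to the average-adult intake, which reduces
to: reduction(sex) = reduction_fraction x baseline intake(sex).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .synthetic_inputs import SodiumBaseline

SODIUM_MG_PER_MMOL = 23.0
BASELINE_YEAR = 2011
DEFAULT_LAW_COST = 3_680_000.0  # NZ$ 2011, average cost of a new act


@dataclass(frozen=True)
class InterventionSpec:
    """A sodium-reduction scenario.

    reduction_fraction is the fraction of total daily sodium removed at
    full implementation for the average adult; phase-in proceeds in
    ``phase_in_years`` equal annual steps beginning in the baseline year.
    """

    name: str
    reduction_fraction: float
    phase_in_years: int = 5
    one_off_cost: float = DEFAULT_LAW_COST
    cost_year: int = BASELINE_YEAR

    def __post_init__(self) -> None:
        if not 0 <= self.reduction_fraction < 1:
            raise ValueError(
                f"{self.name}: reduction_fraction must be in [0, 1), "
                f"got {self.reduction_fraction}")
        if self.phase_in_years < 1:
            raise ValueError(f"{self.name}: phase_in_years must be >= 1")

    @classmethod
    def from_bread_limit(cls, name: str, post_law_mg_per_100g: float,
                         baseline_mg_per_100g: float, bread_share: float,
                         **kwargs) -> "InterventionSpec":
        """Build a spec from a bread sodium-concentration limit."""
        _, reduction = bread_share_shift(post_law_mg_per_100g,
                                         baseline_mg_per_100g, bread_share)
        return cls(name=name, reduction_fraction=reduction, **kwargs)

    @classmethod
    def from_config(cls, cfg: dict) -> "InterventionSpec":
        """Build a spec from a YAML/JSON scenario block.

        The block gives either ``reduction_fraction`` directly or the
        bread-limit triplet (``post_law_mg_per_100g``,
        ``baseline_mg_per_100g``, ``bread_share``).
        """
        cfg = dict(cfg)
        name = cfg.pop("name")
        common = {k: cfg.pop(k) for k in ("phase_in_years", "one_off_cost", "cost_year")
                  if k in cfg}
        if "reduction_fraction" in cfg:
            return cls(name=name, reduction_fraction=cfg.pop("reduction_fraction"), **common)
        if "post_law_mg_per_100g" in cfg:
            return cls.from_bread_limit(
                name, cfg.pop("post_law_mg_per_100g"), cfg.pop("baseline_mg_per_100g"),
                cfg.pop("bread_share"), **common)
        raise ValueError(
            f"scenario {name!r}: need reduction_fraction or a bread-limit block")


# Built-in scenarios.  The printed effect sizes are authoritative model
# inputs (51.5% / 21.8% for substitution; 7.9% / 2.3% for the bread
# limits); the share arithmetic behind the bread fractions is exposed via
# bread_share_shift.  The modest bread limit is fully implemented in the
# baseline year; the others phase in over five equal annual steps.
BUILTIN_SCENARIOS: dict[str, InterventionSpec] = {
    "subst59": InterventionSpec("subst59", 0.515, phase_in_years=5),
    "subst25": InterventionSpec("subst25", 0.218, phase_in_years=5),
    "bread280": InterventionSpec("bread280", 0.079, phase_in_years=5),
    "bread400": InterventionSpec("bread400", 0.023, phase_in_years=1),
    "do_nothing": InterventionSpec("do_nothing", 0.0, phase_in_years=1, one_off_cost=0.0),
}

DO_NOTHING = BUILTIN_SCENARIOS["do_nothing"]


def get_scenario(name: str) -> InterventionSpec:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; built-ins: {sorted(BUILTIN_SCENARIOS)}") from None


def phase_in_fraction(spec: InterventionSpec, year: int,
                      baseline_year: int = BASELINE_YEAR) -> float:
    """Fraction of the full effect in force during calendar ``year``.

    Step k (1-based) applies for the whole of year baseline + k - 1, so
    the first step is active in the baseline year and the effect is
    complete from baseline + phase_in_years - 1 onwards.
    """
    if year < baseline_year:
        raise ValueError(f"year {year} precedes baseline {baseline_year}")
    return min(1.0, (year - baseline_year + 1) / spec.phase_in_years)


def sodium_reduction_mg(spec: InterventionSpec, sex: str, year: int,
                        sodium: SodiumBaseline | None = None,
                        baseline_year: int = BASELINE_YEAR) -> float:
    """Daily sodium reduction (mg/day) for ``sex`` in ``year``.

    The average-adult fraction is rescaled by the sex's intake ratio,
    which collapses to reduction_fraction x sex intake x phase-in.
    ``sex`` may be "male", "female" or "average".
    """
    sodium = sodium or SodiumBaseline()
    intake = sodium.intake_for(sex)
    reduction = spec.reduction_fraction * intake * phase_in_fraction(spec, year, baseline_year)
    return min(reduction, intake)


def mg_to_mmol(mg: float) -> float:
    """Convert mg/day of sodium to mmol/day (molar mass 23.0 mg/mmol)."""
    if mg < 0:
        raise ValueError(f"sodium mass must be non-negative, got {mg}")
    return mg / SODIUM_MG_PER_MMOL


def bread_share_shift(post_law_mg_per_100g: float, baseline_mg_per_100g: float,
                      bread_share: float) -> tuple[float, float]:
    """Shift in bread's share of total sodium under a concentration limit.

    A maximum sodium level in bread scales bread's contribution to total
    intake by the ratio of the post-law to the baseline concentration.
    Returns ``(new_share, absolute_reduction_fraction)`` as fractions of
    total intake.
    """
    if not 0 < post_law_mg_per_100g <= baseline_mg_per_100g:
        raise ValueError(
            "post-law bread sodium concentration must be positive and not "
            f"exceed the baseline ({post_law_mg_per_100g} vs {baseline_mg_per_100g})")
    if not 0 < bread_share < 1:
        raise ValueError(f"bread_share must be in (0, 1), got {bread_share}")
    new_share = post_law_mg_per_100g / baseline_mg_per_100g * bread_share
    return new_share, bread_share - new_share


def with_effect_scale(spec: InterventionSpec, scale: float) -> InterventionSpec:
    """Scenario with its reduction fraction multiplied by ``scale``.

    Used by the probabilistic sensitivity analysis to perturb the
    intervention effect size; the scaled fraction must stay in [0, 1).
    """
    return replace(spec, reduction_fraction=spec.reduction_fraction * scale)
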