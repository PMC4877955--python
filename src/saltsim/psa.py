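"""Probabilistic sensitivity analysis by Monte Carlo over the pipeline.

Parameter uncertainty is propagated by re-running the whole model under
sampled parameter overlays and summarising 95% uncertainty intervals
(2.5th / 97.5th empirical percentiles) for the incremental QALY and cost
deltas of each scenario.  The central estimate is the expected-value run
with every parameter at its point estimate, not the Monte Carlo mean.

Distributions: intervention effect sizes and hazard ratios are normal
with SD = 10% of the point estimate (hazard-ratio draws constrained to
(0, 1)); cost components are gamma with SD = 10% of the mean; disability
weights are beta, moment-matched to their stated 95% intervals and kept
within those bounds.  Out-of-range draws are resampled rather than
clamped, avoiding probability-mass spikes at the bounds.  All parameters
are sampled independently, each from its own counter-based substream of
(seed, parameter, iteration), so adding a parameter never perturbs the
draws of another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics, markov_engine
from .interventions import DO_NOTHING, InterventionSpec
from .synthetic_inputs import ModelInputs

# substream identifiers (kept stable; new parameters get new ids)
_STREAM_EFFECT = 0
_STREAM_HR = 1
_STREAM_COST = 2
_STREAM_DW = 3

COST_COMPONENTS = ("healthy", "chd_first", "chd_subsequent",
                   "stroke_first", "stroke_subsequent")


@dataclass(frozen=True)
class UncertaintySpec:
    """Monte Carlo settings and distribution scales.

    The ``*_sd_frac`` values are SDs as fractions of the point estimate;
    ``dw_sd_scale`` scales the SD implied by the disability weights'
    stated 95% intervals.  Setting every scale to zero makes each draw
    equal the point estimates, collapsing the uncertainty interval onto
    the central estimate.
    """

    n_iterations: int = 2000
    seed: int = 0
    effect_sd_frac: float = 0.10
    hr_sd_frac: float = 0.10
    cost_sd_frac: float = 0.10
    dw_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in ("effect_sd_frac", "hr_sd_frac", "cost_sd_frac", "dw_sd_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ParameterOverlay:
    """One iteration's sampled parameters, applied on top of base inputs."""

    iteration: int
    effect_scales: dict[str, float]          # per scenario name
    hazard_ratios: pd.DataFrame
    cost_scales: dict[str, float]            # per cost component
    disability_weights: dict[str, float]     # per disease


@dataclass
class UncertaintyInterval:
    """Central (expected-value) estimate with a 95% empirical interval."""

    central: float
    lo2_5: float
    hi97_5: float


@dataclass
class PsaResult:
    intervals: dict[str, dict[str, UncertaintyInterval]]  # scenario -> outcome
    central: dict[str, economics.IncrementalResult]
    draws: pd.DataFrame = field(repr=False)  # iteration, scenario, delta_qalys, delta_costs


def _substream(seed: int, stream: int, iteration: int, extra: int = 0
               ) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream, extra, iteration])


def _resample_normal(rng: np.random.Generator, mean, sd, lo=-np.inf, hi=np.inf,
                     max_tries: int = 1000):
    """Normal draw(s) with out-of-range values resampled, not clamped."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    x = rng.normal(mean, sd)
    for _ in range(max_tries):
        bad = (x <= lo) | (x >= hi)
        if not np.any(bad):
            return x
        x = np.where(bad, rng.normal(mean, sd), x)
    raise RuntimeError("resampling failed to produce in-range draws")


def _beta_within(rng: np.random.Generator, lo: float, hi: float, scale: float,
                 central: float, max_tries: int = 1000) -> float:
    """Beta draw moment-matched to a 95% interval, resampled into bounds.

    Mean is the interval midpoint and SD = (hi - lo) / 3.92, scaled by
    ``scale``; a zero scale returns the central point estimate exactly.
    """
    if scale == 0:
        return central
    m = (lo + hi) / 2.0
    s = (hi - lo) / 3.92 * scale
    var = s * s
    if var >= m * (1 - m):
        raise ValueError("beta moment match impossible: variance too large")
    nu = m * (1 - m) / var - 1.0
    a, b = m * nu, (1 - m) * nu
    for _ in range(max_tries):
        x = float(rng.beta(a, b))
        if lo < x < hi:
            return x
    raise RuntimeError("resampling failed to produce an in-bounds disability weight")


def draw_parameters(spec: UncertaintySpec, inputs: ModelInputs,
                    scenarios: list[InterventionSpec], iteration: int
                    ) -> ParameterOverlay:
    """Sample one parameter overlay; pure function of (spec, iteration)."""
    effect_scales = {}
    for i, scen in enumerate(sorted(scenarios, key=lambda s: s.name)):
        if spec.effect_sd_frac == 0 or scen.reduction_fraction == 0:
            effect_scales[scen.name] = 1.0
        else:
            rng = _substream(spec.seed, _STREAM_EFFECT, iteration, extra=i)
            hi = 1.0 / scen.reduction_fraction  # scaled fraction must stay < 1
            effect_scales[scen.name] = float(
                _resample_normal(rng, 1.0, spec.effect_sd_frac, lo=0.0, hi=hi))

    hr = inputs.hazard_ratios.copy()
    if spec.hr_sd_frac > 0:
        rng = _substream(spec.seed, _STREAM_HR, iteration)
        for col in hr.columns:
            base = hr[col].to_numpy()
            hr[col] = _resample_normal(rng, base, spec.hr_sd_frac * base,
                                       lo=0.0, hi=1.0)

    cost_scales = {c: 1.0 for c in COST_COMPONENTS}
    if spec.cost_sd_frac > 0:
        rng = _substream(spec.seed, _STREAM_COST, iteration)
        # gamma with mean 1 and SD = cost_sd_frac: shape k = 1/sd^2
        k = 1.0 / spec.cost_sd_frac ** 2
        for c in COST_COMPONENTS:
            cost_scales[c] = float(rng.gamma(k, 1.0 / k))

    rng = _substream(spec.seed, _STREAM_DW, iteration)
    morb = inputs.morbidity.iloc[0]
    dw = {
        "chd": _beta_within(rng, morb["dw_chd_lo"], morb["dw_chd_hi"],
                            spec.dw_sd_scale, morb["dw_chd"]),
        "stroke": _beta_within(rng, morb["dw_stroke_lo"], morb["dw_stroke_hi"],
                               spec.dw_sd_scale, morb["dw_stroke"]),
    }
    return ParameterOverlay(iteration=iteration, effect_scales=effect_scales,
                            hazard_ratios=hr, cost_scales=cost_scales,
                            disability_weights=dw)


def _cost_scale_map(overlay: ParameterOverlay) -> dict[str, float]:
    return dict(overlay.cost_scales)


def _dw_map(overlay: ParameterOverlay, spec: UncertaintySpec) -> dict[str, float] | None:
    if spec.dw_sd_scale == 0:
        return None
    return dict(overlay.disability_weights)


def run_psa(inputs: ModelInputs, scenarios: list[InterventionSpec],
            spec: UncertaintySpec,
            discount: economics.DiscountSpec | None = None,
            iterations: list[int] | None = None) -> PsaResult:
    """Monte Carlo uncertainty propagation for a set of scenarios.

    ``iterations`` restricts the draw indices evaluated (default
    0..n_iterations-1); passing e.g. the odd indices enables split-half
    stability checks on identical substreams.
    """
    discount = discount or economics.DiscountSpec()
    if spec.n_iterations < 40:
        warnings.warn("fewer than 40 Monte Carlo iterations: 95% percentile "
                      "estimates will be unstable", stacklevel=2)
    iterations = list(range(spec.n_iterations)) if iterations is None else list(iterations)

    # central (expected-value) run
    comp_traj = markov_engine.run_cohort(inputs, DO_NOTHING)
    comp_ledger = economics.accrue(comp_traj, inputs, discount)
    central: dict[str, economics.IncrementalResult] = {}
    for scen in scenarios:
        traj = markov_engine.run_cohort(inputs, scen)
        central[scen.name] = economics.incremental(
            economics.accrue(traj, inputs, discount), comp_ledger)

    records = []
    for it in iterations:
        overlay = draw_parameters(spec, inputs, scenarios, it)
        cs = _cost_scale_map(overlay)
        dw = _dw_map(overlay, spec)
        comp_l = economics.accrue(comp_traj, inputs, discount,
                                  dw_overrides=dw, cost_scales=cs)
        for scen in scenarios:
            traj = markov_engine.run_cohort(
                inputs, scen, hazard_ratios=overlay.hazard_ratios,
                effect_scale=overlay.effect_scales[scen.name])
            ledger = economics.accrue(traj, inputs, discount,
                                      dw_overrides=dw, cost_scales=cs)
            res = economics.incremental(ledger, comp_l)
            records.append((it, scen.name, res.delta_qalys, res.delta_costs))
    draws = pd.DataFrame(records, columns=["iteration", "scenario",
                                           "delta_qalys", "delta_costs"])

    intervals: dict[str, dict[str, UncertaintyInterval]] = {}
    for scen in scenarios:
        sub = draws[draws["scenario"] == scen.name]
        intervals[scen.name] = {}
        for outcome in ("delta_qalys", "delta_costs"):
            vals = sub[outcome].to_numpy()
            lo, hi = np.percentile(vals, [2.5, 97.5])
            intervals[scen.name][outcome] = UncertaintyInterval(
                central=getattr(central[scen.name], outcome),
                lo2_5=float(lo), hi97_5=float(hi))
    return PsaResult(intervals=intervals, central=central, draws=draws)
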