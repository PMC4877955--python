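"""Result surfaces: league tables, subgroup breakdowns, age-time decomposition.

Three views of a scenario's incremental result are produced: a ranked
scenario league table with uncertainty intervals and cost-effectiveness
classifications; per-adult QALY and net-cost breakdowns by
sociodemographic group (age under/over 65 at baseline, sex, ethnicity);
and a decomposition of the discounted QALY gain by the age at which it
accrues (age in the future, not age at baseline) crossed with calendar
decade, with shares computed among the 45+ and 55+ rows of each window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .economics import IncrementalResult, per_capita

# accrual-age rows: mixed 10/5/10-year widths, with a separate 65-69 row
# (the pension-age boundary in this setting)
ACCRUAL_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (35, 44), (45, 54), (55, 64), (65, 69), (70, 74), (75, 84), (85, 94), (95, 104))
_BAND_BOUNDARIES = sorted({lo for lo, _ in ACCRUAL_AGE_BANDS})


def _band_label(lo: int, hi: int) -> str:
    return f"{lo}+" if hi >= 104 else f"{lo}-{hi}"


def decade_windows(start_year: int, end_year: int) -> list[tuple[int, int]]:
    """Disjoint 10-year calendar windows covering [start_year, end_year]."""
    windows = []
    y = start_year
    while y <= end_year:
        windows.append((y, y + 9))
        y += 10
    return windows


def decompose_age_time(result: IncrementalResult,
                       windows: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Bin the discounted QALY delta by accrual age band x decade window.

    Returns one row per (window, age band) with the QALY delta and its
    share of the window total among 45+ and among 55+ rows (NaN for rows
    below the denominator cut).  Cells over all windows sum to the total
    discounted QALY delta.
    """
    years = np.asarray(result.years)
    if windows is None:
        windows = decade_windows(int(years.min()), int(years.max()))
    starts = sorted(w[0] for w in windows)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(sorted(windows), sorted(windows)[1:]):
        if b_lo <= a_hi:
            raise ValueError(f"windows ({a_lo}-{a_hi}) and ({b_lo}-{b_hi}) overlap")
    del starts

    dq = result.delta_qalys_tc  # (T, C), discounted
    ages = result.ages
    rows = []
    for w_lo, w_hi in windows:
        in_window = (years >= w_lo) & (years <= w_hi)
        window_cells = {}
        for lo, hi in ACCRUAL_AGE_BANDS:
            mask = in_window[:, None] & (ages >= lo) & (ages <= hi)
            window_cells[(lo, hi)] = float(dq[mask].sum())
        total45 = sum(v for (lo, _), v in window_cells.items() if lo >= 45)
        total55 = sum(v for (lo, _), v in window_cells.items() if lo >= 55)
        for (lo, hi), q in window_cells.items():
            rows.append({
                "window": f"{w_lo}-{w_hi}",
                "window_start": w_lo,
                "age_band": _band_label(lo, hi),
                "age_lo": lo,
                "qalys": q,
                "share_45plus_pct": (q / total45 * 100.0) if (lo >= 45 and total45 != 0) else np.nan,
                "share_55plus_pct": (q / total55 * 100.0) if (lo >= 55 and total55 != 0) else np.nan,
            })
    return pd.DataFrame(rows)


def early_window_shares(result: IncrementalResult, window: tuple[int, int],
                        age_cut: int) -> float:
    """Percent of a window's discounted QALY delta accruing below age_cut.

    ``age_cut`` must be an accrual-band boundary (45, 55, 65, 70, 75, 85
    or 95) so the share is exactly representable in the binned table.
    """
    if age_cut not in _BAND_BOUNDARIES:
        raise ValueError(f"age_cut {age_cut} is not an accrual-band boundary "
                         f"{_BAND_BOUNDARIES}")
    years = np.asarray(result.years)
    in_window = (years >= window[0]) & (years <= window[1])
    dq = result.delta_qalys_tc
    total = float(dq[in_window].sum())
    if total == 0:
        raise ValueError("window contains no QALY delta")
    below = float(dq[in_window[:, None] & (result.ages < age_cut)].sum())
    return below / total * 100.0


def group_results(result: IncrementalResult) -> pd.DataFrame:
    """Per-adult incremental costs and QALYs by sociodemographic group.

    Groups: age <65 / 65+ at baseline (unlike the accrual-age
    decomposition, this axis is age in the baseline year), women/men, and
    Maori/non-Maori.  Values are per adult alive in the baseline year.
    """
    groups = {
        "age_lt65_2011": result.start_age < 65,
        "age_65plus_2011": result.start_age >= 65,
        "women": result.sex_idx == 1,
        "men": result.sex_idx == 0,
        "maori": result.eth_idx == 0,
        "non_maori": result.eth_idx == 1,
        "all": np.ones_like(result.start_age, dtype=bool),
    }
    rows = []
    for label, mask in groups.items():
        dq, dc = per_capita(result, mask)
        rows.append({"group": label, "qalys_per_adult": dq, "cost_per_adult": dc,
                     "population": float(result.pop[mask].sum())})
    return pd.DataFrame(rows).set_index("group")


def league_table(results: dict[str, IncrementalResult],
                 intervals: dict | None = None) -> pd.DataFrame:
    """Ranked scenario table: QALYs gained (desc), net costs, classification.

    Ties in QALYs break by scenario name for a stable order.  If PSA
    ``intervals`` are supplied (scenario -> outcome -> interval), 95%
    bounds are included.
    """
    rows = []
    for name, res in results.items():
        row = {
            "scenario": name,
            "delta_qalys": res.delta_qalys,
            "delta_costs": res.delta_costs,
            "classification": (res.classification if res.classification != "icer"
                               or res.icer is None else f"{res.icer:,.0f} NZ$/QALY"),
        }
        if intervals and name in intervals:
            row["qalys_lo"] = intervals[name]["delta_qalys"].lo2_5
            row["qalys_hi"] = intervals[name]["delta_qalys"].hi97_5
            row["costs_lo"] = intervals[name]["delta_costs"].lo2_5
            row["costs_hi"] = intervals[name]["delta_costs"].hi97_5
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["scenario", "delta_qalys", "delta_costs",
                                     "classification"])
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["delta_qalys", "scenario"],
                              ascending=[False, True], kind="mergesort")
    return frame.reset_index(drop=True)


def render_markdown(frame: pd.DataFrame, floatfmt: str = ",.0f") -> str:
    """Markdown rendering with thousands separators (CSV keeps full precision)."""
    show = frame.copy()
    for col in show.columns:
        if pd.api.types.is_float_dtype(show[col]):
            show[col] = show[col].map(lambda v: "" if pd.isna(v) else format(v, floatfmt))
    return show.to_markdown(index=False)


# ---------------------------------------------------------------------------
# small ratio helpers for headline summary arithmetic


def ratio_percent(part: float, total: float, decimals: int = 1) -> float:
    """part / total as a percentage, rounded to ``decimals``."""
    if total == 0:
        raise ValueError("total must be nonzero")
    return round(part / total * 100.0, decimals)


def per_adult(total_gain: float, population: float, decimals: int = 2) -> float:
    """Whole-cohort gain expressed per adult."""
    if population <= 0:
        raise ValueError("population must be positive")
    return round(total_gain / population, decimals)


def relative_excess_percent(a: float, b: float, decimals: int = 0) -> float:
    """How much larger ``a`` is than ``b``, as a percentage."""
    if b == 0:
        raise ValueError("reference value must be nonzero")
    return round((a / b - 1.0) * 100.0, decimals)


def plot_age_distribution(cells: pd.DataFrame, path: str) -> None:
    """Bar chart of QALY gains by accrual age band, one series per decade."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = cells.pivot(index="age_band", columns="window", values="qalys")
    order = [_band_label(lo, hi) for lo, hi in ACCRUAL_AGE_BANDS]
    pivot = pivot.reindex(order)
    ax = pivot.plot.bar(figsize=(9, 5))
    ax.set_xlabel("age when QALYs are gained")
    ax.set_ylabel("discounted QALYs gained")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
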