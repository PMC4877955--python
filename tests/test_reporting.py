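"""Reporting: decomposition, subgroup tables, league table, ratio helpers."""

import numpy as np
import pandas as pd
import pytest

from saltsim.economics import IncrementalResult
from saltsim.reporting import (decompose_age_time, early_window_shares,
                               group_results, league_table, per_adult,
                               ratio_percent, relative_excess_percent)


def _point_result(age: int, year: int, qalys: float = 10.0) -> IncrementalResult:
    """A synthetic incremental result with all gains in one (age, year) cell."""
    years = np.arange(2011, 2041)
    T, C = len(years), 2
    ages = np.tile(age + (years - year)[:, None], (1, C))
    dq = np.zeros((T, C))
    dq[years == year, 0] = qalys
    return IncrementalResult(
        scenario_name="point", delta_qalys=qalys, delta_costs=-1.0,
        classification="dominant", icer=None, delta_qalys_tc=dq,
        delta_costs_tc=np.zeros((T, C)), one_off_cost_delta=0.0, years=years,
        ages=ages, sex_idx=np.array([0, 1]), eth_idx=np.array([0, 1]),
        start_age=np.array([age - (year - 2011)] * 2), pop=np.array([100.0, 100.0]))


class TestDecomposeAgeTime:
    def test_single_cell_concentration(self):
        res = _point_result(age=72, year=2025)
        cells = decompose_age_time(res)
        nz = cells[cells["qalys"] != 0]
        assert len(nz) == 1
        assert nz.iloc[0]["window"] == "2021-2030"
        assert nz.iloc[0]["age_band"] == "70-74"
        assert nz.iloc[0]["share_45plus_pct"] == pytest.approx(100.0)

    def test_shares_sum_to_100_within_each_window(self, central_results):
        cells = decompose_age_time(central_results["subst59"])
        for _, window in cells.groupby("window"):
            if window["qalys"].abs().sum() == 0:
                continue
            assert window["share_45plus_pct"].sum() == pytest.approx(100.0, abs=1e-6)
            assert window["share_55plus_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_decomposition_completeness(self, central_results):
        res = central_results["subst59"]
        cells = decompose_age_time(res)
        assert cells["qalys"].sum() == pytest.approx(res.delta_qalys, rel=1e-9)

    def test_overlapping_windows_rejected(self, central_results):
        with pytest.raises(ValueError, match="overlap"):
            decompose_age_time(central_results["bread400"],
                               windows=[(2011, 2020), (2015, 2024)])


class TestEarlyWindowShares:
    def test_all_gains_below_cut(self):
        res = _point_result(age=50, year=2015)
        assert early_window_shares(res, (2011, 2020), 65) == pytest.approx(100.0)

    def test_no_gains_below_cut(self):
        res = _point_result(age=80, year=2015)
        assert early_window_shares(res, (2011, 2020), 45) == pytest.approx(0.0)

    def test_non_boundary_cut_rejected(self, central_results):
        with pytest.raises(ValueError, match="boundary"):
            early_window_shares(central_results["subst59"], (2011, 2020), 60)


class TestGroupResults:
    def test_partitions_cover_cohort(self, central_results):
        g = group_results(central_results["subst25"])
        total = g.loc["all", "population"]
        for pair in (("women", "men"), ("maori", "non_maori"),
                     ("age_lt65_2011", "age_65plus_2011")):
            assert sum(g.loc[p, "population"] for p in pair) == pytest.approx(total)

    def test_partition_recovers_whole_cohort_per_capita(self, central_results):
        g = group_results(central_results["subst59"])
        for pair in (("women", "men"), ("maori", "non_maori")):
            w = sum(g.loc[p, "qalys_per_adult"] * g.loc[p, "population"] for p in pair)
            assert w / g.loc["all", "population"] == pytest.approx(
                g.loc["all", "qalys_per_adult"], rel=1e-12)


class TestLeagueTable:
    def test_ranked_by_qalys_descending(self, central_results):
        table = league_table(central_results)
        assert list(table["scenario"]) == ["subst59", "subst25", "bread280", "bread400"]
        assert table["delta_qalys"].is_monotonic_decreasing

    def test_tie_breaks_by_name(self):
        def fake(name):
            return IncrementalResult(
                scenario_name=name, delta_qalys=5.0, delta_costs=-1.0,
                classification="dominant", icer=None,
                delta_qalys_tc=np.zeros((1, 1)), delta_costs_tc=np.zeros((1, 1)),
                one_off_cost_delta=0.0, years=np.array([2011]),
                ages=np.array([[50]]), sex_idx=np.array([0]),
                eth_idx=np.array([0]), start_age=np.array([50]),
                pop=np.array([1.0]))
        table = league_table({"zeta": fake("zeta"), "alpha": fake("alpha")})
        assert list(table["scenario"]) == ["alpha", "zeta"]

    def test_empty_input_gives_empty_table(self):
        table = league_table({})
        assert table.empty


class TestRatioHelpers:
    def test_headline_quotients(self):
        assert ratio_percent(294_000, 33_200_000, 2) == 0.89
        assert per_adult(294_000, 2_300_000) == 0.13
        assert ratio_percent(13_177 + 60_658, 294_000, 1) == 25.1

    def test_relative_excess(self):
        assert relative_excess_percent(0.163, 0.123) == 33
        assert relative_excess_percent(0.141, 0.115) == 23

    def test_degenerate_denominators_rejected(self):
        with pytest.raises(ValueError):
            ratio_percent(1, 0)
        with pytest.raises(ValueError):
            per_adult(1, 0)
        with pytest.raises(ValueError):
            relative_excess_percent(1, 0)
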