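"""Theil-Sen, Mann-Kendall, Spearman and preseason-temperature logic."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenomap as pm
from phenomap.climate import doy_to_month
from phenomap.grids import growing_season_length
from phenomap.observations import ObservationTable
from phenomap.trends import mann_kendall_s, trend_significance


def brute_force_theil_sen(x, y):
    slopes = [(y[j] - y[i]) / (x[j] - x[i])
              for i, j in combinations(range(len(x)), 2) if x[j] != x[i]]
    return float(np.median(slopes))


class TestTheilSen:
    def test_exact_line(self):
        x = np.arange(1990, 2000)
        assert pm.theil_sen(x, 2 * x) == pytest.approx(2.0)
        assert pm.theil_sen(x, np.full(10, 7.0)) == pytest.approx(0.0)

    def test_hand_computed_median_of_six_slopes(self):
        # pairwise slopes of y=[1,2,4,3] at x=[1,2,3,4]:
        # 1, 3/2, 2/3, 2, 1/2, -1 -> median (1 + 2/3)/2 = 5/6
        assert pm.theil_sen([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(5 / 6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-300, 300), min_size=3, max_size=50))
    def test_matches_brute_force_oracle(self, ys):
        x = np.arange(len(ys), dtype=float)
        assert pm.theil_sen(x, ys) == pytest.approx(
            brute_force_theil_sen(x, np.asarray(ys)), abs=1e-9)

    def test_shift_and_tilt_invariances(self):
        rng = np.random.default_rng(0)
        x = np.arange(1951, 2000, dtype=float)
        y = rng.normal(100, 5, len(x))
        s = pm.theil_sen(x, y)
        assert pm.theil_sen(x, y + 13.5) == pytest.approx(s, abs=1e-9)
        assert pm.theil_sen(x, y + 0.4 * x) == pytest.approx(s + 0.4, abs=1e-9)

    def test_identical_years_undefined(self):
        with pytest.raises(ValueError):
            pm.theil_sen([2000, 2000], [1, 2])


class TestMannKendall:
    def test_s_statistic_hand_count(self):
        # y=[1,2,4,3]: 5 concordant pairs, 1 discordant -> S = 4
        assert mann_kendall_s([1, 2, 3, 4], [1, 2, 4, 3]) == 4

    def test_monotone_series_max_s_minimal_p(self):
        x = np.arange(10)
        y = np.arange(10, dtype=float)
        assert mann_kendall_s(x, y) == 45
        p = trend_significance(x, y)
        assert p < 1e-4

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            trend_significance([1, 2], [1, 2])

    def test_tie_corrected_p_is_valid_probability(self):
        rng = np.random.default_rng(1)
        y = np.round(rng.normal(0, 1, 30), 0)  # heavy ties
        p = trend_significance(np.arange(30), y)
        assert 0 <= p <= 1


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pm.spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert pm.spearman(x, -np.asarray(x)) == pytest.approx(-1.0)

    def test_midrank_tie_hand_value(self):
        # ranks x = 1,2,3; y = 1.5,1.5,3 -> rho = 1.5/sqrt(3)
        assert pm.spearman([1, 2, 3], [2, 2, 3]) == pytest.approx(
            1.5 / np.sqrt(3), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-10000, 10000), min_size=4, max_size=30,
                    unique=True))
    def test_invariant_under_monotone_transform(self, ys):
        x = np.arange(len(ys), dtype=float)
        y = np.asarray(ys, dtype=float)
        rho = pm.spearman(x, y)
        assert pm.spearman(x, np.arctan(y / 50) * 7 + 2) == pytest.approx(
            rho, abs=1e-12)

    def test_zero_rank_variance_flagged(self):
        with pytest.raises(ValueError, match="rank variance"):
            pm.spearman([1, 2, 3], [5, 5, 5])


class TestPreseason:
    def _cube(self, monthly_values):
        geom = pm.GridGeometry(north=48.0, west=11.0, dlat=1.0, dlon=1.0,
                               nrows=1, ncols=1)
        years = [2000, 2001]
        vals = np.zeros((2, 12, 1, 1))
        for (y, m), t in monthly_values.items():
            vals[y - 2000, m - 1, 0, 0] = t
        return pm.TemperatureCube(geom, years, vals), geom

    def test_april_onset_averages_feb_mar_apr(self):
        cube, geom = self._cube({(2001, 2): 2.0, (2001, 3): 5.0, (2001, 4): 8.0})
        onset = pm.Grid(geom, np.array([[100.0]]), np.ones((1, 1), bool))
        onset.year = 2001
        out = pm.preseason_temperature(cube, onset)
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_january_onset_wraps_into_previous_year(self):
        cube, geom = self._cube({(2001, 1): 0.0, (2000, 12): -3.0,
                                 (2000, 11): 6.0})
        onset = pm.Grid(geom, np.array([[15.0]]), np.ones((1, 1), bool))
        onset.year = 2001
        out = pm.preseason_temperature(cube, onset)
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_window_before_cube_start_is_masked(self):
        cube, geom = self._cube({})
        onset = pm.Grid(geom, np.array([[15.0]]), np.ones((1, 1), bool))
        onset.year = 2000  # needs Nov/Dec 1999
        out = pm.preseason_temperature(cube, onset)
        assert not out.mask[0, 0]

    def test_constant_cube_returns_constant(self):
        geom = pm.GridGeometry(north=48.0, west=11.0, dlat=1.0, dlon=1.0,
                               nrows=1, ncols=1)
        cube = pm.TemperatureCube(geom, [2001], np.full((1, 12, 1, 1), 10.0))
        for doy in (100, 200, 330):
            onset = pm.Grid(geom, np.array([[float(doy)]]), np.ones((1, 1), bool))
            onset.year = 2001
            assert pm.preseason_temperature(cube, onset).values[0, 0] == 10.0

    def test_doy_to_month_boundaries(self):
        assert list(doy_to_month([1, 31, 32, 90, 91, 365, 366])) == \
            [1, 1, 2, 3, 4, 12, 12]


class TestTrendMap:
    def test_noiseless_trend_exact_on_every_cell(self):
        w = pm.make_world(sigma=0.0, beta=-0.25, seed=301, shape=(6, 6))
        stack = {int(y): w.true_field(int(y)) for y in w.years[:40]}
        res, summary = pm.trend_map(stack)["interpol"]
        assert all(r.slope == pytest.approx(-0.25, abs=1e-9) for r in res)
        assert summary.prop_sig_negative == 1.0

    def test_station_record_length_filter(self):
        rows = []
        rng = np.random.default_rng(2)
        for sid, n_years in [("long", 35), ("short", 29)]:
            for k in range(n_years):
                rows.append({"station_id": sid, "lat": 48.0, "lon": 11.0,
                             "elev": 300.0, "year": 1951 + k, "phase_id": "p",
                             "doy": int(100 + rng.integers(-5, 5))})
        table = ObservationTable(pd.DataFrame(rows))
        res, _ = pm.trend_map(station_table=table)["obs"]
        assert [r.series_id for r in res] == ["long"]
        # winter relaxation admits >= 15-year series
        res_w, _ = pm.trend_map(station_table=table, winter_phase=True)["obs"]
        assert {r.series_id for r in res_w} == {"long", "short"}


class TestGrowingSeason:
    def _pair(self, spring_val, winter_val):
        geom = pm.GridGeometry(north=1, west=1, dlat=1, dlon=1, nrows=1, ncols=1)
        mk = lambda v: pm.Grid(geom, np.array([[float(v)]]), np.ones((1, 1), bool))
        return mk(spring_val), mk(winter_val)

    def test_uniform_grids(self):
        spring, winter = self._pair(84, 313)
        assert growing_season_length(spring, winter) == pytest.approx(229.0)

    def test_single_cell(self):
        spring, winter = self._pair(100, 300)
        assert growing_season_length(spring, winter) == pytest.approx(200.0)

    def test_inverted_season_warns_but_contributes(self):
        spring, winter = self._pair(300, 100)
        with pytest.warns(UserWarning, match="before first spring"):
            assert growing_season_length(spring, winter) == pytest.approx(-200.0)

    def test_mask_mismatch_raises(self, small_geom):
        g1 = pm.Grid(small_geom, np.ones((3, 3)), np.ones((3, 3), bool))
        m = np.ones((3, 3), bool)
        m[0, 0] = False
        g2 = pm.Grid(small_geom, np.ones((3, 3)), m)
        with pytest.raises(ValueError):
            growing_season_length(g1, g2)
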