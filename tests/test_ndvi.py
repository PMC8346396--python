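"""NDVI pipeline: reliability filter, climatology fill, LOESS, seasons."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

import phenomap as pm
from phenomap.ndvi import (COMPOSITE_DOYS, NdviSeries, fill_climatology,
                           filter_reliability, half_amplitude_seasons,
                           loess_smooth, smooth_to_daily)


def _series(values_by_year, codes=None, pixel="px"):
    rows = []
    for year, vals in values_by_year.items():
        for p, v in enumerate(vals):
            code = codes[year][p] if codes else "good"
            rows.append({"year": year, "period": p,
                         "start_doy": int(COMPOSITE_DOYS[p]), "ndvi": v,
                         "reliability": code})
    return NdviSeries(pixel, pd.DataFrame(rows))


class TestReliabilityFilter:
    def test_keeps_good_and_marginal_only(self):
        vals = [0.1, 0.2, 0.3, 0.4] + [0.5] * 19
        codes = ["good", "cloudy", "marginal", "snow"] + ["good"] * 19
        s = _series({2001: vals}, {2001: codes})
        out = filter_reliability(s)
        kept = out.df.ndvi.notna().to_numpy()[:4]
        assert list(kept) == [True, False, True, False]
        assert out.df.ndvi.iloc[0] == 0.1 and out.df.ndvi.iloc[2] == 0.3

    def test_all_good_unchanged(self):
        s = _series({2001: [0.5] * 23})
        assert filter_reliability(s).df.ndvi.equals(s.df.ndvi)

    def test_all_cloudy_warns(self):
        s = _series({2001: [0.5] * 23}, {2001: ["cloudy"] * 23})
        with pytest.warns(UserWarning, match="no composites"):
            out = filter_reliability(s)
        assert out.df.ndvi.isna().all()


class TestClimatologyFill:
    def test_fills_with_position_mean(self):
        vals1, vals2, vals3 = [0.4] * 23, [0.6] * 23, [0.5] * 23
        vals3[5] = np.nan
        s = _series({2001: vals1, 2002: vals2, 2003: vals3})
        out = fill_climatology(s)
        filled = out.df[(out.df.year == 2003) & (out.df.period == 5)].ndvi.iloc[0]
        assert filled == pytest.approx(0.5)  # mean of 0.4 and 0.6

    def test_no_missing_is_identity_and_idempotent(self):
        rng = np.random.default_rng(0)
        s = _series({2001: rng.uniform(0, 1, 23), 2002: rng.uniform(0, 1, 23)})
        once = fill_climatology(s)
        assert once.df.ndvi.equals(s.df.ndvi)
        vals = s.df.ndvi.to_numpy().copy()
        vals[3] = np.nan
        gappy = s.copy_with(vals)
        assert fill_climatology(fill_climatology(gappy)).df.ndvi.equals(
            fill_climatology(gappy).df.ndvi)

    def test_position_missing_everywhere_stays_missing(self):
        vals1, vals2 = [0.5] * 23, [0.5] * 23
        vals1[7] = vals2[7] = np.nan
        out = fill_climatology(_series({2001: vals1, 2002: vals2}))
        assert out.df[out.df.period == 7].ndvi.isna().all()


class TestLoess:
    def test_reproduces_constants(self):
        s = _series({2001: [0.5] * 23, 2002: [0.5] * 23})
        daily = smooth_to_daily(s)
        assert np.allclose(daily.value, 0.5, atol=1e-9)

    def test_exact_on_linear_ramp_away_from_edges(self):
        t = np.arange(0, 400, 16.0)
        y = 0.001 * t + 0.1
        t_eval = np.arange(50.0, 350.0)
        out = loess_smooth(t, y, t_eval, q=6)
        assert np.allclose(out, 0.001 * t_eval + 0.1, atol=1e-6)

    def test_agrees_with_statsmodels_lowess_on_ramp(self):
        # degree 1 and 2 coincide on a line: cross-check the smoother
        t = np.arange(0, 370, 16.0)
        y = 0.002 * t + 0.05
        ref = sm_lowess(y, t, frac=0.4, return_sorted=False)
        ours = loess_smooth(t, y, t, q=int(np.ceil(0.4 * len(t))))
        assert np.allclose(ours, ref, atol=1e-8)

    def test_smoothing_reduces_noise(self):
        rng = np.random.default_rng(1)
        errs_raw, errs_smooth = [], []
        for rep in range(20):
            s = pm.make_ndvi_series(135, 285, years=(2001, 2002),
                                    seed=500 + rep, noise_sd=0.05)
            clean = pm.make_ndvi_series(135, 285, years=(2001, 2002),
                                        seed=500 + rep, noise_sd=0.0)
            errs_raw.append(np.sqrt(np.mean(
                (s.df.ndvi - clean.df.ndvi) ** 2)))
            daily = smooth_to_daily(s, span=0.25)
            daily_clean = smooth_to_daily(clean, span=0.25)
            errs_smooth.append(np.sqrt(np.mean(
                (daily.value - daily_clean.value) ** 2)))
        assert np.mean(errs_smooth) < np.mean(errs_raw)

    def test_too_few_composites_rejected(self):
        vals = [np.nan] * 23
        vals[:5] = [0.5] * 5
        with pytest.raises(ValueError, match=">= 10"):
            smooth_to_daily(_series({2001: vals}))


class TestHalfAmplitude:
    def _triangular_daily(self, year=2010, base=0.2, peak=0.8):
        doy = np.arange(1, 366, dtype=float)
        vals = np.interp(doy, [1, 100, 180, 300, 365],
                         [base, base, peak, base, base])
        return pd.DataFrame({"year": year, "doy": doy, "value": vals})

    def test_analytic_triangular_crossings(self):
        s = half_amplitude_seasons(self._triangular_daily(), 2010)
        assert (s.sos_doy, s.eos_doy) == (140, 240)
        assert s.threshold == pytest.approx(0.5)

    def test_flat_series_declares_no_season(self):
        daily = pd.DataFrame({"year": 2010, "doy": np.arange(1, 366),
                              "value": 0.31})
        s = half_amplitude_seasons(daily, 2010)
        assert not s.defined and s.reason == "amplitude-below-minimum"

    def test_affine_invariance(self):
        d1 = self._triangular_daily()
        d2 = d1.assign(value=d1.value * 0.7 + 0.11)
        s1 = half_amplitude_seasons(d1, 2010)
        s2 = half_amplitude_seasons(d2, 2010)
        assert (s1.sos_doy, s1.eos_doy) == (s2.sos_doy, s2.eos_doy)

    def test_sos_before_peak_before_eos(self):
        for rep in range(10):
            s = pm.make_ndvi_series(120 + rep, 260 + 2 * rep,
                                    years=(2001, 2002), seed=600 + rep)
            daily = smooth_to_daily(s)
            for year in (2001, 2002):
                est = half_amplitude_seasons(daily, year)
                sel = daily[daily.year == year]
                peak = int(sel.value.idxmax() - sel.index[0]) + 1
                if est.defined:
                    assert est.sos_doy <= peak <= est.eos_doy


def test_full_pipeline_deterministic():
    s = pm.make_ndvi_series(135, 285, years=(2001, 2003), seed=700,
                            flag_fraction=0.1, missing_fraction=0.05)
    r1 = pm.extract_seasons(s)
    r2 = pm.extract_seasons(s)
    assert [(e.sos_doy, e.eos_doy) for e in r1] == \
        [(e.sos_doy, e.eos_doy) for e in r2]
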