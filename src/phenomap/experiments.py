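"""Self-contained benchmark experiments on synthetic worlds.

Each function sets up a synthetic study at a documented scale, runs the
relevant part of the pipeline end to end, and returns the measured
quantities.  They are the package's reproducible evidence base: the test
suite asserts properties of their outputs and the reproduction script
reports them.  All randomness derives from the single ``seed`` argument
via spawned child streams.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .grids import growing_season_length
from .mapping import PhenologyMapper, build_circles, fit_circle
from .ndvi import half_amplitude_seasons, smooth_to_daily
from .observations import ObservationTable
from .synthetic import (implied_spearman, make_coupled_onsets,
                        make_ndvi_series, make_temperature, make_world,
                        sample_observations)
from .trends import _mk_p_batch, correlation_map, theil_sen, trend_map
from .validation import loocv_circle, loocv_refit, subsample_uncertainty

__all__ = [
    "noiseless_exactness",
    "press_oracle_gap",
    "noise_recovery",
    "subsample_curve",
    "trend_recovery",
    "mann_kendall_type1",
    "theil_sen_oracle_gap",
    "correlation_structure",
    "ndvi_triangular",
    "ndvi_end_to_end",
    "growing_season_demo",
]


def _seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def noiseless_exactness(seed: int = 0, shape=(20, 20), n_sites: int = 80) -> dict:
    """Constant-coefficient world without noise: the pipeline must be exact.

    Returns the worst-case circle-coefficient error, onset-grid error
    against the truth field, and the largest circle RMSE_LOOCV (all should
    sit at float-precision zero).
    """
    s1, s2 = _seeds(seed, 2)
    world = make_world(sigma=0.0, beta=0.0, seed=s1, shape=shape)
    obs = sample_observations(world, n_sites, years=np.array([2019]),
                              seed=s2, round_doy=False)
    res = PhenologyMapper(obs, world.dem).fit().loocv()
    truth = world.true_field()
    coeff_err = max(
        float(np.abs(f.coeffs - world.coeff_fields[:, 0, 0]).max())
        for f in res.circle_fits if f.ok
    )
    g = res.pheno_grid
    grid_err = float(np.nanmax(np.abs(g.values - truth.values)[g.mask]))
    max_rmse = max(f.rmse_loocv for f in res.circle_fits
                   if f.rmse_loocv is not None)
    return {"max_coeff_error": coeff_err, "max_grid_error_days": grid_err,
            "max_rmse_loocv_days": float(max_rmse), "n_obs": len(obs)}


def press_oracle_gap(seed: int = 0, n_circles: int = 50) -> dict:
    """PRESS-based LOOCV vs explicit refit-each-observation, random circles.

    Circle sizes 10-60, observer noise in {2, 6, 12} days.
    """
    rng = np.random.default_rng(_seeds(seed, 1)[0])
    worst = 0.0
    for _ in range(n_circles):
        n = int(rng.integers(10, 61))
        sigma = float(rng.choice([2.0, 6.0, 12.0]))
        lat = rng.uniform(47, 50, n)
        lon = rng.uniform(9, 13, n)
        elev = rng.uniform(0, 1500, n)
        doy = 100 + 0.02 * elev + 1.5 * lon - 2 * lat + rng.normal(0, sigma, n)
        t = ObservationTable._from_validated(pd.DataFrame({
            "station_id": [f"s{i}" for i in range(n)], "lat": lat, "lon": lon,
            "elev": elev, "year": 2019, "phase_id": "p", "doy": doy,
        }))
        worst = max(worst, abs(loocv_circle(t) - loocv_refit(t)))
    return {"max_gap_days": float(worst), "n_circles": n_circles}


def noise_recovery(seed: int = 0, reps: int = 100, n_sites: int = 200,
                   sigma: float = 6.0, shape=(20, 20)) -> dict:
    """Gridded-mean RMSE_LOOCV under known observer noise, repeated.

    The LOOCV error estimates out-of-sample prediction error, so its
    expectation sits slightly above the generating noise sd (by roughly
    sigma * p / (2 n_c) for circles of size n_c).
    """
    seeds = _seeds(seed, 2 * reps)
    vals = np.empty(reps)
    for r in range(reps):
        world = make_world(sigma=sigma, beta=0.0, seed=seeds[2 * r], shape=shape)
        obs = sample_observations(world, n_sites, years=np.array([2019]),
                                  seed=seeds[2 * r + 1])
        res = PhenologyMapper(obs, world.dem).fit().loocv()
        vals[r] = res.gridded_rmse_mean()
    in_band = float(((vals >= 0.9 * sigma) & (vals <= 1.1 * sigma)).mean())
    return {"mean_rmse_days": float(vals.mean()), "sd_rmse_days": float(vals.std()),
            "in_band_fraction": in_band, "reps": reps, "values": vals}


def subsample_curve(seed: int = 0, n_sites: int = 600, reps: int = 200,
                    sigma: float = 6.0, shape=(25, 25)) -> dict:
    """RMSE_LOOCV vs retained observation percentage (10%...100%)."""
    s1, s2, s3 = _seeds(seed, 3)
    world = make_world(sigma=sigma, beta=0.0, seed=s1, shape=shape)
    obs = sample_observations(world, n_sites, years=np.array([2019]), seed=s2)
    df = obs.df
    circles = build_circles((df.lat.min(), df.lat.max(),
                             df.lon.min(), df.lon.max()))
    levels = list(range(10, 101, 10))
    results = subsample_uncertainty(obs, circles, levels, n_reps=reps, seed=s3)
    means = np.array([r.mean_rmse for r in results])
    rho = float(stats.spearmanr(levels, means).statistic)
    return {"levels": levels, "mean_rmse_days": means,
            "rmse_at_10pct": float(means[0]), "rmse_at_100pct": float(means[-1]),
            "level_rmse_spearman": rho}


def trend_recovery(seed: int = 0, beta: float = -0.25, sigma: float = 5.0,
                   n_sites: int = 300, n_cells: int = 500,
                   shape=(25, 25)) -> dict:
    """Recover a known long-term trend from 69 years of interpolated maps.

    Station series carry the raw observer noise; grid series come from the
    per-year interpolation, which averages that noise away — their slope
    distribution is correspondingly tighter.
    """
    s1, s2, s3 = _seeds(seed, 3)
    world = make_world(sigma=sigma, beta=beta, seed=s1, shape=shape)
    obs = sample_observations(world, n_sites, seed=s2)
    stack = {}
    for y in world.years:
        sel = obs.select(year=int(y))
        stack[int(y)] = PhenologyMapper(sel, world.dem).fit().pheno_grid
    out = trend_map(stack, obs, max_grid_series=n_cells, seed=s3)
    grid_res, grid_sum = out["interpol"]
    st_res, st_sum = out["obs"]
    sig = np.mean([r.p_value < 0.05 for r in grid_res])
    return {
        "true_slope": beta,
        "grid_mean_slope": grid_sum.mean_slope,
        "grid_slope_sd": grid_sum.sd_slope,
        "grid_sig_fraction": float(sig),
        "station_mean_slope": st_sum.mean_slope,
        "station_slope_sd": st_sum.sd_slope,
        "n_grid_series": grid_sum.n_series,
        "n_station_series": st_sum.n_series,
    }


def mann_kendall_type1(seed: int = 0, n: int = 30, sims: int = 10000,
                       alpha: float = 0.05) -> dict:
    """Empirical size of the Mann-Kendall test under exchangeable noise."""
    rng = np.random.default_rng(_seeds(seed, 1)[0])
    y = rng.standard_normal((sims, n))
    p = _mk_p_batch(y)
    return {"rejection_rate": float((p < alpha).mean()), "sims": sims, "n": n}


def theil_sen_oracle_gap(seed: int = 0, cases: int = 60) -> dict:
    """Theil-Sen vs exhaustive pairwise-slope median on all n <= 50 cases."""
    from itertools import combinations
    rng = np.random.default_rng(_seeds(seed, 1)[0])
    worst = 0.0
    for _ in range(cases):
        n = int(rng.integers(3, 51))
        x = np.arange(n, dtype=float)
        y = rng.normal(0, 50, n)
        slopes = [(y[j] - y[i]) / (x[j] - x[i])
                  for i, j in combinations(range(n), 2)]
        worst = max(worst, abs(theil_sen(x, y) - float(np.median(slopes))))
    return {"max_gap": float(worst), "cases": cases}


def correlation_structure(seed: int = 0, shape=(12, 12),
                          spring_coupling: float = -0.8,
                          autumn_coupling: float = 0.6) -> dict:
    """Preseason-temperature correlation of coupled spring/autumn phases.

    Correlations are measured with the climatological preseason window,
    which recovers the generating coupling; the per-year window is also
    reported for the sign structure.
    """
    s1, s2, s3, s4 = _seeds(seed, 4)
    world = make_world(sigma=0.0, beta=0.0, seed=s1, shape=shape)
    cube = make_temperature(world, seed=s2)
    out = {}
    for name, coupling, s in (("spring", spring_coupling, s3),
                              ("autumn", autumn_coupling, s4)):
        stack = make_coupled_onsets(world, cube, coupling, seed=s)
        clim = correlation_map(stack, cube, climatological_months=True)
        peryear = correlation_map(stack, cube)
        out[f"{name}_mean_rho"] = float(clim["interpol"].rho.mean())
        out[f"{name}_mean_rho_per_year_window"] = float(
            peryear["interpol"].rho.mean())
        out[f"{name}_implied_rho"] = float(implied_spearman(coupling))
    return out


def ndvi_triangular() -> dict:
    """Analytic triangular curve: crossings known in closed form."""
    doy = np.arange(1, 366, dtype=float)
    vals = np.interp(doy, [1, 100, 180, 300, 365], [0.2, 0.2, 0.8, 0.2, 0.2])
    daily = pd.DataFrame({"year": 2010, "doy": doy, "value": vals})
    s = half_amplitude_seasons(daily, 2010)
    return {"sos_doy": s.sos_doy, "eos_doy": s.eos_doy,
            "threshold": s.threshold}


def ndvi_end_to_end(seed: int = 0, reps: int = 200, sos_true: float = 135.0,
                    eos_true: float = 285.0) -> dict:
    """Degraded-composite recovery of season bounds.

    Each repetition samples a 3-year double-logistic series at 16-day
    cadence, degrades ~10% of composites (flags + outright gaps), runs
    reliability filtering, climatology fill and LOESS smoothing, and reads
    the half-amplitude seasons.  Truth is the same extractor applied to
    the clean curve.
    """
    from .ndvi import extract_seasons
    clean = make_ndvi_series(sos_true, eos_true, years=(2001, 2003), seed=0,
                             noise_sd=0.0)
    truth = {s.year: (s.sos_doy, s.eos_doy) for s in extract_seasons(clean)}
    seeds = _seeds(seed, reps)
    sos_err, eos_err = [], []
    for r in range(reps):
        series = make_ndvi_series(sos_true, eos_true, years=(2001, 2003),
                                  seed=seeds[r], flag_fraction=0.05,
                                  missing_fraction=0.05)
        for est in extract_seasons(series):
            if est.defined:
                sos_err.append(abs(est.sos_doy - truth[est.year][0]))
                eos_err.append(abs(est.eos_doy - truth[est.year][1]))
    sos_err = np.array(sos_err)
    eos_err = np.array(eos_err)
    return {
        "sos_within_2d_fraction": float((sos_err <= 2).mean()),
        "eos_within_4d_fraction": float((eos_err <= 4).mean()),
        "mean_abs_sos_error_days": float(sos_err.mean()),
        "n_seasons": int(len(sos_err)),
    }


def growing_season_demo(seed: int = 0, shape=(20, 20), n_sites: int = 150,
                        sigma: float = 6.0) -> dict:
    """First-spring and winter maps from one network; season length.

    The two phases share the observer network and differ in their onset
    surfaces (spring ~DOY 100, winter ~DOY 310 at domain center).
    """
    s1, s2, s3 = _seeds(seed, 3)
    world_spring = make_world(sigma=sigma, beta=0.0, seed=s1, shape=shape)
    # winter phase: same terrain, later plane with a weak reversed gradient
    world_winter = make_world(sigma=sigma, beta=0.0, seed=s1, shape=shape,
                              coeffs=(250.0, -0.01, -1.0, 1.5))
    obs_sp = sample_observations(world_spring, n_sites,
                                 years=np.array([2019]), seed=s2)
    obs_wi = sample_observations(world_winter, n_sites,
                                 years=np.array([2019]), seed=s3,
                                 phase_id="132-35")
    g_sp = PhenologyMapper(obs_sp, world_spring.dem).fit().pheno_grid
    g_wi = PhenologyMapper(obs_wi, world_winter.dem).fit().pheno_grid
    length = growing_season_length(g_sp, g_wi)
    true_len = (world_winter.true_field().mean()
                - world_spring.true_field().mean())
    return {"season_length_days": float(length),
            "true_length_days": float(true_len),
            "spring_mean_doy": g_sp.mean(), "winter_mean_doy": g_wi.mean()}
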