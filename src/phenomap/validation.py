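"""Leave-one-out uncertainty of the circle fits and network thinning.

RMSE_LOOCV for a circle is the root mean square of the prediction errors
obtained by excluding each observation in turn,

    RMSE_LOOCV = sqrt( (1/n) sum_i (P_i^(-i) - O_i)^2 ),

where P_i^(-i) is the model prediction at point i from the fit without
point i.  For ordinary least squares the leave-one-out residual equals
the PRESS residual e_i / (1 - h_ii) of the full fit, so no refitting is
needed; the explicit refit path is retained as an independent oracle and
as the fallback when a leverage approaches one.

The observer-thinning experiment repeats the map validation after
randomly discarding observations network-wide (no spatial balancing, as
in real attrition), measuring how the interpolation uncertainty grows as
the network shrinks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .grids import DemGrid, Grid
from .mapping import (MIN_FIT_N, CircleFit, CircleSpec, assign_observations,
                      fit_circle, idw_scalar)
from .observations import ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "loocv_circle",
    "loocv_refit",
    "loocv_surface",
    "SubsampleResult",
    "subsample_uncertainty",
]

_LEVERAGE_TOL = 1e-8  # 1 - h_ii below this forces an explicit refit


def loocv_circle(members: ObservationTable, min_fit_n: int = MIN_FIT_N) -> float:
    """RMSE_LOOCV of one circle via the PRESS identity.

    Requires at least ``min_fit_n + 1`` observations so that every
    leave-one-out fit is still admissible.  Observations whose leverage is
    numerically one fall back to an explicit refit; if the reduced design
    is rank-deficient the point is dropped from the average and logged.
    """
    n = len(members)
    if n < min_fit_n + 1:
        raise ValueError(f"need >= {min_fit_n + 1} observations for LOOCV, got {n}")
    X, y = members.design_matrix()
    res = sm.OLS(y, X).fit()
    h = res.get_influence().hat_matrix_diag
    denom = 1.0 - h
    press = np.empty(n)
    usable = np.ones(n, dtype=bool)
    regular = denom > _LEVERAGE_TOL
    press[regular] = res.resid[regular] / denom[regular]
    for i in np.flatnonzero(~regular):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        if np.linalg.matrix_rank(Xi) < X.shape[1]:
            usable[i] = False
            logger.warning("LOOCV: dropping observation %d (leave-one-out "
                           "design rank-deficient)", i)
            continue
        beta = np.linalg.lstsq(Xi, yi, rcond=None)[0]
        press[i] = y[i] - X[i] @ beta
    if not usable.any():
        raise ValueError("no usable leave-one-out predictions")
    return float(np.sqrt(np.mean(press[usable] ** 2)))


def loocv_refit(members: ObservationTable) -> float:
    """Brute-force RMSE_LOOCV: refit excluding each observation in turn.

    Quadratically slower than the PRESS route; kept as the independent
    oracle it is tested against.
    """
    X, y = members.design_matrix()
    n = len(y)
    errs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        errs[i] = y[i] - X[i] @ beta
    return float(np.sqrt(np.mean(errs**2)))


def loocv_surface(fits: list[CircleFit], circles: list[CircleSpec],
                  grid: Grid | DemGrid) -> Grid:
    """IDW interpolation of the per-circle RMSE_LOOCV to the grid.

    Identical weighting machinery as the coefficient interpolation,
    applied to the scalar RMSE layer.
    """
    values = {f.index: f.rmse_loocv for f in fits
              if f.ok and f.rmse_loocv is not None}
    if not values:
        raise ValueError("no circle carries an RMSE_LOOCV value")
    return idw_scalar(values, fits, circles, grid)


@dataclass
class SubsampleResult:
    """Thinning outcome at one retention percentage."""

    percentage: float
    n_reps: int
    rmse_per_rep: np.ndarray      # mean circle RMSE_LOOCV per repetition (NaN if none)
    n_circles_per_rep: np.ndarray  # fittable circles entering each average

    def __post_init__(self) -> None:
        if not 0 < self.percentage <= 100:
            raise ValueError("percentage must lie in (0, 100]")
        if self.n_reps < 1:
            raise ValueError("need at least one repetition")

    @property
    def available(self) -> bool:
        return bool(np.isfinite(self.rmse_per_rep).any())

    @property
    def mean_rmse(self) -> float:
        return float(np.nanmean(self.rmse_per_rep))

    @property
    def sd_rmse(self) -> float:
        return float(np.nanstd(self.rmse_per_rep))


def subsample_uncertainty(
    table: ObservationTable,
    circles: list[CircleSpec],
    percentages: list[float] = tuple(range(10, 101, 10)),
    n_reps: int = 1000,
    seed: int = 0,
    min_fit_n: int = MIN_FIT_N,
) -> list[SubsampleResult]:
    """Average RMSE_LOOCV after random network-wide thinning.

    For each retention level p, each repetition draws floor(p n / 100)
    observations globally without replacement (no spatial balancing — the
    draw mimics uncontrolled observer attrition), recomputes every
    circle's RMSE_LOOCV on the retained set, and averages over the circles
    that remain fittable; circles that fall below the minimum size are
    excluded from that repetition's average rather than zero-filled.
    Repetition RNG streams are spawned from one master seed, so individual
    repetitions are independent yet the whole experiment is reproducible.
    At 100% retention every repetition equals the full-data average.
    """
    if len(table) == 0:
        raise ValueError("empty observation table")
    n = len(table)
    master = np.random.SeedSequence(seed)
    results = []
    for p in percentages:
        if not 0 < p <= 100:
            raise ValueError(f"percentage {p} outside (0, 100]")
        k = int(np.floor(p * n / 100.0))
        reps = 1 if p == 100 else n_reps  # the 100% draw is deterministic
        child_seeds = master.spawn(reps)
        rmse_reps = np.full(n_reps, np.nan)
        ncirc_reps = np.zeros(n_reps, dtype=int)
        for r in range(reps):
            rng = np.random.default_rng(child_seeds[r])
            idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
            sub = table.subset(np.sort(idx))
            members = assign_observations(circles, sub)
            vals = []
            for c in circles:
                rows = members[c.index]
                if len(rows) < min_fit_n + 1:
                    continue
                csub = sub.subset(rows)
                fit = fit_circle(csub, c.index, min_fit_n)
                if not fit.ok:
                    continue
                try:
                    vals.append(loocv_circle(csub, min_fit_n))
                except ValueError:
                    continue
            if vals:
                rmse_reps[r] = np.mean(vals)
                ncirc_reps[r] = len(vals)
        if reps == 1:  # broadcast the deterministic 100% value
            rmse_reps[:] = rmse_reps[0]
            ncirc_reps[:] = ncirc_reps[0]
        res = SubsampleResult(float(p), n_reps, rmse_reps, ncirc_reps)
        if not res.available:
            logger.warning("retention %g%%: no circle fittable in any repetition", p)
        else:
            logger.info("retention %g%%: mean RMSE_LOOCV %.2f days over %d reps",
                        p, res.mean_rmse, n_reps)
        results.append(res)
    return results
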