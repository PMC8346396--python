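"""Circle layout, per-circle regression, IDW and model evaluation."""

import numpy as np
import pandas as pd
import pytest

import phenomap as pm
from phenomap.grids import anomaly_map, mask_elevation
from phenomap.mapping import CircleFit, apply_model, idw_coefficients
from phenomap.observations import ObservationTable


def _table(lat, lon, elev, doy, year=2019, phase="p"):
    n = len(lat)
    return ObservationTable(pd.DataFrame({
        "station_id": [f"s{i}" for i in range(n)], "lat": lat, "lon": lon,
        "elev": elev, "year": year, "phase_id": phase, "doy": doy,
    }))


def _float_table(lat, lon, elev, doy):
    df = pd.DataFrame({
        "station_id": [f"s{i}" for i in range(len(lat))], "lat": lat,
        "lon": lon, "elev": elev, "year": 2019, "phase_id": "p", "doy": doy,
    })
    return ObservationTable._from_validated(df)


class TestBuildCircles:
    def test_even_spacing_on_integer_bbox(self):
        circles = pm.build_circles((0, 4, 0, 5), 5, 6)
        assert len(circles) == 30
        lats = sorted({c.center_lat for c in circles})
        lons = sorted({c.center_lon for c in circles})
        assert lats == [0, 1, 2, 3, 4]
        assert lons == [0, 1, 2, 3, 4, 5]

    def test_single_circle_at_bbox_center(self):
        (c,) = pm.build_circles((47, 51, 9, 13), 1, 1)
        assert (c.center_lat, c.center_lon) == (49, 11)

    def test_default_layout_is_30_circles_radius_195(self):
        circles = pm.build_circles((47, 55, 6, 15))
        assert len(circles) == 30
        assert all(c.radius == 1.95 for c in circles)

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            pm.build_circles((47, 47, 9, 13), 5, 6)


class TestAssignment:
    def test_membership_rules(self):
        circles = pm.build_circles((0, 4, 0, 4), 2, 2, radius=2.5)
        # obs 0 at a center; obs 1 equidistant (d=2) from two centers;
        # obs 2 at the middle, d=2.83 from every corner center
        t = _table([0.0, 0.0, 2.0], [0.0, 2.0, 2.0],
                   [100, 100, 100], [90, 91, 92])
        members = pm.assign_observations(circles, t)
        by_center = {(c.center_lat, c.center_lon): members[c.index]
                     for c in circles}
        assert 0 in by_center[(0, 0)]          # at the center
        assert 1 in by_center[(0, 0)]          # equidistant: in both
        assert 1 in by_center[(0, 4)]
        for idx in members.values():           # middle point uncovered
            assert 2 not in idx


class TestFitCircle:
    def test_noiseless_plane_recovered_to_1e9(self):
        rng = np.random.default_rng(1)
        lat = rng.uniform(47, 50, 10)
        lon = rng.uniform(9, 13, 10)
        elev = rng.uniform(0, 1500, 10)
        doy = 300 + 0.01 * elev + 2 * lon - 3 * lat
        fit = pm.fit_circle(_float_table(lat, lon, elev, doy))
        assert np.allclose(fit.coeffs, [300, 0.01, 2, -3], atol=1e-9)

    def test_constant_response_gives_zero_slopes(self):
        rng = np.random.default_rng(2)
        fit = pm.fit_circle(_table(rng.uniform(47, 50, 12),
                                   rng.uniform(9, 13, 12),
                                   rng.uniform(0, 1500, 12), [100] * 12))
        assert np.allclose(fit.coeffs, [100, 0, 0, 0], atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        lat = rng.uniform(47, 50, 50)
        lon = rng.uniform(9, 13, 50)
        elev = rng.uniform(0, 1500, 50)
        doy = 100 + 0.02 * elev + lon - 2 * lat + rng.normal(0, 6, 50)
        t = _float_table(lat, lon, elev, doy)
        fit = pm.fit_circle(t)
        X, y = t.design_matrix()
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent route
        assert np.allclose(fit.coeffs, beta, atol=1e-8)

    def test_too_few_observations_marks_failure(self):
        fit = pm.fit_circle(_table([48] * 3, [11] * 3, [100, 200, 300],
                                   [90, 91, 92]))
        assert not fit.ok and fit.reason == "too-few-observations"

    def test_rank_deficiency_marks_failure_not_exception(self):
        # all sites at one location: lon/lat/elev collinear with intercept
        fit = pm.fit_circle(_table([48] * 10, [11] * 10, [500] * 10,
                                   list(range(90, 100))))
        assert not fit.ok and fit.reason == "rank-deficient"

    def test_point_on_fitted_plane_leaves_fit_unchanged(self):
        rng = np.random.default_rng(4)
        lat = rng.uniform(47, 50, 20)
        lon = rng.uniform(9, 13, 20)
        elev = rng.uniform(0, 1500, 20)
        doy = 100 + 0.02 * elev + lon - 2 * lat + rng.normal(0, 6, 20)
        t = _float_table(lat, lon, elev, doy)
        fit = pm.fit_circle(t)
        new_lat, new_lon, new_elev = 48.5, 11.0, 700.0
        new_doy = fit.coeffs @ [1, new_elev, new_lon, new_lat]
        t2 = _float_table(np.r_[lat, new_lat], np.r_[lon, new_lon],
                          np.r_[elev, new_elev], np.r_[doy, new_doy])
        fit2 = pm.fit_circle(t2)
        assert np.allclose(fit.coeffs, fit2.coeffs, atol=1e-9)


class TestIdw:
    def _grid(self):
        geom = pm.GridGeometry(north=1.0, west=0.0, dlat=1.0, dlon=1.0,
                               nrows=1, ncols=1)
        return pm.DemGrid(geom, np.array([[100.0]]), np.ones((1, 1), bool))

    def test_hand_evaluated_weighted_mean(self):
        # contributors at distances 1 and 2 with a0 = 10 and 20:
        # (10/1 + 20/2) / (1 + 1/2) = 13.333...
        circles = [pm.CircleSpec(0, 1.0, 1.0, 3.0), pm.CircleSpec(1, 1.0, 2.0, 3.0)]
        fits = [CircleFit(0, np.array([10.0, 0, 0, 0]), 10),
                CircleFit(1, np.array([20.0, 0, 0, 0]), 10)]
        cg = idw_coefficients(fits, circles, self._grid())
        assert cg.values[0, 0, 0] == pytest.approx(40.0 / 3.0, abs=1e-12)

    def test_identical_contributors_reproduce_vector(self):
        coeffs = np.array([100.0, 0.02, 1.5, -2.0])
        circles = [pm.CircleSpec(i, 1.0, float(i), 5.0) for i in range(4)]
        fits = [CircleFit(i, coeffs.copy(), 10) for i in range(4)]
        cg = idw_coefficients(fits, circles, self._grid())
        assert np.allclose(cg.values[:, 0, 0], coeffs, atol=1e-12)

    def test_cell_on_center_copies_bit_exactly(self):
        coeffs_a = np.array([123.456789, 0.0123, 1.1, -2.2])
        circles = [pm.CircleSpec(0, 1.0, 0.0, 3.0), pm.CircleSpec(1, 1.0, 2.0, 3.0)]
        fits = [CircleFit(0, coeffs_a, 10),
                CircleFit(1, np.array([99.0, 0, 0, 0]), 10)]
        cg = idw_coefficients(fits, circles, self._grid())
        assert np.array_equal(cg.values[:, 0, 0], coeffs_a)

    def test_uncovered_cell_masked_with_warning(self):
        circles = [pm.CircleSpec(0, 50.0, 50.0, 0.5)]
        fits = [CircleFit(0, np.zeros(4), 10)]
        with pytest.warns(UserWarning, match="no fitted circle"):
            cg = idw_coefficients(fits, circles, self._grid())
        assert not cg.mask.any()

    def test_convex_combination_property(self):
        rng = np.random.default_rng(5)
        geom = pm.GridGeometry(north=50.0, west=9.0, dlat=0.2, dlon=0.2,
                               nrows=10, ncols=10)
        dem = pm.DemGrid(geom, rng.uniform(0, 900, (10, 10)),
                         np.ones((10, 10), bool))
        circles = pm.build_circles(geom.bbox(), 2, 3, radius=3.0)
        fits = [CircleFit(c.index, rng.normal(0, 10, 4), 10) for c in circles]
        cg = idw_coefficients(fits, circles, dem)
        vals = np.stack([f.coeffs for f in fits])
        for k in range(4):
            assert np.all(cg.values[k][cg.mask] >= vals[:, k].min() - 1e-12)
            assert np.all(cg.values[k][cg.mask] <= vals[:, k].max() + 1e-12)


class TestApplyAndMask:
    def test_arithmetic_example(self):
        geom = pm.GridGeometry(north=48.0, west=11.0, dlat=1.0, dlon=1.0,
                               nrows=1, ncols=1)
        dem = pm.DemGrid(geom, np.array([[500.0]]), np.ones((1, 1), bool))
        cg = pm.CoefficientGrid(geom,
                                np.array([300.0, 0.01, 2.0, -3.0]).reshape(4, 1, 1),
                                np.ones((1, 1), bool))
        out = apply_model(cg, dem)
        assert out.values[0, 0] == pytest.approx(300 + 5 + 22 - 144)

    def test_intercept_only_gives_uniform_grid(self, flat_world):
        geom = flat_world.geometry
        vals = np.zeros((4, *geom.shape))
        vals[0] = 77.0
        cg = pm.CoefficientGrid(geom, vals, np.ones(geom.shape, bool))
        out = apply_model(cg, flat_world.dem)
        assert np.allclose(out.values[out.mask], 77.0)

    def test_geometry_mismatch_raises(self, flat_world, small_geom):
        cg = pm.CoefficientGrid(small_geom, np.zeros((4, 3, 3)),
                                np.ones((3, 3), bool))
        with pytest.raises(ValueError, match="geometr"):
            apply_model(cg, flat_world.dem)

    def test_elevation_mask_strict_threshold(self):
        geom = pm.GridGeometry(north=48.0, west=11.0, dlat=0.1, dlon=0.1,
                               nrows=1, ncols=4)
        dem = pm.DemGrid(geom, np.array([[800.0, 999.0, 1000.0, 1500.0]]),
                         np.ones((1, 4), bool))
        g = pm.Grid(geom, np.ones((1, 4)), np.ones((1, 4), bool))
        masked = mask_elevation(g, dem, 1000.0)
        assert list(masked.mask[0]) == [True, True, False, False]
        unchanged = mask_elevation(g, dem, np.inf)
        assert unchanged.mask.all()
        with pytest.warns(UserWarning, match="every cell"):
            mask_elevation(g, dem, 0.0)


class TestAnomaly:
    def test_centering(self, small_geom):
        vals = np.zeros((3, 3))
        vals[0] = [10, 20, 30]
        mask = np.array([[1, 1, 1], [0, 0, 0], [0, 0, 0]], bool)
        a = anomaly_map(pm.Grid(small_geom, vals, mask))
        assert np.allclose(a.values[0], [-10, 0, 10])
        assert abs(np.nansum(a.values[a.mask])) < 1e-9

    def test_single_cell_is_zero(self):
        geom = pm.GridGeometry(north=1, west=1, dlat=1, dlon=1, nrows=1, ncols=1)
        a = anomaly_map(pm.Grid(geom, np.array([[42.0]]), np.ones((1, 1), bool)))
        assert a.values[0, 0] == 0.0

    def test_fully_masked_raises(self, small_geom):
        g = pm.Grid(small_geom, np.zeros((3, 3)), np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            anomaly_map(g)


def test_coefficient_grid_invariant_to_row_permutation(noisy_obs, noisy_world):
    res1 = pm.PhenologyMapper(noisy_obs, noisy_world.dem).fit()
    perm = np.random.default_rng(6).permutation(len(noisy_obs))
    res2 = pm.PhenologyMapper(noisy_obs.subset(perm), noisy_world.dem).fit()
    m = res1.coefficient_grid.mask
    assert np.allclose(res1.coefficient_grid.values[:, m],
                       res2.coefficient_grid.values[:, m], atol=1e-9)
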