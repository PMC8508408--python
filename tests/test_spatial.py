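"""Spatial methods against independent oracles: brute-force KDE evaluation,
closed-form/statsmodels OLS in the large-bandwidth limit, per-location WLS,
and permutation-test calibration for Moran's I."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrscore import spatial
from mrscore._geo import aeqd_project, haversine_m
from mrscore.errors import ConfigurationError
from mrscore.synthetic import generate_gwr_surface


class TestProjection:
    def test_radial_distances_exact(self):
        # azimuthal equidistant: distances from the centre equal great-circle
        rng = np.random.default_rng(2)
        lon = 110 + rng.normal(0, 3, 20)
        lat = 35 + rng.normal(0, 3, 20)
        x, y = aeqd_project(lon, lat, 110.0, 35.0)
        planar = np.hypot(x, y)
        geodesic = haversine_m(110.0, 35.0, lon, lat)
        assert np.allclose(planar, geodesic, rtol=1e-9)


class TestKde:
    def test_single_point_closed_form(self):
        h = 0.7
        val = spatial.kde_at(np.array([[0.0, 0.0]]), np.array([[0.0, 0.0]]), h)
        assert val[0] == pytest.approx(1.0 / (2 * math.pi * h * h))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 2, (50, 2))
        queries = rng.normal(0, 2, (10, 2))
        h = 0.9
        mine = spatial.kde_at(pts, queries, h)
        brute = np.array([
            sum(math.exp(-((q - p) ** 2).sum() / (2 * h * h))
                / (2 * math.pi * h * h) for p in pts) / len(pts)
            for q in queries])
        assert np.abs(mine - brute).max() < 1e-10

    def test_integrates_to_one(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 3, (40, 2))
        surf = spatial.kde(pts, h=0.8)
        assert surf.integral() == pytest.approx(1.0, abs=0.02)

    def test_mixture_linearity(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (30, 2))
        b = rng.normal(5, 1, (20, 2))
        q = rng.uniform(-2, 7, (15, 2))
        h = 0.8
        combined = spatial.kde_at(np.vstack([a, b]), q, h)
        mix = (30 * spatial.kde_at(a, q, h) + 20 * spatial.kde_at(b, q, h)) / 50
        assert np.allclose(combined, mix, atol=1e-14)

    def test_density_decays_from_isolated_point(self):
        pts = np.array([[0.0, 0.0]])
        q = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        vals = spatial.kde_at(pts, q, 1.0)
        assert (np.diff(vals) < 0).all()

    def test_invalid_bandwidth(self):
        with pytest.raises(ConfigurationError):
            spatial.kde_at(np.zeros((1, 2)), np.zeros((1, 2)), 0.0)

    def test_ascii_grid_round_trip(self, tmp_path):
        surf = spatial.kde(np.zeros((1, 2)), h=1.0, nx=16, ny=16)
        path = tmp_path / "grid.asc"
        surf.write_ascii_grid(path)
        data = np.loadtxt(path, skiprows=6)[::-1]
        assert np.allclose(data, surf.density, rtol=1e-6)


class TestGwr:
    def test_large_bandwidth_equals_global_ols(self):
        df = generate_gwr_surface(200, seed=5, noise_sd=0.3)
        coords = df[["u", "v"]].to_numpy()
        fit = spatial.gwr_fit(coords, df["y"].to_numpy(), df["x"].to_numpy(),
                              bandwidth=1e9)
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert np.abs(fit.coefficients - ols.params.to_numpy()).max() < 1e-6

    def test_perfect_linear_fit(self):
        df = generate_gwr_surface(
            60, seed=2, noise_sd=0.0,
            beta_fields={"beta0": lambda u, v: np.full_like(u, 1.0),
                         "beta1": lambda u, v: np.full_like(u, 2.0)})
        fit = spatial.gwr_fit(df[["u", "v"]].to_numpy(), df["y"].to_numpy(),
                              df["x"].to_numpy(), bandwidth=0.3)
        assert np.abs(fit.residuals).max() < 1e-9
        assert np.allclose(fit.local_r2, 1.0)

    def test_matches_per_location_wls_oracle(self):
        df = generate_gwr_surface(80, seed=6, noise_sd=0.2)
        coords = df[["u", "v"]].to_numpy()
        b = 0.25
        fit = spatial.gwr_fit(coords, df["y"].to_numpy(), df["x"].to_numpy(), b)
        design = sm.add_constant(df["x"]).to_numpy()
        for i in (0, 17, 44, 79):
            d2 = ((coords - coords[i]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (b * b))
            wls = sm.WLS(df["y"], design, weights=w).fit()
            assert np.allclose(fit.coefficients[i], wls.params, atol=1e-8)

    def test_coefficient_recovery_beats_global_ols(self):
        df = generate_gwr_surface(400, seed=11, noise_sd=0.1)
        coords = df[["u", "v"]].to_numpy()
        b, _ = spatial.select_bandwidth(coords, df["y"].to_numpy(),
                                        df["x"].to_numpy(), 0.02, 2.0)
        fit = spatial.gwr_fit(coords, df["y"].to_numpy(), df["x"].to_numpy(), b)
        ols_b1 = sm.OLS(df["y"], sm.add_constant(df["x"])).fit().params.iloc[1]
        rmse_gwr = np.sqrt(((fit.coefficients[:, 1] - df["beta1_true"]) ** 2).mean())
        rmse_ols = np.sqrt(((ols_b1 - df["beta1_true"]) ** 2).mean())
        assert rmse_gwr < rmse_ols

    def test_translation_invariance(self):
        df = generate_gwr_surface(100, seed=3, noise_sd=0.2)
        coords = df[["u", "v"]].to_numpy()
        fit1 = spatial.gwr_fit(coords, df["y"].to_numpy(), df["x"].to_numpy(), 0.3)
        fit2 = spatial.gwr_fit(coords + [123.0, -45.0], df["y"].to_numpy(),
                               df["x"].to_numpy(), 0.3)
        assert np.allclose(fit1.fitted, fit2.fitted, atol=1e-8)

    def test_kernel_form(self):
        # w_ii = 1, symmetric, strictly decreasing with distance
        d = np.array([0.0, 1.0, 2.0, 3.0])
        w = np.exp(-d ** 2 / 1.5 ** 2)
        assert w[0] == 1.0
        assert (np.diff(w) < 0).all()

    def test_residual_identity(self):
        df = generate_gwr_surface(60, seed=4, noise_sd=0.5)
        fit = spatial.gwr_fit(df[["u", "v"]].to_numpy(), df["y"].to_numpy(),
                              df["x"].to_numpy(), 0.4)
        assert np.allclose(fit.residuals, df["y"].to_numpy() - fit.fitted)
        assert ((fit.local_r2 >= 0) & (fit.local_r2 <= 1)).all()


class TestBandwidthSelection:
    def test_minimizer_beats_trace(self):
        df = generate_gwr_surface(150, seed=21, noise_sd=0.2)
        coords = df[["u", "v"]].to_numpy()
        b, trace = spatial.select_bandwidth(coords, df["y"].to_numpy(),
                                            df["x"].to_numpy(), 0.05, 5.0)
        best = trace.loc[trace["bandwidth"] == b, "aicc"].item()
        assert best <= trace["aicc"].min() + 1e-12

    def test_deterministic(self):
        df = generate_gwr_surface(120, seed=22, noise_sd=0.2)
        coords = df[["u", "v"]].to_numpy()
        args = (coords, df["y"].to_numpy(), df["x"].to_numpy(), 0.05, 5.0)
        assert spatial.select_bandwidth(*args)[0] == \
            spatial.select_bandwidth(*args)[0]

    def test_constant_field_prefers_global_model(self):
        fields = {"beta0": lambda u, v: np.full_like(u, 1.0),
                  "beta1": lambda u, v: np.full_like(u, 2.0)}
        df = generate_gwr_surface(150, seed=23, beta_fields=fields, noise_sd=0.3)
        coords = df[["u", "v"]].to_numpy()
        b, trace = spatial.select_bandwidth(coords, df["y"].to_numpy(),
                                            df["x"].to_numpy(), 0.05, 50.0)
        # with no spatial variation the widest bandwidths win on AICc
        assert b > 5.0

    def test_invalid_range(self):
        with pytest.raises(ConfigurationError):
            spatial.select_bandwidth(np.zeros((10, 2)), np.zeros(10),
                                     np.zeros(10), 1.0, 0.5)


class TestMoransI:
    def test_expected_value_closed_form(self):
        rng = np.random.default_rng(1)
        res = spatial.morans_i(rng.normal(size=10), rng.uniform(0, 1, (10, 2)),
                               k=3, permutations=99)
        assert res.expected == pytest.approx(-1.0 / 9.0)

    def test_null_calibration(self):
        """i.i.d. values show no significant autocorrelation in >= 18/20
        seeded replicates."""
        ok = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            coords = rng.uniform(0, 1, (80, 2))
            values = rng.normal(size=80)
            ok += spatial.morans_i(values, coords, seed=s).p_value > 0.05
        assert ok >= 18

    def test_smooth_gradient_detected(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 1, (80, 2))
        res = spatial.morans_i(coords[:, 0] + coords[:, 1], coords, seed=0)
        assert res.i > res.expected
        assert res.p_value <= 0.001

    def test_constant_values_not_applicable(self):
        rng = np.random.default_rng(1)
        res = spatial.morans_i(np.full(20, 3.0), rng.uniform(0, 1, (20, 2)))
        assert not res.applicable and np.isnan(res.i)


class TestReport:
    def test_perfect_fit_summary(self):
        df = generate_gwr_surface(
            40, seed=2, noise_sd=0.0,
            beta_fields={"beta0": lambda u, v: np.full_like(u, 1.0),
                         "beta1": lambda u, v: np.full_like(u, 2.0)})
        fit = spatial.gwr_fit(df[["u", "v"]].to_numpy(), df["y"].to_numpy(),
                              df["x"].to_numpy(), 0.5)
        table, summary = spatial.gwr_report(fit)
        assert summary["mean_local_r2"] == pytest.approx(1.0)
        assert summary["sum_std_residuals"] == pytest.approx(0.0, abs=1e-6)

    def test_csv_round_trip(self, tmp_path):
        df = generate_gwr_surface(40, seed=7, noise_sd=0.3)
        fit = spatial.gwr_fit(df[["u", "v"]].to_numpy(), df["y"].to_numpy(),
                              df["x"].to_numpy(), 0.4, column_names=("x",))
        table, _ = spatial.gwr_report(fit, index=[f"c{i}" for i in range(40)])
        path = tmp_path / "gwr.csv"
        table.to_csv(path)
        again = pd.read_csv(path, index_col=0)
        pd.testing.assert_frame_equal(table, again, check_exact=False,
                                      rtol=1e-14)

    def test_gdp_drives_scores_more_than_population(self, default_frame_scores):
        """On the default synthetic national dataset, the composite score is
        better explained locally by GDP than by population (two fits on the
        same dataset at a common bandwidth)."""
        cities, scores = default_frame_scores
        data = scores.merge(cities, on="city_code", suffixes=("", "_c"))
        x, y = spatial.project_cities(data["longitude"], data["latitude"])
        coords = np.column_stack([x, y])
        r2 = {}
        for cov in ("gdp", "population"):
            xv = ((data[cov] - data[cov].mean()) / data[cov].std()).to_numpy()
            fit = spatial.gwr_fit(coords, data["mrsc"].to_numpy(float), xv,
                                  500_000.0)
            r2[cov] = fit.local_r2.mean()
        assert r2["gdp"] > r2["population"]
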