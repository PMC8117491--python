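"""Variograms, kriging variants, censoring rules and the censored-data EM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expochain import geostat
from expochain.geostat import (
    VariogramModel,
    censor_bounds,
    empirical_variogram,
    external_drift_kriging,
    fit_variogram,
    impute_censored_em,
    ordinary_kriging,
    regression_kriging,
    simulate_gaussian_field,
)
from expochain.geostat import test_anisotropy as anisotropy_test
from expochain.region import STATUS_BELOW_LOQ, STATUS_NON_DETECT, STATUS_QUANTIFIED


def brute_force_ok(coords, values, model, target):
    """Independent direct assembly + solve of the ordinary kriging system."""
    n = len(values)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                A[i, j] = model.gamma(np.linalg.norm(coords[i] - coords[j]))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.array([model.gamma(np.linalg.norm(c - target)) for c in coords] + [1.0])
    sol = np.linalg.solve(A, b)
    return float(sol[:n] @ values), float(sol[:n] @ b[:n] + sol[n])


class TestEmpiricalVariogram:
    def test_constant_field_zero(self, rng):
        coords = rng.uniform(0, 1000, (30, 2))
        emp = empirical_variogram(coords, np.full(30, 3.2), np.array([0, 500, 1000, 1500]))
        assert (emp.gamma == 0).all()

    def test_two_point_hand_value(self):
        emp = empirical_variogram(np.array([[0.0, 0.0], [100.0, 0.0]]),
                                  np.array([0.0, 2.0]), np.array([0.0, 200.0]))
        assert len(emp) == 1
        assert emp.gamma.iloc[0] == pytest.approx(2.0)  # (1/2) * 2^2

    def test_white_noise_flat_at_unit_sill(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(0, 10000, (200, 2))
        vals = rng.standard_normal(200)
        emp = empirical_variogram(coords, vals, np.linspace(0, 8000, 9))
        # gamma_hat ~ sigma^2 = 1 within 3 sigma of the pair-count sampling error
        for r in emp.itertuples():
            se = np.sqrt(2.0 / r.n_pairs)  # var of mean of 0.5*(z_i-z_j)^2 ~ chi2_1
            assert abs(r.gamma - 1.0) <= 3 * se * 1.5

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            empirical_variogram(np.zeros((1, 2)), np.zeros(1), np.array([0.0, 1.0]))


class TestFitVariogram:
    def test_exact_spherical_recovery(self):
        truth = VariogramModel("spherical", 0.0, 1.0, 5000.0)
        lags = np.linspace(250, 9750, 20)
        emp = pd.DataFrame({"direction": np.nan, "lag": lags,
                            "gamma": truth.gamma(lags), "n_pairs": 100})
        fit = fit_variogram(emp, family="spherical")
        assert fit.nugget == pytest.approx(0.0, abs=1e-6)
        assert fit.partial_sill == pytest.approx(1.0, abs=1e-6)
        assert fit.range_ == pytest.approx(5000.0, rel=1e-6)

    def test_pure_nugget_data(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10000, (300, 2))
        vals = rng.standard_normal(300)
        emp = empirical_variogram(coords, vals, np.linspace(0, 7000, 10))
        fit = fit_variogram(emp)
        # flat curve: either absorbed in the nugget or a tiny-range structure
        assert fit.nugget > 0.5 or fit.range_ < 1000.0

    def test_recovery_on_simulated_field(self):
        truth = VariogramModel("spherical", 0.0, 1.0, 8000.0)
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 40000, (400, 2))
        z = simulate_gaussian_field(coords, truth, seed=7)
        emp = empirical_variogram(coords, z, np.linspace(1e-9, 20000, 13))
        fit = fit_variogram(emp, family="spherical")
        assert 0.7 * 8000 <= fit.range_ <= 1.3 * 8000
        assert 0.7 <= fit.sill <= 1.3


class TestAnisotropy:
    def _directional(self, ratio, seed):
        truth = VariogramModel("spherical", 0.0, 1.0, 8000.0,
                               anisotropy_ratio=1.0 / ratio, anisotropy_angle=0.0)
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 50000, (500, 2))
        z = simulate_gaussian_field(coords, truth, seed=seed)
        return empirical_variogram(coords, z, np.linspace(1e-9, 20000, 11),
                                   directions=[0.0, 90.0], angle_tol=20.0)

    def test_identical_directions_isotropic(self):
        lags = np.linspace(250, 9750, 15)
        truth = VariogramModel("spherical", 0.0, 1.0, 5000.0)
        emp = pd.concat([
            pd.DataFrame({"direction": d, "lag": lags, "gamma": truth.gamma(lags),
                          "n_pairs": 50})
            for d in (0.0, 90.0)
        ])
        out = anisotropy_test(emp)
        assert not out["anisotropic"]
        assert out["ratio"] == pytest.approx(1.0, rel=1e-3)

    def test_geometric_anisotropy_recovered(self):
        emp = self._directional(ratio=2.0, seed=3)
        out = anisotropy_test(emp)
        assert out["anisotropic"]
        assert 1.5 <= out["ratio"] <= 2.7

    def test_threshold_rule(self):
        lags = np.linspace(250, 9750, 15)
        m0 = VariogramModel("spherical", 0.0, 1.0, 5000.0)
        m1 = VariogramModel("spherical", 0.0, 1.0, 7000.0)  # ratio 1.4 < 1.5
        emp = pd.concat([
            pd.DataFrame({"direction": 0.0, "lag": lags, "gamma": m0.gamma(lags),
                          "n_pairs": 50}),
            pd.DataFrame({"direction": 90.0, "lag": lags, "gamma": m1.gamma(lags),
                          "n_pairs": 50}),
        ])
        out = anisotropy_test(emp, threshold=1.5)
        assert not out["anisotropic"]


class TestKriging:
    MODEL = VariogramModel("spherical", 0.0, 1.0, 5000.0)

    def test_single_sample_constant_prediction(self):
        pred, var = ordinary_kriging(np.array([[0.0, 0.0]]), np.array([4.2]),
                                     self.MODEL, np.array([[100.0, 5000.0]]))
        assert pred[0] == pytest.approx(4.2)

    def test_exact_at_data_with_zero_nugget(self, rng):
        coords = rng.uniform(0, 10000, (8, 2))
        vals = rng.normal(0, 1, 8)
        pred, var = ordinary_kriging(coords, vals, self.MODEL, coords)
        np.testing.assert_allclose(pred, vals, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_matches_brute_force_solve(self, rng):
        coords = rng.uniform(0, 10000, (5, 2))
        vals = rng.normal(0, 1, 5)
        targets = rng.uniform(0, 10000, (6, 2))
        pred, var = ordinary_kriging(coords, vals, self.MODEL, targets)
        for k, t in enumerate(targets):
            bp, bv = brute_force_ok(coords, vals, self.MODEL, t)
            assert pred[k] == pytest.approx(bp, abs=1e-9)
            assert var[k] == pytest.approx(bv, abs=1e-9)

    def test_variance_nonnegative(self, rng):
        coords = rng.uniform(0, 10000, (20, 2))
        vals = rng.normal(0, 1, 20)
        _, var = ordinary_kriging(coords, vals, self.MODEL, rng.uniform(0, 10000, (50, 2)))
        assert (var >= 0).all()

    def test_duplicate_locations_averaged(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5000.0, 0.0]])
        vals = np.array([1.0, 3.0, 0.0])
        with pytest.warns(UserWarning, match="duplicate"):
            pred, _ = ordinary_kriging(coords, vals, self.MODEL, np.array([[0.0, 0.0]]))
        assert pred[0] == pytest.approx(2.0, abs=1e-8)

    def test_local_neighborhood_large_n(self, rng):
        coords = rng.uniform(0, 50000, (600, 2))
        vals = rng.normal(0, 1, 600)
        pred, var = ordinary_kriging(coords, vals, self.MODEL, coords[:3])
        np.testing.assert_allclose(pred, vals[:3], atol=1e-7)


class TestExternalDrift:
    MODEL = VariogramModel("spherical", 0.0, 1.0, 5000.0)

    def test_constant_auxiliary_equals_ok(self, rng):
        coords = rng.uniform(0, 10000, (12, 2))
        vals = rng.normal(0, 1, 12)
        targets = rng.uniform(0, 10000, (7, 2))
        p_ok, _ = ordinary_kriging(coords, vals, self.MODEL, targets)
        p_ed, _ = external_drift_kriging(coords, vals, self.MODEL,
                                         np.full(12, 3.3), targets, np.full(7, 3.3))
        np.testing.assert_allclose(p_ed, p_ok, atol=1e-9)

    def test_exact_affine_drift_reproduced(self, rng):
        coords = rng.uniform(0, 10000, (15, 2))
        aux = coords[:, 0] / 1000.0
        vals = 2.0 + 0.5 * aux  # exactly affine in the auxiliary
        targets = rng.uniform(0, 10000, (9, 2))
        aux_t = targets[:, 0] / 1000.0
        pred, _ = external_drift_kriging(coords, vals, self.MODEL, aux, targets, aux_t)
        np.testing.assert_allclose(pred, 2.0 + 0.5 * aux_t, atol=1e-7)

    def test_missing_auxiliary_at_target_errors(self, rng):
        coords = rng.uniform(0, 10000, (5, 2))
        with pytest.raises(ValueError, match="auxiliary"):
            external_drift_kriging(coords, np.zeros(5), self.MODEL,
                                   np.arange(5.0), coords, np.array([np.nan] * 5))

    def test_edk_beats_ok_on_drifted_field(self):
        # field = 2*aux + spherical residual; leave-one-out RMSE comparison
        rng = np.random.default_rng(15)
        n = 300
        coords = rng.uniform(0, 40000, (n, 2))
        aux = coords[:, 0] / 10000.0 + np.sin(coords[:, 1] / 8000.0)
        resid = simulate_gaussian_field(
            coords, VariogramModel("spherical", 0.0, 0.25, 8000.0), seed=15
        )
        z = 2.0 * aux + resid
        model = VariogramModel("spherical", 0.0, 0.25, 8000.0)
        idx = rng.choice(n, 60, replace=False)
        err_ok, err_ed = [], []
        for i in idx:
            mask = np.arange(n) != i
            p1, _ = ordinary_kriging(coords[mask], z[mask], model, coords[i:i + 1])
            p2, _ = external_drift_kriging(coords[mask], z[mask], model, aux[mask],
                                           coords[i:i + 1], aux[i:i + 1])
            err_ok.append(p1[0] - z[i])
            err_ed.append(p2[0] - z[i])
        assert np.std(err_ed) < np.std(err_ok)


class TestRegressionKriging:
    def test_zero_residuals_returns_trend(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        coords = rng.uniform(0, 10000, (50, 2))
        cov = rng.uniform(0, 1, 50)
        z = np.where(cov > 0.5, 2.0, 0.0)  # an interpolating tree fits this exactly
        pred, trend, _ = regression_kriging(
            coords, z, cov, cov[:10], coords[:10], seed=0,
            learner=DecisionTreeRegressor(random_state=0),
        )
        np.testing.assert_allclose(trend, z[:10], atol=1e-9)
        np.testing.assert_allclose(pred, z[:10], atol=1e-9)

    def test_constant_covariates_warns_and_degenerates(self, rng):
        coords = rng.uniform(0, 10000, (30, 2))
        z = rng.normal(0, 1, 30)
        with pytest.warns(UserWarning, match="constant covariates"):
            regression_kriging(coords, z, np.ones(30), np.ones(5), coords[:5], seed=0)

    def test_rk_beats_edk_on_step_trend(self):
        rng = np.random.default_rng(21)
        n = 300
        coords = rng.uniform(0, 40000, (n, 2))
        aux = rng.uniform(-1, 1, n)
        resid = simulate_gaussian_field(
            coords, VariogramModel("spherical", 0.0, 0.04, 8000.0), seed=21
        )
        z = np.where(aux > 0, 2.0, 0.0) + resid  # strongly nonlinear in aux
        model = VariogramModel("spherical", 0.0, 0.04, 8000.0)
        idx = rng.choice(n, 50, replace=False)
        err_ed, err_rk = [], []
        for i in idx:
            m = np.arange(n) != i
            p_ed, _ = external_drift_kriging(coords[m], z[m], model, aux[m],
                                             coords[i:i + 1], aux[i:i + 1])
            p_rk, _, _ = regression_kriging(coords[m], z[m], aux[m], aux[i:i + 1],
                                            coords[i:i + 1], seed=0)
            err_ed.append(p_ed[0] - z[i])
            err_rk.append(p_rk[0] - z[i])
        assert np.sqrt(np.mean(np.square(err_rk))) < np.sqrt(np.mean(np.square(err_ed)))


class TestCensorBounds:
    def _df(self, status, value=np.nan, lod=0.01, loq=0.03):
        return pd.DataFrame({"status": [status], "value": [value],
                             "LOD": [lod], "LOQ": [loq]})

    @pytest.mark.parametrize(
        "status,value,lb,ub",
        [
            (STATUS_NON_DETECT, np.nan, 0.0, 0.01),
            (STATUS_BELOW_LOQ, np.nan, 0.01, 0.03),
            (STATUS_QUANTIFIED, 0.05, 0.05, 0.05),
        ],
    )
    def test_substitution_rules(self, status, value, lb, ub):
        df = self._df(status, value)
        assert censor_bounds(df, "LB").iloc[0] == pytest.approx(lb)
        assert censor_bounds(df, "UB").iloc[0] == pytest.approx(ub)

    def test_unknown_status_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            censor_bounds(self._df("mystery"), "LB")

    @settings(max_examples=50, derandomize=True)
    @given(
        status=st.sampled_from([STATUS_NON_DETECT, STATUS_BELOW_LOQ, STATUS_QUANTIFIED]),
        lod=st.floats(1e-6, 1.0),
        ratio=st.floats(1.0, 10.0),
        value=st.floats(0.0, 100.0),
    )
    def test_ub_dominates_lb(self, status, lod, ratio, value):
        df = pd.DataFrame({"status": [status], "value": [value],
                           "LOD": [lod], "LOQ": [lod * ratio]})
        lb = censor_bounds(df, "LB").iloc[0]
        ub = censor_bounds(df, "UB").iloc[0]
        assert 0.0 <= lb <= ub


class TestCensoredEM:
    def _censored_bivariate(self, seed, n=500, frac=0.4, corr=0.8):
        rng = np.random.default_rng(seed)
        cov = np.array([[1.0, corr], [corr, 1.0]])
        X = rng.multivariate_normal([0.0, 0.0], cov, n)
        lod = np.quantile(X[:, 0], frac)
        obs = X.copy()
        obs[X[:, 0] < lod, 0] = np.nan
        bounds = np.full_like(obs, np.nan)
        bounds[:, 0] = lod
        return X, obs, bounds, lod

    def test_no_censoring_gives_sample_mean(self, rng):
        X = rng.normal(0, 1, (50, 2))
        res = impute_censored_em(X, np.full_like(X, np.nan), n_boot=1, seed=0)
        np.testing.assert_allclose(res.mean, X.mean(axis=0), atol=1e-12)
        assert res.n_iter == 1

    def test_recovers_mean_better_than_lod_substitution(self):
        X, obs, bounds, lod = self._censored_bivariate(seed=5)
        res = impute_censored_em(obs, bounds, n_boot=1, seed=0)
        naive = np.where(np.isnan(obs[:, 0]), lod, obs[:, 0]).mean()
        assert abs(res.mean[0]) < 0.05
        assert abs(res.mean[0]) < abs(naive)

    def test_bootstrap_determinism(self):
        _, obs, bounds, _ = self._censored_bivariate(seed=6, n=120)
        a = impute_censored_em(obs, bounds, n_boot=2, seed=3)
        b = impute_censored_em(obs, bounds, n_boot=2, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)
        # imputed draws respect the censoring bound
        cens = np.isnan(obs)
        assert (a.draws[:, cens] <= bounds[cens] + 1e-12).all()

    def test_all_censored_errors(self):
        obs = np.full((10, 2), np.nan)
        with pytest.raises(ValueError, match="censored"):
            impute_censored_em(obs, np.zeros((10, 2)), n_boot=1, seed=0)
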