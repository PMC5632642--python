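"""Mixed-model likelihood machinery: oracle agreement, reductions to OLS,
estimation, criteria and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from dendrogrowth import lmm_core as lc
from dendrogrowth import synthetic_data as sd


def _random_instance(rng, n_trees=None, max_years=6, n_fixed=1, n_random=0,
                     gaps=True):
    """Small random dataset + spec + params for oracle comparisons."""
    n_trees = n_trees or int(rng.integers(2, 5))
    fixed = tuple(f"x{i}" for i in range(n_fixed))
    random = fixed[:n_random]
    rows = []
    for j in range(n_trees):
        m = int(rng.integers(3, max_years + 1))
        yrs = np.sort(rng.choice(np.arange(2000, 2000 + max_years + 4),
                                 size=m, replace=False)) if gaps \
            else np.arange(2000, 2000 + m)
        for y in yrs:
            row = {"tree_id": f"T{j}", "year": int(y),
                   "resp": float(rng.normal())}
            for f in fixed:
                row[f] = float(rng.normal())
            rows.append(row)
    df = pd.DataFrame(rows)
    spec = lc.ModelSpec(response="resp", fixed=fixed, random=random, ar1=True)
    data = lc.GroupedData.from_frame(df, spec)
    params = lc.LMMParams(
        beta=rng.normal(size=1 + n_fixed),
        re_sd=np.abs(rng.normal(0.5, 0.3, size=1 + n_random)),
        phi=float(rng.uniform(-0.8, 0.8)),
        sigma=float(rng.uniform(0.3, 1.5)))
    return spec, data, params


def oracle_loglik(data, params):
    """Brute-force density of the stacked response under one big MVN with
    explicitly assembled block covariance."""
    n = data.n_obs
    V = np.zeros((n, n))
    bounds = np.r_[data.starts, n]
    G = np.diag(np.asarray(params.re_sd) ** 2)
    for i in range(data.n_groups):
        lo, hi = bounds[i], bounds[i + 1]
        yrs = data.years[lo:hi]
        d = np.abs(yrs[:, None] - yrs[None, :])
        C = np.sign(params.phi) ** (d % 2) * np.abs(params.phi) ** d.astype(float)
        np.fill_diagonal(C, 1.0)
        Z = data.Z[lo:hi]
        V[lo:hi, lo:hi] = Z @ G @ Z.T + params.sigma ** 2 * C
    mu = data.X @ params.beta
    return float(multivariate_normal(mean=mu, cov=V, allow_singular=True).logpdf(data.y))


class TestMarginalLoglik:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for i in range(40):
            n_fixed = int(rng.integers(1, 3))
            n_random = int(rng.integers(0, n_fixed + 1))
            spec, data, params = _random_instance(
                rng, n_fixed=n_fixed, n_random=n_random, gaps=bool(i % 2))
            ll = lc.marginal_loglik(spec, data, params, method="ML")
            assert ll == pytest.approx(oracle_loglik(data, params), abs=1e-8)

    def test_phi_zero_no_re_reduces_to_iid_gaussian(self):
        rng = np.random.default_rng(5)
        spec, data, params = _random_instance(rng, n_fixed=2)
        params.phi = 0.0
        params.re_sd = np.array([0.0])
        ll = lc.marginal_loglik(spec, data, params)
        resid = data.y - data.X @ params.beta
        expect = stats.norm.logpdf(resid, scale=params.sigma).sum()
        assert ll == pytest.approx(expect, abs=1e-10)

    def test_reml_equals_ml_plus_adjustment(self):
        rng = np.random.default_rng(11)
        spec, data, params = _random_instance(rng, n_fixed=2, n_random=1)
        p = data.X.shape[1]
        # assemble V explicitly for the adjustment term
        n = data.n_obs
        bounds = np.r_[data.starts, n]
        G = np.diag(params.re_sd ** 2)
        V = np.zeros((n, n))
        for i in range(data.n_groups):
            lo, hi = bounds[i], bounds[i + 1]
            yrs = data.years[lo:hi]
            C = np.abs(params.phi) ** np.abs(yrs[:, None] - yrs[None, :]).astype(float)
            C *= np.sign(params.phi) ** (np.abs(yrs[:, None] - yrs[None, :]) % 2)
            np.fill_diagonal(C, 1.0)
            V[lo:hi, lo:hi] = data.Z[lo:hi] @ G @ data.Z[lo:hi].T \
                + params.sigma ** 2 * C
        Vi = np.linalg.inv(V)
        XtVX = data.X.T @ Vi @ data.X
        beta_gls = np.linalg.solve(XtVX, data.X.T @ Vi @ data.y)
        ml_at_gls = lc.marginal_loglik(
            spec, data, lc.LMMParams(beta=beta_gls, re_sd=params.re_sd,
                                     phi=params.phi, sigma=params.sigma), "ML")
        expect = ml_at_gls - 0.5 * np.linalg.slogdet(XtVX)[1] \
            + 0.5 * p * np.log(2 * np.pi)
        got = lc.marginal_loglik(spec, data, params, method="REML")
        assert got == pytest.approx(expect, abs=1e-8)

    def test_invariant_under_tree_reordering_and_year_shift(self):
        rng = np.random.default_rng(21)
        spec, data, params = _random_instance(rng, n_fixed=1, n_random=1)
        ll = lc.marginal_loglik(spec, data, params)
        # rebuild with reversed tree labels and shifted years
        df = pd.DataFrame({"tree_id": [f"Z{9 - g}" for g in data.group],
                           "year": data.years + 100,
                           "resp": data.y, "x0": data.X[:, 1]})
        data2 = lc.GroupedData.from_frame(df, spec)
        assert lc.marginal_loglik(spec, data2, params) == pytest.approx(ll, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        rng = np.random.default_rng(1)
        spec, data, params = _random_instance(rng)
        for bad in [dict(phi=1.0), dict(phi=-1.2), dict(sigma=0.0)]:
            p2 = lc.LMMParams(beta=params.beta, re_sd=params.re_sd,
                              phi=bad.get("phi", params.phi),
                              sigma=bad.get("sigma", params.sigma))
            with pytest.raises(ValueError):
                lc.marginal_loglik(spec, data, p2)

    def test_unstructured_g_matches_oracle(self):
        rng = np.random.default_rng(33)
        spec0, data, params = _random_instance(rng, n_fixed=1, n_random=1)
        spec = lc.ModelSpec(response="resp", fixed=spec0.fixed,
                            random=spec0.random, random_cov="unstructured",
                            ar1=True)
        params.re_corr = 0.6
        # oracle with correlated G
        sds = params.re_sd
        G = np.array([[sds[0] ** 2, 0.6 * sds[0] * sds[1]],
                      [0.6 * sds[0] * sds[1], sds[1] ** 2]])
        n = data.n_obs
        bounds = np.r_[data.starts, n]
        V = np.zeros((n, n))
        for i in range(data.n_groups):
            lo, hi = bounds[i], bounds[i + 1]
            yrs = data.years[lo:hi]
            d = np.abs(yrs[:, None] - yrs[None, :])
            C = np.sign(params.phi) ** (d % 2) * np.abs(params.phi) ** d.astype(float)
            np.fill_diagonal(C, 1.0)
            V[lo:hi, lo:hi] = data.Z[lo:hi] @ G @ data.Z[lo:hi].T \
                + params.sigma ** 2 * C
        expect = multivariate_normal(mean=data.X @ params.beta, cov=V
                                     ).logpdf(data.y)
        assert lc.marginal_loglik(spec, data, params) == pytest.approx(expect, abs=1e-8)


class TestFitLMM:
    @staticmethod
    def _panel(design, **kw):
        df = sd.simulate_rwi_panel(design, **kw)
        return df.rename(columns={"rwi": "resp"})

    def test_reduction_to_ols(self, quiet_design):
        df = self._panel(quiet_design, n_trees=10, beta={"curJul": 0.2},
                         seed=2, years_per_tree=40, sigma_b0=0.0, phi=0.0)
        spec = lc.ModelSpec(response="resp", fixed=("curJul", "curApr"),
                            random=(), ar1=False)
        data = lc.GroupedData.from_frame(df, spec)
        fit = lc.fit_lmm(spec, data, method="ML", compute_var_se=False)
        if fit.re_sd["intercept"] > 0:  # singular fit may sit at the floor
            assert fit.re_sd["intercept"] < 1e-3
        ols = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(), ols, atol=1e-6)

    def test_parameter_recovery_single_simulation(self, quiet_design):
        df = self._panel(quiet_design, n_trees=60, beta={"curJul": 0.2},
                         seed=3, years_per_tree=100, sigma_b0=0.1,
                         phi=0.6, sigma=0.15)
        spec = lc.ModelSpec(response="resp", fixed=("curJul",), random=(), ar1=True)
        data = lc.GroupedData.from_frame(df, spec)
        fit = lc.fit_lmm(spec, data, method="ML")
        assert fit.converged
        assert fit.beta["curJul"] == pytest.approx(0.2, abs=3 * fit.se["curJul"])
        assert fit.phi == pytest.approx(0.6, abs=3 * fit.phi_se)
        assert fit.sigma == pytest.approx(0.15, abs=3 * fit.sigma_se)
        assert fit.re_sd["intercept"] == pytest.approx(
            0.1, abs=3 * fit.re_sd_se["intercept"])

    def test_restarts_agree(self, quiet_design):
        df = self._panel(quiet_design, n_trees=15, beta={"curJun": 0.15},
                         seed=4, years_per_tree=50)
        spec = lc.ModelSpec(response="resp", fixed=("curJun",), random=(), ar1=True)
        data = lc.GroupedData.from_frame(df, spec)
        base = lc.fit_lmm(spec, data, method="ML", compute_var_se=False)
        again = lc.fit_lmm(spec, data, method="ML", n_restarts=5,
                           compute_var_se=False)
        assert again.loglik == pytest.approx(base.loglik, abs=1e-4)

    def test_nested_model_loglik_monotone(self, quiet_design):
        df = self._panel(quiet_design, n_trees=20, beta={"curJul": 0.2},
                         seed=6, years_per_tree=60)
        small = lc.ModelSpec(response="resp", fixed=("curJul",), random=(), ar1=True)
        big = lc.ModelSpec(response="resp", fixed=("curJul", "curApr", "prevSep"),
                           random=(), ar1=True)
        ll_small = lc.fit_lmm(small, lc.GroupedData.from_frame(df, small),
                              method="ML", compute_var_se=False).loglik
        ll_big = lc.fit_lmm(big, lc.GroupedData.from_frame(df, big),
                            method="ML", compute_var_se=False).loglik
        assert ll_big >= ll_small - 1e-6

    def test_phi_near_zero_when_truth_uncorrelated(self, quiet_design):
        hits = 0
        for seed in range(12):
            df = self._panel(quiet_design, n_trees=60, beta={"curJul": 0.2},
                             seed=100 + seed, years_per_tree=80, phi=0.0)
            spec = lc.ModelSpec(response="resp", fixed=("curJul",), random=(),
                                ar1=True)
            fit = lc.fit_lmm(spec, lc.GroupedData.from_frame(df, spec),
                             method="ML", compute_var_se=False)
            hits += abs(fit.phi) < 0.1
        assert hits >= 11  # >= 90%

    def test_preconditions(self, quiet_design):
        df = self._panel(quiet_design, n_trees=1, beta={}, seed=1,
                         years_per_tree=30)
        spec = lc.ModelSpec(response="resp", fixed=(), random=(), ar1=True)
        with pytest.raises(ValueError, match="2 groups"):
            lc.fit_lmm(spec, lc.GroupedData.from_frame(df, spec))


class TestInformationCriteria:
    def test_arithmetic(self):
        fit = lc.LMMFit(spec=lc.ModelSpec(response="r"), method="ML",
                        beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
                        pvalues=pd.Series(dtype=float), cov_beta=np.empty((0, 0)),
                        re_sd=pd.Series(dtype=float), re_corr=None, phi=0.0,
                        sigma=1.0, loglik=-100.0, n_obs=100, n_groups=10,
                        converged=True, k_params=5)
        aic, bic = lc.information_criteria(fit)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200.0 + 5 * np.log(100), abs=1e-4)

    def test_zero_parameters_rejected(self):
        fit = lc.LMMFit(spec=lc.ModelSpec(response="r"), method="ML",
                        beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
                        pvalues=pd.Series(dtype=float), cov_beta=np.empty((0, 0)),
                        re_sd=pd.Series(dtype=float), re_corr=None, phi=0.0,
                        sigma=1.0, loglik=-100.0, n_obs=100, n_groups=10,
                        converged=True, k_params=0)
        with pytest.raises(ValueError):
            lc.information_criteria(fit)

    def test_bic_prefers_smaller_model_under_null(self, quiet_design):
        wins = 0
        n_rep = 30
        for seed in range(n_rep):
            df = sd.simulate_rwi_panel(quiet_design, n_trees=10,
                                       beta={"curJul": 0.2}, seed=300 + seed,
                                       years_per_tree=40, phi=0.3
                                       ).rename(columns={"rwi": "resp"})
            small = lc.ModelSpec(response="resp", fixed=("curJul",), random=(),
                                 ar1=True)
            # curJan is pure noise with respect to the response
            big = lc.ModelSpec(response="resp", fixed=("curJul", "curJan"),
                               random=(), ar1=True)
            b_small = lc.information_criteria(
                lc.fit_lmm(small, lc.GroupedData.from_frame(df, small),
                           method="ML", compute_var_se=False))[1]
            b_big = lc.information_criteria(
                lc.fit_lmm(big, lc.GroupedData.from_frame(df, big),
                           method="ML", compute_var_se=False))[1]
            wins += b_small < b_big
        assert wins >= 0.8 * n_rep


class TestDiagnostics:
    @staticmethod
    def _fit(df, fixed=("curJul",), ar1=True):
        spec = lc.ModelSpec(response="resp", fixed=fixed, random=(), ar1=ar1)
        data = lc.GroupedData.from_frame(df, spec)
        return lc.fit_lmm(spec, data, method="REML",
                          compute_var_se=False), data

    def test_whitened_residuals_uncorrelated_when_well_specified(self, quiet_design):
        df = sd.simulate_rwi_panel(quiet_design, n_trees=40, beta={"curJul": 0.2},
                                   seed=8, years_per_tree=80, phi=0.6
                                   ).rename(columns={"rwi": "resp"})
        fit, data = self._fit(df)
        rep = lc.diagnostics(fit, data)
        assert -0.1 <= rep.lag1_autocorr <= 0.1
        assert not rep.normality_flag

    def test_duplicated_predictor_flagged_infinite_vif(self, quiet_design):
        df = sd.simulate_rwi_panel(quiet_design, n_trees=10, beta={"curJul": 0.2},
                                   seed=9, years_per_tree=40
                                   ).rename(columns={"rwi": "resp"})
        df["curJul_copy"] = df["curJul"]
        fit, data = self._fit(df, fixed=("curJul", "curJul_copy"))
        rep = lc.diagnostics(fit, data)
        assert not np.isfinite(rep.vif["curJul"])
        assert not np.isfinite(rep.vif["curJul_copy"])

    def test_heavy_tailed_noise_flagged(self, quiet_design, rng):
        df = sd.simulate_rwi_panel(quiet_design, n_trees=30, beta={"curJul": 0.2},
                                   seed=10, years_per_tree=60, phi=0.0,
                                   sigma=0.05).rename(columns={"rwi": "resp"})
        df["resp"] = df["resp"] + 0.1 * rng.standard_t(df=2, size=len(df))
        fit, data = self._fit(df)
        rep = lc.diagnostics(fit, data)
        assert rep.normality_flag


class TestRandomEffects:
    def test_blups_shrink_toward_zero_and_track_truth(self, quiet_design):
        df = sd.simulate_rwi_panel(quiet_design, n_trees=40, beta={"curJul": 0.2},
                                   seed=13, years_per_tree=100, sigma_b0=0.15,
                                   phi=0.2, sigma=0.1
                                   ).rename(columns={"rwi": "resp"})
        spec = lc.ModelSpec(response="resp", fixed=("curJul",), random=(), ar1=True)
        data = lc.GroupedData.from_frame(df, spec)
        fit = lc.fit_lmm(spec, data, method="REML", compute_var_se=False)
        blups = lc.random_effects(fit, data)
        # per-tree mean residual should correlate strongly with the BLUPs
        resid = df["resp"] - fit.beta["intercept"] - fit.beta["curJul"] * df["curJul"]
        tree_means = resid.groupby(df["tree_id"]).mean()
        r = np.corrcoef(tree_means[blups.index], blups["intercept"])[0, 1]
        assert r > 0.95
        assert np.abs(blups["intercept"]).max() <= np.abs(tree_means).max() + 1e-9
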