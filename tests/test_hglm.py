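import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from methvar.exceptions import DegenerateRegionError, ValidationError
from methvar.hglm import (FitConfig, MeanVarianceHGLM, RegionDesign,
                          build_region_design, fit_region, h_likelihood,
                          solve_mean_model, solve_variance_model,
                          update_sigma_b2)
from methvar.io import MValueMatrix, SampleDesign
from methvar.simulate import simulate_region

from conftest import make_region_design


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

class TestBuildRegionDesign:
    def _pieces(self, n_cpgs=3, N=4):
        rng = np.random.default_rng(0)
        cpgs = [f"cg{j}" for j in range(n_cpgs)]
        samples = [f"S{i}" for i in range(N)]
        matrix = MValueMatrix(cpgs, samples, rng.normal(size=(n_cpgs, N)))
        design = SampleDesign(samples, np.tile([0.0, 1.0], N // 2 + 1)[:N])
        return cpgs, matrix, design

    def test_stacking_shapes(self):
        cpgs, matrix, design = self._pieces(3, 4)
        rd = build_region_design(cpgs, matrix, design)
        assert rd.y.shape == (12,)
        Z = rd.Z
        assert Z.shape == (12, 4)
        assert np.all(Z.sum(axis=0) == 3)
        # sample-major, CpG-minor: first 3 observations belong to sample 0
        assert np.array_equal(rd.subject[:3], [0, 0, 0])
        np.testing.assert_allclose(rd.y[:3], matrix.values[:, 0])

    def test_single_cpg_region_identity_incidence(self):
        cpgs, matrix, design = self._pieces(1, 4)
        rd = build_region_design(cpgs, matrix, design)
        np.testing.assert_array_equal(rd.Z, np.eye(4))

    def test_empty_region_errors(self):
        _, matrix, design = self._pieces()
        with pytest.raises(ValidationError, match="zero usable"):
            build_region_design([], matrix, design)

    def test_sample_permutation_equivariance(self):
        cpgs, matrix, design = self._pieces(3, 8)
        rd = build_region_design(cpgs, matrix, design)
        fit = fit_region(rd)
        perm = np.random.default_rng(1).permutation(8)
        matrix2 = MValueMatrix(cpgs, [matrix.sample_ids[i] for i in perm],
                               matrix.values[:, perm])
        design2 = SampleDesign([design.sample_ids[i] for i in perm],
                               design.phenotype[perm])
        fit2 = fit_region(build_region_design(cpgs, matrix2, design2))
        assert fit2.delta_hat == pytest.approx(fit.delta_hat, abs=1e-10)
        assert fit2.kappa_hat == pytest.approx(fit.kappa_hat, abs=1e-10)
        assert fit2.sigma_b2 == pytest.approx(fit.sigma_b2, abs=1e-10)


# ---------------------------------------------------------------------------
# mean model
# ---------------------------------------------------------------------------

class TestSolveMeanModel:
    def test_reduces_to_ols_at_zero_sigma_b2(self):
        rd = make_region_design(3, 10, seed=1)
        w = np.ones(rd.n_obs)
        ms = solve_mean_model(rd, w, 0.0)
        g = rd.X_mean[:, 1]
        diff = rd.y[g == 1].mean() - rd.y[g == 0].mean()
        assert ms.theta[1] == pytest.approx(diff, abs=1e-10)
        assert np.all(ms.b == 0)

    def test_large_sigma_b2_limit_single_cpg(self):
        # one CpG per subject: b absorbs the residuals as sigma_b2 -> inf
        rd = make_region_design(1, 8, seed=3)
        w = np.ones(rd.n_obs)
        ms = solve_mean_model(rd, w, 1e10)
        resid = rd.y - rd.X_mean @ ms.theta
        np.testing.assert_allclose(ms.b, resid, atol=1e-6)

    def test_matches_brute_force_h_maximization(self):
        # penalized WLS solution == argmax of h over (theta, b), variances fixed
        rng = np.random.default_rng(7)
        for seed in range(3):
            rd = make_region_design(3, 6, seed=seed, delta=0.4)
            w = np.exp(0.3 * rng.normal(size=rd.n_obs))
            sb2 = 0.5
            ms = solve_mean_model(rd, w, sb2)

            def negh(par):
                th, b = par[:2], par[2:]
                mu = rd.X_mean @ th + b[rd.subject]
                data = np.sum(0.5 * np.log(w) - w * (rd.y - mu) ** 2 / 2)
                pen = np.sum(-b ** 2 / (2 * sb2))
                return -(data + pen)

            opt = minimize(negh, np.zeros(2 + rd.n_subjects), method="BFGS",
                           options={"gtol": 1e-12})
            got = np.concatenate([ms.theta, ms.b])
            assert np.max(np.abs(got - opt.x)) < 1e-6

    def test_rejects_nonpositive_weights(self):
        rd = make_region_design(2, 5, seed=0)
        with pytest.raises(ValidationError):
            solve_mean_model(rd, np.zeros(rd.n_obs), 0.1)


# ---------------------------------------------------------------------------
# variance model
# ---------------------------------------------------------------------------

class TestSolveVarianceModel:
    def test_intercept_only_closed_form(self):
        rd = make_region_design(3, 10, seed=2, var_design="intercept")
        e = np.random.default_rng(0).normal(size=rd.n_obs) * 1.7
        vs = solve_variance_model(rd, e, use_leverage_correction=False, tol=1e-12)
        assert vs.phi[0] == pytest.approx(np.log(np.mean(e ** 2)), abs=1e-8)

    def test_two_group_closed_form(self):
        # group-wise ML residual variances 1.0 and 4.0 -> kappa = log 4
        N = 20
        g = np.repeat([0.0, 1.0], N // 2)
        X = np.column_stack([np.ones(N), g])
        rng = np.random.default_rng(5)
        e = rng.normal(size=N)
        e[:10] = e[:10] / np.sqrt(np.mean(e[:10] ** 2))          # MLE var 1
        e[10:] = 2.0 * e[10:] / np.sqrt(np.mean(e[10:] ** 2))    # MLE var 4
        rd = RegionDesign(y=e, X_mean=X, X_var=X, subject=np.arange(N), n_subjects=N)
        vs = solve_variance_model(rd, e, use_leverage_correction=False, tol=1e-12)
        assert vs.phi[0] == pytest.approx(0.0, abs=1e-8)
        assert vs.phi[1] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_score_zero_at_optimum(self):
        rd = make_region_design(3, 15, seed=6)
        e = np.random.default_rng(1).normal(size=rd.n_obs)
        q = np.full(rd.n_obs, 0.1)
        vs = solve_variance_model(rd, e, q, use_leverage_correction=True, tol=1e-14)
        d = e ** 2 / (1 - q)
        wp = (1 - q) / 2
        sig2 = np.exp(rd.X_var @ vs.phi)
        score = rd.X_var.T @ (wp * (d / sig2 - 1.0))
        assert np.max(np.abs(score)) < 1e-8

    def test_matches_statsmodels_gamma_glm(self):
        rd = make_region_design(3, 30, seed=4)
        e = np.random.default_rng(2).normal(size=rd.n_obs)
        vs = solve_variance_model(rd, e, use_leverage_correction=False, tol=1e-12)
        glm = sm.GLM(e ** 2, rd.X_var,
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        np.testing.assert_allclose(vs.phi, glm.params, atol=1e-7)

    def test_all_zero_residuals_degenerate(self):
        rd = make_region_design(2, 5, seed=0)
        with pytest.raises(DegenerateRegionError):
            solve_variance_model(rd, np.zeros(rd.n_obs), use_leverage_correction=False)


class TestUpdateSigmaB2:
    def test_zero_b_gives_zero(self):
        assert update_sigma_b2(np.zeros(5), np.full(5, 0.2)) == 0.0

    def test_direct_formula(self):
        assert update_sigma_b2(np.array([1.0, -1.0]),
                               np.array([0.5, 0.5])) == pytest.approx(2.0)

    def test_matches_reml_in_homoscedastic_case(self):
        # intercept-only variance design: converged fit == Gaussian LMM REML
        N, n_cpgs = 40, 5
        rng = np.random.default_rng(3)
        g = np.repeat([0.0, 1.0], N // 2)
        V = simulate_region(n_cpgs, N, g, 0.4, 1.0, 0.5, 1.0, rng)
        y = V.T.reshape(-1)
        X = np.repeat(np.column_stack([np.ones(N), g]), n_cpgs, axis=0)
        s = np.repeat(np.arange(N), n_cpgs)
        rd = RegionDesign(y=y, X_mean=X, X_var=np.ones((y.size, 1)),
                          subject=s, n_subjects=N)
        fit = fit_region(rd, FitConfig(tol=1e-10, abs_tol=1e-12, max_iter=1000))
        ml = sm.MixedLM(y, X, groups=s).fit(reml=True)
        assert fit.sigma_b2 == pytest.approx(float(np.asarray(ml.cov_re)[0, 0]), abs=1e-4)
        assert fit.delta_hat == pytest.approx(ml.params[1], abs=1e-6)
        assert np.exp(fit.kappa_hat) == pytest.approx(ml.scale, abs=1e-4)
        assert fit.se_delta == pytest.approx(float(np.asarray(ml.bse)[1]), abs=1e-4)


# ---------------------------------------------------------------------------
# full alternating fit
# ---------------------------------------------------------------------------

class TestFitRegion:
    def test_joint_ml_oracle_pinned(self):
        # sigma_b2 pinned to 0, correction off -> joint Gaussian location-scale ML
        rd = make_region_design(4, 12, seed=2, delta=0.5, kappa=0.4, rho=0.0)
        cfg = FitConfig(pin_sigma_b2=0.0, leverage_correction=False,
                        tol=1e-10, abs_tol=1e-12, max_iter=500)
        fit = fit_region(rd, cfg)
        assert fit.converged

        def negll(par):
            th, ph = par[:2], par[2:]
            mu = rd.X_mean @ th
            eta = rd.X_var @ ph
            return -np.sum(-0.5 * (np.log(2 * np.pi) + eta)
                           - (rd.y - mu) ** 2 / (2 * np.exp(eta)))

        opt = minimize(negll, np.zeros(4), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 50000})
        got = np.concatenate([fit.theta, fit.phi])
        assert np.max(np.abs(got - opt.x)) < 1e-4

    def test_oracle_equivalence_many_small_instances(self):
        # >= 20 random small instances, sigma_b2 pinned, correction off
        cfg = FitConfig(pin_sigma_b2=0.0, leverage_correction=False,
                        tol=1e-11, abs_tol=1e-13, max_iter=1000)
        for seed in range(20):
            rd = make_region_design(2 + seed % 2, 8 + seed % 3, seed=seed,
                                    delta=0.3, kappa=0.3)
            fit = fit_region(rd, cfg)
            assert fit.converged

            def negll(par):
                mu = rd.X_mean @ par[:2]
                eta = rd.X_var @ par[2:]
                return float(np.sum(0.5 * eta + (rd.y - mu) ** 2
                                    / (2 * np.exp(eta))))

            start = np.concatenate([fit.theta, fit.phi])
            opt = minimize(negll, np.zeros(4), method="Nelder-Mead",
                           options={"xatol": 1e-11, "fatol": 1e-14,
                                    "maxiter": 100000, "adaptive": True})
            assert np.max(np.abs(start - opt.x)) < 1e-4, f"seed {seed}"

    def test_ols_limit_invariant(self):
        # sigma_b2 pinned 0, intercept-only variance design:
        # delta == OLS coefficient, exp(gamma0) == ML residual variance
        rd = make_region_design(3, 14, seed=9, delta=0.6, var_design="intercept")
        cfg = FitConfig(pin_sigma_b2=0.0, leverage_correction=False,
                        tol=1e-12, abs_tol=1e-14, max_iter=500)
        fit = fit_region(rd, cfg)
        theta_ols, *_ = np.linalg.lstsq(rd.X_mean, rd.y, rcond=None)
        resid = rd.y - rd.X_mean @ theta_ols
        assert fit.delta_hat == pytest.approx(theta_ols[1], abs=1e-8)
        assert np.exp(fit.phi[0]) == pytest.approx(np.mean(resid ** 2), abs=1e-8)

    def test_scale_equivariance(self):
        rd = make_region_design(3, 20, seed=11, delta=0.5, kappa=0.5)
        fit1 = fit_region(rd, FitConfig(tol=1e-10, abs_tol=1e-12))
        s = 3.0
        rd2 = RegionDesign(y=s * rd.y, X_mean=rd.X_mean, X_var=rd.X_var,
                           subject=rd.subject, n_subjects=rd.n_subjects)
        fit2 = fit_region(rd2, FitConfig(tol=1e-10, abs_tol=1e-12))
        assert fit2.delta_hat == pytest.approx(s * fit1.delta_hat, abs=1e-7)
        assert fit2.phi[0] == pytest.approx(fit1.phi[0] + 2 * np.log(s), abs=1e-7)
        assert fit2.kappa_hat == pytest.approx(fit1.kappa_hat, abs=1e-7)

    def test_null_region_estimates_near_zero(self):
        # Monte-Carlo calibration: delta and kappa within 3 SEs of 0 almost always
        hits_d = hits_k = n = 0
        for seed in range(200):
            rd = make_region_design(4, 30, seed=1000 + seed)
            fit = fit_region(rd)
            if not fit.converged:
                continue
            n += 1
            hits_d += abs(fit.delta_hat) < 3 * fit.se_delta
            hits_k += abs(fit.kappa_hat) < 3 * fit.se_kappa
        assert n > 190
        assert hits_d / n >= 0.97
        assert hits_k / n >= 0.97

    def test_parameter_recovery_large_n(self):
        # delta = 0.7, kappa = log 2.5, n_r = 5, rho = 0.5, N = 2000
        rng = np.random.default_rng(21)
        g = np.zeros(2000); g[1000:] = 1.0
        V = simulate_region(5, 2000, g, 0.5, 1.0, 0.7, 2.5, rng)
        X = np.repeat(np.column_stack([np.ones(2000), g]), 5, axis=0)
        rd = RegionDesign(y=V.T.reshape(-1), X_mean=X, X_var=X.copy(),
                          subject=np.repeat(np.arange(2000), 5), n_subjects=2000)
        fit = fit_region(rd)
        assert fit.delta_hat == pytest.approx(0.7, abs=0.05)
        assert fit.kappa_hat == pytest.approx(np.log(2.5), abs=0.10)

    def test_median_bias_over_replicates(self):
        deltas, kappas = [], []
        for seed in range(200):
            rng = np.random.default_rng([77, seed])
            g = np.zeros(500); g[250:] = 1.0
            V = simulate_region(5, 500, g, 0.5, 1.0, 0.7, 2.5, rng)
            X = np.repeat(np.column_stack([np.ones(500), g]), 5, axis=0)
            rd = RegionDesign(y=V.T.reshape(-1), X_mean=X, X_var=X.copy(),
                              subject=np.repeat(np.arange(500), 5), n_subjects=500)
            fit = fit_region(rd)
            deltas.append(fit.delta_hat)
            kappas.append(fit.kappa_hat)
        assert abs(np.median(deltas) - 0.7) < 0.02
        assert abs(np.median(kappas) - np.log(2.5)) < 0.05

    def test_single_cpg_region_pins_sigma_b2(self):
        rd = make_region_design(1, 20, seed=4, delta=0.3)
        fit = fit_region(rd)
        assert fit.sigma_b2 == 0.0
        assert np.all(fit.b_hat == 0.0)

    def test_nonconvergence_policy(self):
        rd = make_region_design(3, 10, seed=5, delta=0.5, kappa=0.5)
        fit = fit_region(rd, FitConfig(max_iter=1))
        assert not fit.converged
        assert np.isfinite(fit.delta_hat)  # report: last iterate retained
        fit_na = fit_region(rd, FitConfig(max_iter=1, on_nonconverged="na"))
        assert not fit_na.converged and np.isnan(fit_na.delta_hat)


# ---------------------------------------------------------------------------
# h-likelihood
# ---------------------------------------------------------------------------

class TestHLikelihood:
    def test_single_observation_value(self):
        # 1 observation, mu = y, sigma2 = 1, sigma_b2 = 0 -> -log(2 pi)/2
        rd = RegionDesign(y=np.array([2.0]), X_mean=np.ones((1, 1)),
                          X_var=np.ones((1, 1)), subject=np.array([0]),
                          n_subjects=1)
        from methvar.hglm import RegionFit
        fit = fit_region(rd, FitConfig(pin_sigma_b2=0.0))  # trivially degenerate
        h = -0.5 * np.log(2 * np.pi)
        from methvar.hglm import _h_value
        assert _h_value(np.array([2.0]), np.array([2.0]), np.array([0.0]),
                        np.zeros(1), 0.0) == pytest.approx(h, abs=1e-9)

    def test_translation_invariance(self, small_rd):
        fit = fit_region(small_rd)
        h1 = h_likelihood(small_rd, fit)
        rd2 = RegionDesign(y=small_rd.y + 5.0, X_mean=small_rd.X_mean,
                           X_var=small_rd.X_var, subject=small_rd.subject,
                           n_subjects=small_rd.n_subjects)
        fit2 = fit_region(rd2)
        # same residual structure after refit: h unchanged
        assert h_likelihood(rd2, fit2) == pytest.approx(h1, abs=1e-6)
        # and directly: shifting y and mu together leaves h fixed
        from methvar.hglm import _h_value
        assert _h_value(small_rd.y + 3.0, fit.mu_hat + 3.0, fit.eta_hat,
                        fit.b_hat, fit.sigma_b2) == pytest.approx(h1, abs=1e-10)

    def test_monotone_over_iterations_coordinate_ascent(self):
        # with sigma_b2 pinned and correction off the alternation is coordinate
        # ascent on the joint likelihood; single tiny decreases are tolerated
        for seed in (0, 1, 2):
            rd = make_region_design(4, 15, seed=seed, delta=0.4, kappa=0.6)
            fit = fit_region(rd, FitConfig(pin_sigma_b2=0.0,
                                           leverage_correction=False,
                                           track_history=True))
            h = np.array(fit.history)
            assert np.all(np.diff(h) > -1e-8)

    def test_rejects_nonpositive_sigma2(self, small_rd):
        fit = fit_region(small_rd)
        from methvar.hglm import _h_value
        with pytest.raises(ValidationError):
            _h_value(small_rd.y, fit.mu_hat, np.full(small_rd.n_obs, np.nan),
                     fit.b_hat, fit.sigma_b2)


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------

class TestMeanVarianceHGLM:
    def _xy(self, seed=0, N=50, n_cpgs=4, delta=0.8, kappa=0.7):
        rng = np.random.default_rng(seed)
        g = np.repeat([0.0, 1.0], N // 2)
        V = simulate_region(n_cpgs, N, g, 0.4, 1.0, delta, float(np.exp(kappa)), rng)
        y = V.T.reshape(-1)
        X = np.repeat(g, n_cpgs)[:, None]
        groups = np.repeat(np.arange(N), n_cpgs)
        return X, y, groups

    def test_fit_sets_attributes(self):
        X, y, groups = self._xy()
        m = MeanVarianceHGLM().fit(X, y, groups=groups)
        for attr in ("delta_", "kappa_", "sigma_b2_", "se_delta_", "se_kappa_",
                     "converged_", "n_iter_", "h_likelihood_"):
            assert hasattr(m, attr)
        assert m.converged_
        assert m.sigma_b2_ >= 0

    def test_get_set_params_clone(self):
        from sklearn.base import clone
        m = MeanVarianceHGLM(tol=1e-7, leverage_correction=False)
        params = m.get_params()
        assert params["tol"] == 1e-7 and params["leverage_correction"] is False
        m2 = clone(m).set_params(max_iter=5)
        assert m2.get_params()["max_iter"] == 5

    def test_predict_uses_random_effects_for_seen_groups(self):
        X, y, groups = self._xy()
        m = MeanVarianceHGLM().fit(X, y, groups=groups)
        mu = m.predict(X, groups=groups)
        assert mu.shape == y.shape
        np.testing.assert_allclose(mu, m.result_.mu_hat, atol=1e-10)

    def test_predict_variance_respects_kappa(self):
        X, y, groups = self._xy()
        m = MeanVarianceHGLM().fit(X, y, groups=groups)
        v = m.predict_variance(np.array([[0.0], [1.0]]))
        assert np.log(v[1] / v[0]) == pytest.approx(m.kappa_, abs=1e-10)

    def test_without_groups_degrades_to_double_glm(self):
        X, y, _ = self._xy()
        m = MeanVarianceHGLM().fit(X, y)
        assert m.sigma_b2_ == 0.0
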