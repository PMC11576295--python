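"""ML CFA estimation, scaled test statistic and fit indices."""

import numpy as np
import pandas as pd
import pytest

from ipvkit import cfa


def _cov_summary(S, n=500):
    p = S.shape[0]
    items = [f"x{i}" for i in range(p)]
    return cfa.CovarianceSummary(
        S=pd.DataFrame(S, index=items, columns=items),
        n=n,
        means=pd.Series(0.0, index=items),
        sds=pd.Series(1.0, index=items),
    ), items


def _two_factor_sigma():
    lam = np.array([0.7, 0.6, 0.5, 0.8, 0.65, 0.55])
    fidx = np.array([0, 0, 0, 1, 1, 1])
    phi = np.array([[1.0, 0.4], [0.4, 1.0]])
    Lam = np.zeros((6, 2))
    Lam[np.arange(6), fidx] = lam
    Sigma = Lam @ phi @ Lam.T
    np.fill_diagonal(Sigma, 1.0)
    return Sigma, lam, phi


class TestSampleCovariance:
    def test_identical_columns(self):
        x = pd.Series([1.0, 2.0, 4.0, 3.0])
        cov = cfa.sample_covariance(pd.DataFrame({"a": x, "b": x, "c": -x}))
        S = cov.S
        assert S.loc["a", "b"] == pytest.approx(S.loc["a", "a"])
        assert S.loc["a", "c"] == pytest.approx(-S.loc["a", "a"])

    def test_hand_computed_toy(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 5.0]})
        cov = cfa.sample_covariance(df)
        assert cov.S.loc["a", "a"] == pytest.approx(1.0)
        assert cov.S.loc["a", "b"] == pytest.approx(1.5)  # ((−1)(−1)+0·(−1)+1·2)/2
        assert cov.S.loc["b", "b"] == pytest.approx(3.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cfa.sample_covariance(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]}))


class TestFitML:
    def test_perfect_fit_recovers_parameters(self):
        Sigma, lam, phi = _two_factor_sigma()
        cov, items = _cov_summary(Sigma)
        spec = cfa.correlated_spec({"f1": items[:3], "f2": items[3:]})
        fit = cfa.fit_ml(cov, spec)
        assert fit.f_min <= 1e-8
        assert np.abs(fit.lambda_std.to_numpy() - lam).max() < 1e-4
        assert fit.phi.iloc[0, 1] == pytest.approx(0.4, abs=1e-4)

    def test_just_identified_three_items(self):
        Sigma = np.eye(3) + 0.4 * (1 - np.eye(3))
        cov, items = _cov_summary(Sigma)
        fit = cfa.fit_ml(cov, cfa.single_factor_spec(items))
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_cross_check_against_statsmodels_ml_factor(self):
        # independent single-factor ML oracle (EFA with one factor is the
        # same model as single-factor CFA)
        from statsmodels.multivariate.factor import Factor

        rng = np.random.default_rng(42)
        for _ in range(3):
            p = int(rng.integers(5, 9))
            lam_t = rng.uniform(0.3, 0.85, p)
            Sigma = np.outer(lam_t, lam_t)
            np.fill_diagonal(Sigma, 1.0)
            X = rng.standard_normal((400, p)) @ np.linalg.cholesky(Sigma).T
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
            fit = cfa.fit_ml(cfa.sample_covariance(df), cfa.single_factor_spec(df.columns))
            oracle = np.abs(np.ravel(Factor(df.to_numpy(), n_factor=1, method="ml").fit().loadings))
            assert np.abs(np.abs(fit.lambda_std.to_numpy()) - oracle).max() < 1e-3

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        Sigma, _, _ = _two_factor_sigma()
        X = rng.standard_normal((300, 6)) @ np.linalg.cholesky(Sigma).T
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(6)])
        spec = cfa.correlated_spec({"f1": list(df.columns[:3]), "f2": list(df.columns[3:])})
        fit_a = cfa.fit_ml(cfa.sample_covariance(df), spec)
        scaled = df.copy()
        scaled["x0"] = scaled["x0"] * 37.0
        fit_b = cfa.fit_ml(cfa.sample_covariance(scaled), spec)
        assert np.abs(fit_a.lambda_std - fit_b.lambda_std).max() < 1e-6
        assert fit_a.chi2 == pytest.approx(fit_b.chi2, abs=1e-6)
        idx_a = cfa.fit_indices(fit_a, cfa.independence_baseline(cfa.sample_covariance(df)))
        idx_b = cfa.fit_indices(fit_b, cfa.independence_baseline(cfa.sample_covariance(scaled)))
        for name in ("rmsea", "srmr", "cfi"):
            assert getattr(idx_a, name) == pytest.approx(getattr(idx_b, name), abs=1e-6)

    def test_correlation_input_equals_standardized_covariance_fit(self):
        rng = np.random.default_rng(11)
        Sigma, _, _ = _two_factor_sigma()
        X = rng.standard_normal((300, 6)) @ np.linalg.cholesky(Sigma).T
        X = X * np.array([1.0, 2.0, 0.5, 3.0, 1.5, 0.7])
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(6)])
        spec = cfa.correlated_spec({"f1": list(df.columns[:3]), "f2": list(df.columns[3:])})
        cov = cfa.sample_covariance(df)
        fit_cov = cfa.fit_ml(cov, spec)
        R = df.corr()
        cov_r = cfa.CovarianceSummary(S=R, n=300, means=df.mean(), sds=df.std(ddof=1))
        fit_corr = cfa.fit_ml(cov_r, spec)
        assert np.abs(fit_cov.lambda_std - fit_corr.lambda_std).max() < 1e-5

    def test_heywood_case_clamped_and_flagged(self):
        # implied uniqueness of the first item is negative (lambda^2 = 1.7)
        R = np.array([[1.0, 0.85, 0.7], [0.85, 1.0, 0.35], [0.7, 0.35, 1.0]])
        cov, items = _cov_summary(R, n=200)
        fit = cfa.fit_ml(cov, cfa.single_factor_spec(items))
        assert fit.heywood_items == ("x0",)
        assert fit.theta["x0"] <= 1.1e-6

    def test_non_pd_covariance_rejected(self):
        R = np.array([[1.0, 0.9, 0.7], [0.9, 1.0, 0.3], [0.7, 0.3, 1.0]])
        cov, items = _cov_summary(R)
        with pytest.raises(ValueError, match="positive definite"):
            cfa.fit_ml(cov, cfa.single_factor_spec(items))


class TestSatorraBentler:
    def test_df_zero_flagged(self):
        rng = np.random.default_rng(0)
        Sigma = np.eye(3) + 0.4 * (1 - np.eye(3))
        X = rng.standard_normal((200, 3)) @ np.linalg.cholesky(Sigma).T
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        fit = cfa.fit_ml(cfa.sample_covariance(df), cfa.single_factor_spec(df.columns))
        fit = cfa.satorra_bentler(df, fit)
        assert fit.sb_c == 1.0
        assert fit.chi2_scaled == fit.chi2
        assert "df=0" in fit.sb_flag

    def test_heavy_tails_inflate_scaling(self):
        rng = np.random.default_rng(3)
        Sigma, _, _ = _two_factor_sigma()
        n = 8000
        g = rng.chisquare(5, n) / 5  # multivariate t with 5 df
        X = (rng.standard_normal((n, 6)) @ np.linalg.cholesky(Sigma).T) / np.sqrt(g)[:, None]
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(6)])
        spec = cfa.correlated_spec({"f1": list(df.columns[:3]), "f2": list(df.columns[3:])})
        fit = cfa.satorra_bentler(df, cfa.fit_ml(cfa.sample_covariance(df), spec))
        assert fit.sb_c > 1.2


class TestFitIndices:
    def test_chi2_equal_df_gives_saturated_indices(self):
        Sigma, _, _ = _two_factor_sigma()
        cov, items = _cov_summary(Sigma, n=201)
        spec = cfa.correlated_spec({"f1": items[:3], "f2": items[3:]})
        fit = cfa.fit_ml(cov, spec)
        idx = cfa.fit_indices(fit, cfa.independence_baseline(cov))
        assert idx.rmsea == 0.0
        assert idx.cfi == 1.0
        assert idx.srmr <= 1e-6

    def test_rmsea_closed_form(self):
        # chi2=100, df=50, n=201 -> sqrt(50/(50*200)) = 0.0707
        rmsea = np.sqrt(max(0.0, (100 - 50) / (50 * 200)))
        assert rmsea == pytest.approx(0.0707, abs=5e-5)

    def test_rmsea_monotone_in_chi2(self):
        df_, n = 40, 300
        vals = [
            np.sqrt(max(0.0, (c - df_) / (df_ * (n - 1)))) for c in (50, 80, 120, 200)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_rmsea_ci_properties(self):
        lo, hi = cfa.rmsea_ci(30.0, 40, 300)
        assert (lo, hi) == (0.0, pytest.approx(hi))
        chi2, df_, n = 265.09, 74, 698
        lo, hi = cfa.rmsea_ci(chi2, df_, n)
        point = np.sqrt((chi2 - df_) / (df_ * (n - 1)))
        assert lo <= point <= hi
        assert 0 < lo < hi < 0.10

    def test_baseline_must_match_items(self):
        Sigma, _, _ = _two_factor_sigma()
        cov, items = _cov_summary(Sigma)
        spec = cfa.correlated_spec({"f1": items[:3], "f2": items[3:]})
        fit = cfa.fit_ml(cov, spec)
        other, _ = _cov_summary(np.eye(4))
        with pytest.raises(ValueError, match="same items"):
            cfa.fit_indices(fit, cfa.independence_baseline(other))


class TestCompareModels:
    def test_self_comparison_zero_deltas(self):
        Sigma, _, _ = _two_factor_sigma()
        cov, items = _cov_summary(Sigma)
        spec = cfa.correlated_spec({"f1": items[:3], "f2": items[3:]})
        fit = cfa.fit_ml(cov, spec)
        base = cfa.independence_baseline(cov)
        idx = cfa.fit_indices(fit, base)
        rec = cfa.compare_models(fit, fit, idx, idx)
        assert rec["delta_chi2"] == 0.0 and rec["delta_df"] == 0
        assert rec["delta_rmsea"] == 0.0

    def test_two_factor_beats_one_factor_on_two_factor_data(self):
        rng = np.random.default_rng(13)
        lam = np.full(6, 0.7)
        fidx = np.array([0, 0, 0, 1, 1, 1])
        phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        Lam = np.zeros((6, 2))
        Lam[np.arange(6), fidx] = lam
        Sigma = Lam @ phi @ Lam.T
        np.fill_diagonal(Sigma, 1.0)
        X = rng.standard_normal((600, 6)) @ np.linalg.cholesky(Sigma).T
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(6)])
        cov = cfa.sample_covariance(df)
        base = cfa.independence_baseline(cov)
        fit1 = cfa.fit_ml(cov, cfa.single_factor_spec(df.columns))
        fit2 = cfa.fit_ml(
            cov, cfa.correlated_spec({"f1": list(df.columns[:3]), "f2": list(df.columns[3:])})
        )
        idx1 = cfa.fit_indices(fit1, base)
        idx2 = cfa.fit_indices(fit2, base)
        assert idx2.rmsea < idx1.rmsea

    def test_different_items_rejected(self):
        Sigma, _, _ = _two_factor_sigma()
        cov, items = _cov_summary(Sigma)
        fit = cfa.fit_ml(cov, cfa.single_factor_spec(items))
        other, oitems = _cov_summary(np.eye(4) + 0.2 * (1 - np.eye(4)))
        fit_o = cfa.fit_ml(other, cfa.single_factor_spec(oitems))
        with pytest.raises(ValueError, match="same items"):
            cfa.compare_models(fit, fit_o)
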