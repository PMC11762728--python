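import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import divelev as dl
from divelev.regress import (
    aicc,
    beta_fit,
    compress_unit_interval,
    design_matrix,
    glm_fit,
    lr_test,
    pseudo_r2,
    quadratic_vertex,
)


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def beta_sample(rng, X, beta, phi):
    mu = logistic(X @ beta)
    return rng.beta(mu * phi, (1 - mu) * phi)


class TestBetaFit:
    def test_intercept_only_constant_half(self):
        fit = beta_fit(pd.DataFrame(index=range(25)), np.full(25, 0.5))
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_linked_relation_pseudo_r2_one(self):
        T = np.linspace(0, 25, 60)
        y = logistic(-2.6 + 0.02 * T)
        fit = beta_fit(pd.DataFrame({"t": T}), y)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-8)
        assert fit.params["t"] == pytest.approx(0.02, abs=1e-6)

    def test_boundary_values_compressed_not_fatal(self):
        y = np.array([0.0, 0.1, 0.3, 0.5, 0.2, 0.4, 0.15, 0.05])
        fit = beta_fit(pd.DataFrame(index=range(len(y))), y)
        assert np.isfinite(fit.params["const"])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_fit(pd.DataFrame(index=range(4)), [0.2, 0.4, 1.2, 0.5])

    def test_loglik_not_below_initializer(self):
        """Ascent check: the optimizer never ends worse than where it starts
        (enforced inside beta_fit; here we just confirm fits succeed on
        awkward, heteroskedastic-looking data)."""
        rng = np.random.default_rng(21)
        for seed in range(5):
            X = pd.DataFrame({"x": np.linspace(-2, 2, 80)})
            y = beta_sample(rng, np.column_stack([np.ones(80), X["x"]]),
                            np.array([-1.0, 0.8]), 12.0)
            fit = beta_fit(X, y)
            assert np.isfinite(fit.loglik)
            assert fit.phi > 0

    def test_wald_interval_coverage(self):
        """Simulation study at the study-like regime: beta = (-2.6, 0.022),
        phi = 100, n = 500; each coefficient's 95% Wald interval should cover
        the truth in >= 90% of replicates."""
        truth = np.array([-2.6, 0.022])
        T = np.tile(np.linspace(0, 25, 100), 5)
        X = pd.DataFrame({"bio1": T})
        design = np.column_stack([np.ones(len(T)), T])
        cover = np.zeros(2)
        n_rep = 200
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            y = beta_sample(rng, design, truth, 100.0)
            fit = beta_fit(X, y)
            lo = fit.params.to_numpy() - 1.96 * fit.bse.to_numpy()
            hi = fit.params.to_numpy() + 1.96 * fit.bse.to_numpy()
            cover += (lo <= truth) & (truth <= hi)
        assert (cover / n_rep >= 0.90).all()


class TestPseudoR2:
    def test_permuted_predictor_destroys_correlation(self):
        rng = np.random.default_rng(77)
        T = np.linspace(0, 25, 1000)
        y = beta_sample(rng, np.column_stack([np.ones(1000), T]),
                        np.array([-2.0, 0.05]), 60.0)
        fit = beta_fit(pd.DataFrame({"t": rng.permutation(T)}), y)
        assert fit.pseudo_r2 < 0.05

    def test_matches_direct_correlation_oracle(self):
        rng = np.random.default_rng(8)
        T = np.linspace(0, 20, 120)
        y = beta_sample(rng, np.column_stack([np.ones(120), T]),
                        np.array([-1.5, 0.06]), 40.0)
        fit = beta_fit(pd.DataFrame({"t": T}), y)
        gy = np.log(fit.y / (1 - fit.y))
        oracle = np.corrcoef(fit.linpred, gy)[0, 1] ** 2
        assert fit.pseudo_r2 == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        fit = beta_fit(pd.DataFrame(index=range(10)), np.full(10, 0.3))
        assert fit.pseudo_r2 is None


class TestGlmFit:
    def test_intercept_only_constant(self):
        fit = glm_fit(pd.DataFrame(index=range(3)), [60.0, 60.0, 60.0])
        assert fit.params["const"] == pytest.approx(60.0)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)
        assert fit.kl_r2 == 0.0

    def test_noiseless_linear_data_exact(self):
        x = np.linspace(0, 10, 40)
        y = 5.0 + 2.0 * x
        fit = glm_fit(pd.DataFrame({"x": x}), y)
        assert fit.params["const"] == pytest.approx(5.0, abs=1e-8)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-8)

    def test_deviance_formula_oracle(self):
        rng = np.random.default_rng(5)
        x = np.repeat(np.arange(31.0), 10)
        y = rng.poisson(50 + 3 * x - 0.13 * x**2).astype(float)
        fit = glm_fit(pd.DataFrame({"x": x, "x^2": x**2}), y)
        mu = fit.fitted
        oracle = 2 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        assert fit.deviance == pytest.approx(oracle, abs=1e-9)

    def test_quadratic_vertex_recovery(self):
        """Poisson draws from mu = 50 + 3x - 0.13x^2 on a 0..30 grid,
        n = 600: the fitted vertex lands within 0.5 of the truth 11.54."""
        rng = np.random.default_rng(600)
        x = np.repeat(np.arange(31.0), 20)[:600]
        y = rng.poisson(50 + 3 * x - 0.13 * x**2).astype(float)
        fit = glm_fit(pd.DataFrame({"x": x, "x^2": x**2}), y)
        vertex, kind = quadratic_vertex(fit.params["x"], fit.params["x^2"])
        assert kind == "maximum"
        assert vertex == pytest.approx(3 / (2 * 0.13), abs=0.5)

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError):
            glm_fit(pd.DataFrame(index=range(3)), [1.0, -1.0, 2.0])

    def test_kl_r2_in_unit_interval(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 10, 100)
        y = rng.poisson(20 + 2 * x).astype(float)
        fit = glm_fit(pd.DataFrame({"x": x}), y)
        assert 0.0 <= fit.kl_r2 <= 1.0
        assert fit.deviance <= fit.null_deviance
        assert fit.aicc > fit.aic


class TestQuadraticVertex:
    def test_origin_maximum(self):
        assert quadratic_vertex(0.0, -1.0) == (0.0, "maximum")

    def test_minimum_labeled(self):
        v, kind = quadratic_vertex(-4.0, 2.0)
        assert v == pytest.approx(1.0) and kind == "minimum"

    def test_no_vertex(self):
        with pytest.raises(ValueError):
            quadratic_vertex(1.0, 0.0)


class TestLrTest:
    def _fits(self, rng, quadratic_truth=False, n=120):
        x = np.linspace(0, 14, n)
        mu = 20 + 1.5 * x + (-(0.35) * (x - 7) ** 2 if quadratic_truth else 0)
        y = rng.poisson(np.clip(mu, 0.5, None)).astype(float)
        small = glm_fit(pd.DataFrame({"x": x}), y)
        large = glm_fit(pd.DataFrame({"x": x, "x^2": x**2}), y)
        return small, large

    def test_identical_models(self):
        rng = np.random.default_rng(1)
        small, _ = self._fits(rng)
        mc = lr_test(small, small)
        assert mc.statistic == 0.0 and mc.p == 1.0 and mc.df == 0

    def test_chi2_quantile(self):
        # p of a LR statistic of 3.84 on 1 df is ~0.050
        assert st.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 50)
        y = rng.poisson(10 + x).astype(float)
        a = glm_fit(pd.DataFrame({"x": x}), y)
        b = glm_fit(pd.DataFrame({"z": x**2}), y)
        with pytest.raises(ValueError, match="nested"):
            lr_test(a, b)

    def test_quadratic_term_never_lowers_loglik(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            small, large = self._fits(rng, quadratic_truth=rng.random() < 0.5)
            assert large.loglik >= small.loglik - 1e-6

    def test_type_i_error_calibrated(self):
        """Under a linear truth, the quadratic-vs-linear LR test at alpha=0.05
        rejects in about 5% of replicates (0.05 +/- 0.02 over 500 runs)."""
        rng = np.random.default_rng(1234)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            small, large = self._fits(rng, quadratic_truth=False, n=100)
            mc = lr_test(small, large)
            rejections += mc.p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestAicc:
    def test_hand_value(self):
        assert aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_tends_to_aic(self):
        assert aicc(-10.0, 3, 10**6) - (20 + 6) < 1e-3

    def test_domain(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)


class TestDesignMatrix:
    def test_formula_with_power_terms(self):
        df = pd.DataFrame({"age_elev": [1.0, 2, 3], "bio1": [2.0, 3, 4]})
        y, X, resp = design_matrix(df, "age_elev ~ bio1 + bio1^2")
        assert resp == "age_elev"
        assert list(X.columns) == ["bio1", "bio1^2"]
        assert X["bio1^2"].tolist() == [4.0, 9.0, 16.0]

    def test_nan_rows_dropped(self):
        df = pd.DataFrame({"y": [1.0, np.nan, 3], "x": [1.0, 2, 3]})
        y, X, _ = design_matrix(df, "y ~ x")
        assert len(y) == 2 and len(X) == 2
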