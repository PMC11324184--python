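import numpy as np
import pandas as pd
import pytest
from scipy import stats

from befmf.associations import (
    ModelAveraging,
    aicc,
    fit_mixed,
    partial_correlation,
    spearman,
)


class TestSpearman:
    def test_strictly_increasing(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 80])
        assert res.coefficient == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        # d = (2, 1, 1): rho = 1 - 6*6/(3*8) = -0.5
        res = spearman([1, 2, 3], [3, 1, 2])
        assert res.coefficient == pytest.approx(-0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = spearman(x, y).coefficient
        r2 = spearman(np.exp(x), y**3).coefficient
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_exact_p_matches_enumeration_for_perfect_rank(self):
        # only 2 of 4! = 24 orderings achieve |rho| = 1
        res = spearman([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.p == pytest.approx(2 / 24)

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(1)
        pvals = [
            spearman(rng.normal(size=20), rng.normal(size=20)).p for _ in range(2000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 40))
        res = partial_correlation(x, y)
        assert res.coefficient == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)
        assert res.p == pytest.approx(stats.pearsonr(x, y)[1], abs=1e-10)

    def test_common_cause_partialled_out(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(200):
            z = rng.normal(size=60)
            x = z + rng.normal(size=60)
            y = z + rng.normal(size=60)
            vals.append(partial_correlation(x, y, z).coefficient)
        assert abs(np.mean(vals)) < 0.02

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("xyzu"))
        df["y"] += 0.5 * df["x"] + 0.3 * df["z"]
        ours = partial_correlation(df["x"], df["y"], df[["z", "u"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "u"])
        assert ours.coefficient == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_recursive_formula_oracle(self):
        # single control: r_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))
        rng = np.random.default_rng(5)
        x, y, z = rng.normal(size=(3, 80))
        y = y + 0.4 * x + 0.6 * z
        r_xy = stats.pearsonr(x, y)[0]
        r_xz = stats.pearsonr(x, z)[0]
        r_yz = stats.pearsonr(y, z)[0]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert partial_correlation(x, y, z).coefficient == pytest.approx(
            expected, abs=1e-10
        )

    def test_collinear_controls_rejected(self):
        x = np.arange(20.0)
        y = np.random.default_rng(6).normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, x)


class TestAICc:
    def test_no_parameter_penalty(self):
        assert aicc(-5.0, 0, 50) == pytest.approx(10.0)

    def test_formula_by_hand(self):
        assert aicc(-10, 3, 20) == pytest.approx(20 + 6 + 24 / 16)

    def test_converges_to_aic(self):
        assert aicc(-10, 3, 10**5) - (20 + 6) < 1e-3

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10, 5, 6)


class TestModelAveraging:
    def test_single_predictor_reproduces_ols(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        res = ModelAveraging(y, pd.DataFrame({"x": x})).fit()
        assert res.importance_pct["x"] == pytest.approx(100.0)
        from befmf._utils import zscore
        import statsmodels.api as sm

        ols = sm.OLS(zscore(y), sm.add_constant(zscore(x))).fit()
        # a single predictor means a single candidate model: the averaged
        # slope is exactly that model's OLS slope
        assert res.coefficients["x"] == pytest.approx(ols.params[1], abs=1e-12)

    def test_akaike_weights_and_importance_sums(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = X["a"] - 0.5 * X["c"] + rng.normal(size=60)
        res = ModelAveraging(y, X).fit()
        assert res.model_table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert res.importance_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert len(res.model_table) == 2**4 - 1  # every non-empty subset

    def test_near_duplicate_predictors_share_importance(self):
        rng = np.random.default_rng(9)
        shares = []
        for _ in range(40):
            a = rng.normal(size=80)
            b = a + 0.05 * rng.normal(size=80)  # near-duplicate
            y = a + b + 0.5 * rng.normal(size=80)
            res = ModelAveraging(y, pd.DataFrame({"a": a, "b": b})).fit()
            shares.append(res.importance_pct["a"])
        assert np.mean(shares) == pytest.approx(50.0, abs=5.0)

    def test_null_predictors_centered_at_zero(self):
        rng = np.random.default_rng(10)
        betas = []
        for _ in range(300):
            X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
            res = ModelAveraging(rng.normal(size=40), X).fit()
            betas.append(res.coefficients.to_numpy())
        mean_abs = np.abs(np.mean(betas, axis=0))
        assert (mean_abs < 0.02).all()

    def test_exact_collinearity_guard(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError, match="collinear"):
            ModelAveraging(x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_predictor_count_guard(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(30, 13)))
        with pytest.raises(ValueError, match="12"):
            ModelAveraging(rng.normal(size=30), X)

    def test_natural_vs_zero_averaging(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=list("ab"))
        y = 0.2 * X["a"] + rng.normal(size=50)
        zero = ModelAveraging(y, X, averaging="zero").fit()
        nat = ModelAveraging(y, X, averaging="natural").fit()
        # shrinking towards zero in models that drop the predictor makes
        # the zero-method coefficient smaller in magnitude
        assert abs(zero.coefficients["a"]) <= abs(nat.coefficients["a"]) + 1e-12


class TestMixedModel:
    def test_reduces_to_ols_without_group_variance(self):
        import befmf

        cfg = befmf.MicrocosmConfig(sigma_combination=0.0, n_replicates=25)
        d, div, f, _ = befmf.generate_microcosm(cfg, seed=5)
        from befmf._utils import zscore
        import statsmodels.api as sm

        X = pd.DataFrame(
            {
                "plant": zscore(d["plant_richness"].astype(float)),
                "drought": d["drought"].astype(float),
            }
        )
        y = f["total_N"].to_numpy()
        mixed = fit_mixed(y, X, d["plant_combination"].to_numpy())
        ols = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
        # REML puts the group variance at (or near) the boundary when the
        # true variance is zero; at the boundary the GLS fit is exactly OLS,
        # otherwise the fixed effects differ only by the tiny estimated
        # variance component
        if mixed.group_var < 1e-8:
            np.testing.assert_allclose(
                mixed.params.to_numpy(), np.asarray(ols.params), atol=1e-6
            )
        else:
            assert mixed.group_var < 0.02
            np.testing.assert_allclose(
                mixed.params.to_numpy(), np.asarray(ols.params), atol=0.02
            )

    def test_single_group_falls_back_to_ols(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        fit = fit_mixed(X["x"] * 2 + rng.normal(size=20), X, np.repeat("g1", 20))
        assert fit.ols_fallback
        assert fit.group_var == 0.0

    def test_recovers_group_variance(self, microcosm_default):
        d, div, f, truth = microcosm_default
        from befmf._utils import zscore

        X = pd.DataFrame(
            {
                "plant": zscore(d["plant_richness"].astype(float)),
                "micro": zscore(div["microbial_composite"].to_numpy()),
                "drought": d["drought"].astype(float),
            }
        )
        fit = fit_mixed(f["total_C"].to_numpy(), X, d["plant_combination"].to_numpy())
        assert fit.group_var >= 0
        assert fit.resid_var > 0
        assert np.isfinite(fit.bse).all()
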