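import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from befmf.multifunctionality import (
    DegenerateColumnError,
    Multifunctionality,
    averaged_emf,
    best_fit_regression,
    composite_richness,
    multithreshold_counts,
    standardize_function,
    standardize_matrix,
    threshold_slope_curve,
    validate_service_map,
    weighted_emf,
)


def _random_matrix(rng, n=20, p=8):
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)]
    )


class TestStandardize:
    def test_linear_spacing(self):
        np.testing.assert_allclose(standardize_function([2, 4, 6]), [0, 0.5, 1])

    def test_log_spacing_is_linear(self):
        np.testing.assert_allclose(
            standardize_function([1, 10, 100], "log"), [0, 0.5, 1], atol=1e-12
        )

    def test_constant_column_raises(self):
        with pytest.raises(DegenerateColumnError):
            standardize_function([5, 5, 5])

    @pytest.mark.parametrize(
        "values,transform", [([0, 1, 2], "log"), ([-1, 1, 2], "sqrt")]
    )
    def test_transform_domain_errors(self, values, transform):
        with pytest.raises(ValueError):
            standardize_function(values, transform)

    def test_order_preserved_and_extremes_attained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        s = standardize_function(x)
        assert s.min() == 0 and s.max() == 1
        assert np.all(np.argsort(s) == np.argsort(x))

    def test_missing_values_propagate(self):
        s = standardize_function([1.0, np.nan, 3.0, 5.0])
        assert np.isnan(s[1]) and s[0] == 0 and s[3] == 1


class TestServiceMap:
    def test_requires_partition(self):
        with pytest.raises(ValueError, match="appears in services"):
            validate_service_map({"a": ["f1"], "b": ["f1"]}, ["f1"])
        with pytest.raises(ValueError, match="not assigned"):
            validate_service_map({"a": ["f1"]}, ["f1", "f2"])
        with pytest.raises(KeyError):
            validate_service_map({"a": ["nope"]}, ["f1"])
        with pytest.raises(ValueError, match="no member"):
            validate_service_map({"a": []}, [])


class TestEMF:
    def test_service_mean_example(self):
        std = pd.DataFrame({"f1": [0.2], "f2": [0.4], "f3": [0.6]})
        smap = {"s1": ["f1"], "s2": ["f2"], "s3": ["f3"]}
        _, emf = weighted_emf(std, smap)
        assert emf.iloc[0] == pytest.approx(0.4)

    def test_single_service_equals_averaged(self):
        rng = np.random.default_rng(1)
        std = standardize_matrix(_random_matrix(rng))
        _, w = weighted_emf(std, {"all": list(std.columns)})
        np.testing.assert_allclose(w, averaged_emf(std), atol=1e-14)

    def test_two_stage_mean_oracle(self):
        # unequal service sizes (3,2,3,2,3,3): the index must equal a
        # brute-force groupby mean-of-means computed independently
        rng = np.random.default_rng(2)
        std = standardize_matrix(_random_matrix(rng, n=30, p=16))
        sizes = [3, 2, 3, 2, 3, 3]
        cols = iter(std.columns)
        smap = {f"s{i}": [next(cols) for _ in range(k)] for i, k in enumerate(sizes)}
        _, w = weighted_emf(std, smap)
        brute = np.mean(
            [[std.loc[i, m].mean() for m in smap.values()] for i in std.index], axis=1
        )
        np.testing.assert_allclose(w.to_numpy(), brute, atol=1e-12)

    def test_equal_service_sizes_identity(self):
        rng = np.random.default_rng(3)
        std = standardize_matrix(_random_matrix(rng, p=6))
        smap = {"a": ["f0", "f1"], "b": ["f2", "f3"], "c": ["f4", "f5"]}
        _, w = weighted_emf(std, smap)
        np.testing.assert_allclose(w, averaged_emf(std), atol=1e-12)

    def test_all_zero_matrix_averages_to_zero(self):
        std = pd.DataFrame(np.zeros((4, 3)), columns=list("abc"))
        assert averaged_emf(std).eq(0).all()

    @given(
        arrays(float, (12, 6), elements=st.floats(-50, 50)),
        st.floats(0.1, 9.0),
        st.floats(-20, 20),
    )
    def test_affine_invariance(self, raw, a, b):
        # a strictly increasing affine map of any raw function leaves the
        # standardized values (hence both EMF indices) unchanged
        df = pd.DataFrame(raw, columns=[f"f{j}" for j in range(6)])
        if any(df[c].nunique() < 2 for c in df.columns):
            return
        std1 = standardize_matrix(df)
        df2 = df.copy()
        df2["f0"] = a * df2["f0"] + b
        std2 = standardize_matrix(df2)
        np.testing.assert_allclose(std1, std2, atol=1e-9)

    def test_bounds_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            std = standardize_matrix(_random_matrix(rng))
            smap = {"a": list(std.columns[:4]), "b": list(std.columns[4:])}
            _, w = weighted_emf(std, smap)
            assert ((w >= 0) & (w <= 1)).all()
            av = averaged_emf(std)
            assert ((av >= 0) & (av <= 1)).all()


class TestCompositeRichness:
    def test_single_group(self):
        np.testing.assert_allclose(
            composite_richness(pd.DataFrame({"r": [10, 20, 30]})), [0, 0.5, 1]
        )

    def test_brute_force_three_groups(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "plant": rng.integers(1, 30, 25),
                "bacteria": rng.integers(100, 3000, 25),
                "fungi": rng.integers(50, 800, 25),
            }
        )
        comp = composite_richness(df)
        brute = np.mean(
            [standardize_function(df[c].to_numpy()) for c in df.columns], axis=0
        )
        np.testing.assert_allclose(comp.to_numpy(), brute, atol=1e-12)
        assert comp.between(0, 1).all()

    def test_constant_group_raises(self):
        with pytest.raises(DegenerateColumnError):
            composite_richness(pd.DataFrame({"r": [3, 3, 3]}))


class TestMultithreshold:
    def test_hand_enumeration_strict(self):
        f = pd.DataFrame({"f1": [1.0, 0.5], "f2": [10.0, 2.0]})
        counts = multithreshold_counts(f, [50])
        # maxima (1, 10); cutoffs (0.5, 5): 1>0.5 and 10>5 but 0.5>0.5 is
        # false under strict exceedance and 2>5 is false
        assert counts[50].tolist() == [2, 0]

    def test_inclusive_variant(self):
        f = pd.DataFrame({"f1": [1.0, 0.5], "f2": [10.0, 2.0]})
        counts = multithreshold_counts(f, [50], inclusive=True)
        assert counts[50].tolist() == [2, 1]

    def test_low_threshold_counts_everything(self):
        f = pd.DataFrame({"f1": [5.0, 6.0], "f2": [7.0, 8.0]})
        counts = multithreshold_counts(f, [5])
        assert (counts[5] == 2).all()

    def test_extreme_threshold_bound(self):
        rng = np.random.default_rng(6)
        f = _random_matrix(rng) + 10
        counts = multithreshold_counts(f, [99.999])
        assert counts[99.999].sum() <= f.shape[1]

    @pytest.mark.parametrize("t", [0, 100, -5])
    def test_threshold_range_errors(self, t):
        with pytest.raises(ValueError):
            multithreshold_counts(pd.DataFrame({"f": [1.0, 2.0]}), [t])

    @given(arrays(float, (10, 5), elements=st.floats(0.1, 100)))
    def test_counts_monotone_in_threshold(self, raw):
        f = pd.DataFrame(raw, columns=[f"f{j}" for j in range(5)])
        counts = multithreshold_counts(f, [10, 25, 50, 75, 90])
        arr = counts.to_numpy()
        assert np.all(np.diff(arr, axis=1) <= 0)
        assert arr.min() >= 0 and arr.max() <= 5


class TestThresholdSlopes:
    def test_exact_linear_counts(self):
        d = np.array([1.0, 2, 3, 4, 5])
        counts = pd.DataFrame({50: (2 * d).astype(int)})
        prof = threshold_slope_curve(d, counts)
        assert prof.slopes.loc[50, "slope"] == pytest.approx(2.0)
        assert prof.slopes.loc[50, "adj_r2"] == pytest.approx(1.0)

    def test_constant_counts(self):
        d = np.array([1.0, 2, 3, 4, 5])
        counts = pd.DataFrame({50: [3, 3, 3, 3, 3]})
        prof = threshold_slope_curve(d, counts)
        assert prof.slopes.loc[50, "slope"] == pytest.approx(0.0)
        assert prof.slopes.loc[50, "adj_r2"] <= 0

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=30)
        counts = pd.DataFrame({t: rng.integers(0, 10, 30) for t in (10, 50, 90)})
        prof = threshold_slope_curve(d, counts)
        X = np.column_stack([np.ones(30), d])
        for t in (10, 50, 90):
            beta = np.linalg.solve(X.T @ X, X.T @ counts[t].to_numpy())
            assert prof.slopes.loc[t, "slope"] == pytest.approx(beta[1], abs=1e-10)

    def test_constant_diversity_raises(self):
        with pytest.raises(DegenerateColumnError):
            threshold_slope_curve(np.ones(5), pd.DataFrame({50: [1, 2, 3, 4, 5]}))


class TestBestFit:
    def test_exact_parabola_selects_quadratic(self):
        x = np.linspace(-3, 3, 20)
        res = best_fit_regression(x, 1 + 2 * x - 0.5 * x**2)
        assert res["fit"] == "quadratic"
        assert res["adj_r2"] == pytest.approx(1.0)

    def test_exact_line_selects_linear(self):
        # with a true zero quadratic term the adjustment penalty means the
        # quadratic fit cannot beat the line on adjusted R²
        x = np.linspace(0, 10, 25)
        res = best_fit_regression(x, 3 - 0.7 * x)
        assert res["fit"] == "linear"
        assert res["adj_r2"] == pytest.approx(1.0)

    def test_noise_only_selection_near_chance(self):
        rng = np.random.default_rng(8)
        picks = []
        slopes = []
        for _ in range(300):
            x = rng.normal(size=25)
            res = best_fit_regression(x, rng.normal(size=25))
            picks.append(res["fit"] == "quadratic")
            slopes.append(res["coefficients"][1])
        assert 0.2 < np.mean(picks) < 0.8
        assert abs(np.mean(slopes)) < 0.05

    def test_constant_x_raises(self):
        with pytest.raises(DegenerateColumnError):
            best_fit_regression(np.ones(10), np.arange(10.0))


class TestModelObject:
    def test_fit_flags_incomplete_samples(self):
        f = pd.DataFrame(
            {"f1": [1.0, 2, 3, 4], "f2": [np.nan, np.nan, np.nan, 4.0]},
            index=list("abcd"),
        )
        # f2 observed only once cannot be standardized
        with pytest.raises(DegenerateColumnError):
            Multifunctionality(f, {"s1": ["f1"], "s2": ["f2"]}).fit()

    def test_result_frame_round_trip(self, microcosm_default):
        _, _, functions, _ = microcosm_default
        from befmf import MICROCOSM_SERVICE_MAP

        res = Multifunctionality(functions, MICROCOSM_SERVICE_MAP).fit()
        frame = res.to_frame()
        assert list(frame.columns[-2:]) == ["emf_weighted", "emf_averaged"]
        assert frame.notna().all().all()
        assert res.standardized.to_numpy().min() >= 0
        assert res.standardized.to_numpy().max() <= 1
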