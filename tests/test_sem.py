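"""ML covariance-structure fitting: data preparation, discrepancy function,
estimation oracles, fit indices, bootstrap and model ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import endopath as ep
from conftest import random_correlation, table_from_matrix


def _table(columns: dict, species=None) -> ep.TraitTable:
    df = pd.DataFrame(columns)
    if species is not None:
        df.index = species
    return ep.TraitTable(df)


class TestPrepare:
    def test_log10_then_standardize(self):
        t = _table({"x": [10.0, 100.0, 1000.0]})
        out = ep.prepare(t, {"x"})
        assert out.transform_state["x"] == "standardized"
        np.testing.assert_allclose(out.data["x"], [-1, 0, 1])

    def test_idempotent_on_standardized_input(self, rng):
        t = ep.prepare(_table({"x": rng.normal(size=12), "y": rng.normal(size=12)}))
        again = ep.prepare(t)
        np.testing.assert_allclose(again.data.to_numpy(), t.data.to_numpy(), atol=1e-10)

    def test_every_column_zero_mean_unit_sd(self, rng):
        t = _table({"a": rng.uniform(1, 9, 20), "b": rng.exponential(2, 20)})
        out = ep.prepare(t, {"b"})
        assert np.allclose(out.data.mean(), 0, atol=1e-10)
        assert np.allclose(out.data.std(ddof=1), 1, atol=1e-10)

    def test_nonpositive_log_value_names_species_and_column(self):
        t = _table({"x": [1.0, -2.0, 3.0]}, species=["s1", "s2", "s3"])
        with pytest.raises(ep.DataError, match="x.*s2"):
            ep.prepare(t, {"x"})

    def test_missing_values_rejected(self):
        with pytest.raises(ep.DataError):
            _table({"x": [1.0, np.nan, 3.0]})


class TestSampleCorrelation:
    def test_structure(self, rng):
        t = table_from_matrix(rng.standard_normal((30, 4)), list("abcd"))
        S = ep.sample_correlation(t).to_numpy()
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)
        assert np.linalg.eigvalsh(S).min() > -1e-12

    def test_large_sample_independence(self, rng):
        n = 100_000
        t = table_from_matrix(rng.standard_normal((n, 3)), list("abc"))
        S = ep.sample_correlation(t).to_numpy()
        off = S[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n))

    def test_collinear_columns_flagged(self, rng):
        x = rng.standard_normal(25)
        t = table_from_matrix(np.column_stack([x, 2 * x]), ["a", "b"])
        with pytest.warns(UserWarning, match="singular"):
            S = ep.sample_correlation(t)
        assert S.loc["a", "b"] == pytest.approx(1.0)

    def test_too_few_rows(self, rng):
        t = ep.TraitTable(pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]}))
        with pytest.raises(ep.DataError):
            ep.sample_correlation(t)


class TestMLDiscrepancy:
    def test_zero_iff_equal(self, rng):
        S = random_correlation(4, rng)
        assert ep.ml_discrepancy(S, S) == pytest.approx(0, abs=1e-12)
        assert ep.ml_discrepancy(S, np.eye(4)) > 0

    def test_closed_form_two_by_two(self):
        S = np.array([[1, 0.5], [0.5, 1]])
        # ln|I| + tr(S) - ln|S| - 2 = -ln(0.75)
        assert ep.ml_discrepancy(S, np.eye(2)) == pytest.approx(0.287682, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        S = random_correlation(4, rng)
        Sigma = random_correlation(4, rng)
        perm = rng.permutation(4)
        f1 = ep.ml_discrepancy(S, Sigma)
        f2 = ep.ml_discrepancy(S[np.ix_(perm, perm)], Sigma[np.ix_(perm, perm)])
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_non_positive_definite_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            ep.ml_discrepancy(np.eye(2), S)


class TestFitML:
    def test_single_path_closed_form(self, rng):
        x = rng.standard_normal(60)
        y = 0.7 * x + rng.standard_normal(60)
        t = table_from_matrix(np.column_stack([x, y]), ["x", "y"])
        r = float(ep.sample_correlation(t).loc["x", "y"])
        m = ep.build_model(["x", "y"], [("x", "y", "b")])
        fit = ep.fit_ml(m, t, ep.FitOptions(n_restarts=2))
        assert fit.converged
        assert fit.estimates["b"] == pytest.approx(r, abs=1e-6)
        assert fit.estimates["v_y"] == pytest.approx(1 - r * r, abs=1e-6)
        assert fit.chi2 == pytest.approx(0, abs=1e-6)

    def test_fully_free_model_is_just_identified(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        t = table_from_matrix(np.column_stack([x, y]), ["x", "y"])
        m = ep.build_model(
            ["x", "y"], [("x", "y", "b")], fixed_unit_variance=()
        )
        fit = ep.fit_ml(m, t, ep.FitOptions(n_restarts=2))
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0, abs=1e-8)
        assert np.isnan(fit.rmsea)

    def test_ml_equals_ols_on_recursive_model(self, rng):
        X = rng.standard_normal((40, 3)) @ random_correlation(3, rng)
        t = table_from_matrix(X, ["mb", "BMR", "MMR"])
        m = ep.build_model(
            ["mb", "BMR", "MMR"],
            [("mb", "BMR", "b2"), ("mb", "MMR", "b1"), ("BMR", "MMR", "c")],
        )
        fit = ep.fit_ml(m, t, ep.FitOptions(n_restarts=2))
        S = ep.sample_correlation(t).to_numpy()
        b2_ols = S[0, 1]
        b_ols = np.linalg.solve(S[:2, :2], S[:2, 2])
        assert fit.estimates["b2"] == pytest.approx(b2_ols, abs=1e-6)
        assert fit.estimates["b1"] == pytest.approx(b_ols[0], abs=1e-6)
        assert fit.estimates["c"] == pytest.approx(b_ols[1], abs=1e-6)

    def test_parameter_recovery_model_vi(self):
        model = ep.model_zoo("VI", b3="covariance")
        theta = dict(ep.DEFAULT_THETA)
        t = ep.simulate_traits(model, theta, 5000, seed=3)
        fit = ep.fit_ml(model, t, ep.FitOptions(n_restarts=2, seed=0))
        assert fit.converged
        for name, true in theta.items():
            assert abs(fit.estimates[name] - true) < 3 * fit.se[name], name

    def test_missing_variable_rejected(self, rng):
        t = table_from_matrix(rng.standard_normal((20, 2)), ["x", "y"])
        with pytest.raises(ep.DataError):
            ep.fit_ml(ep.model_zoo("VI"), t)

    def test_seed_reproducible(self, trait_table_vi):
        m = ep.model_zoo("VI")
        opts = ep.FitOptions(n_restarts=3, seed=5)
        f1 = ep.fit_ml(m, trait_table_vi, opts)
        f2 = ep.fit_ml(m, trait_table_vi, opts)
        assert f1.estimates == f2.estimates


class TestFitIndices:
    # printed (chi2, df) -> printed BIC, at n = 17 species
    @pytest.mark.parametrize(
        "chi2,df,expected",
        [(6.33, 8, -16.3), (1.29, 5, -12.9), (4.13, 7, -15.7)],
    )
    def test_bic_published_rows(self, chi2, df, expected):
        assert ep.bic(chi2, df, 17) == pytest.approx(expected, abs=0.05)

    def test_bic_zero_df_identity(self):
        for c, n in [(2.5, 17), (0.0, 5), (11.0, 200)]:
            assert ep.bic(c, 0, n) == c

    @pytest.mark.parametrize(
        "chi2,df,expected",
        [(11.08, 7, 0.19), (10.65, 6, 0.22), (3.30, 8, 0.0)],
    )
    def test_rmsea_published_rows(self, chi2, df, expected):
        assert ep.rmsea(chi2, df, 17) == pytest.approx(expected, abs=0.005)

    def test_rmsea_boundary_and_undefined(self):
        assert ep.rmsea(6.0, 6, 17) == 0.0
        assert np.isnan(ep.rmsea(3.0, 0, 17))


class TestBootstrap:
    @pytest.fixture()
    def xy_table(self, rng):
        x = rng.standard_normal(40)
        y = 0.8 * x + 0.6 * rng.standard_normal(40)
        return table_from_matrix(np.column_stack([x, y]), ["x", "y"])

    @pytest.fixture()
    def xy_model(self):
        return ep.build_model(["x", "y"], [("x", "y", "b")])

    def test_same_seed_identical(self, xy_model, xy_table):
        a = ep.bootstrap_ci(xy_model, xy_table, n_replicates=40, seed=11)
        b = ep.bootstrap_ci(xy_model, xy_table, n_replicates=40, seed=11)
        assert a.intervals == b.intervals

    def test_row_order_invariance(self, xy_model, xy_table, rng):
        perm = rng.permutation(xy_table.n)
        shuffled = ep.TraitTable(xy_table.data.iloc[perm])
        a = ep.bootstrap_ci(xy_model, xy_table, n_replicates=40, seed=11)
        b = ep.bootstrap_ci(xy_model, shuffled, n_replicates=40, seed=11)
        assert a.intervals == b.intervals

    def test_single_replicate_degenerate(self, xy_model, xy_table):
        res = ep.bootstrap_ci(xy_model, xy_table, n_replicates=1, seed=0)
        lo, hi = res.intervals["b"]
        assert lo == hi

    def test_coverage_of_true_coefficient(self):
        """Percentile intervals on resampled species cover the generating
        coefficient at roughly the nominal rate."""
        b_true = 0.8
        m = ep.build_model(["x", "y"], [("x", "y", "b")])
        hits = 0
        outer = 30
        for i in range(outer):
            rng = np.random.default_rng(100 + i)
            x = rng.standard_normal(200)
            y = b_true * x + np.sqrt(1 - b_true**2) * rng.standard_normal(200)
            t = table_from_matrix(np.column_stack([x, y]), ["x", "y"])
            res = ep.bootstrap_ci(m, t, n_replicates=199, seed=i)
            lo, hi = res.intervals["b"]
            hits += lo <= b_true <= hi
        assert hits / outer >= 0.8


class TestModelSelection:
    def _fit(self, mid, bic, df, n=17):
        return ep.FitResult(
            model_id=mid, parameters=(), estimates={}, se={}, z={}, p_wald={},
            f_min=0.0, chi2=0.0, df=df, p_chi2=1.0, bic=bic, rmsea=0.0,
            r2={}, converged=True, heywood=False, n_used=n,
        )

    def test_sorted_by_bic(self):
        out = ep.model_selection_table(
            [self._fit("V", -17.5, 7), self._fit("VI", -19.3, 8)]
        )
        assert list(out["model_id"]) == ["VI", "V"]

    def test_tie_broken_by_larger_df_then_id(self):
        out = ep.model_selection_table(
            [self._fit("B", -10.0, 5), self._fit("A", -10.0, 7), self._fit("C", -10.0, 7)]
        )
        assert list(out["model_id"]) == ["A", "C", "B"]

    def test_single_fit(self):
        out = ep.model_selection_table([self._fit("VI", -19.3, 8)])
        assert len(out) == 1

    def test_mixed_sample_sizes_rejected(self):
        with pytest.raises(ValueError):
            ep.model_selection_table(
                [self._fit("A", -1.0, 5, n=17), self._fit("B", -2.0, 5, n=20)]
            )


class TestEquationsReport:
    def test_report_contains_fitted_equations(self, trait_table_vi):
        m = ep.model_zoo("VI")
        fit = ep.fit_ml(m, trait_table_vi, ep.FitOptions(n_restarts=2))
        text = ep.equations_report([fit], {"VI": m})
        assert "Model VI:" in text
        assert "R_max =" in text and "MMR" in text
        assert "(P = " in text
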