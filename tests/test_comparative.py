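import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tisdiv import comparative, synthetic
from tisdiv.comparative import (
    backward_elimination_cv,
    box_cox_transform,
    correlation_matrix,
    filter_extreme,
    pagel_covariance,
    pgls_pagel,
    scaled_ols,
    spearman,
    tree_covariance,
    vif,
)


class TestBoxCox:
    @pytest.mark.parametrize("lam,x,expected", [(0.0, math.e, 1.0), (1.0, 5.0, 4.0), (0.5, 4.0, 2.0)])
    def test_known_values(self, lam, x, expected):
        assert box_cox_transform([x], lam)[0] == pytest.approx(expected)

    def test_nonpositive_rejected_with_rows(self):
        with pytest.raises(ValueError, match="offending rows: \\[1\\]"):
            box_cox_transform([1.0, -2.0, 3.0], 0.5)

    @given(st.floats(-2, 2), st.lists(st.integers(1, 1000), min_size=3, max_size=10, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing(self, lam, xs):
        x = np.sort(np.asarray(xs, dtype=float)) / 10.0
        out = box_cox_transform(x, lam)
        assert (np.diff(out) > 0).all()


class TestSpearman:
    def test_monotone_is_one(self):
        x = [1, 2, 3, 4, 5, 6]
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = [1.0, 2, 3, 4, 5]
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_tied_toy_matches_hand_ranks(self):
        # y = [2, 1, 3, 3, 5]: ranks [2, 1, 3.5, 3.5, 5] (average ranks)
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 3, 3, 5]
        rx = np.array([1, 2, 3, 4, 5.0])
        ry = np.array([2, 1, 3.5, 3.5, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected)

    def test_pairwise_complete(self):
        x = [1, 2, np.nan, 4, 5, 6, 7, 8]
        y = [1, 2, 3, 4, 5, np.nan, 7, 8]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(np.linalg.qr(rng.standard_normal((50, 3)))[0],
                         columns=list("abc"))
        assert (vif(X) < 1.2).all()

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        v = vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        base = rng.standard_normal(80)
        X = pd.DataFrame({
            "a": base + 0.6 * rng.standard_normal(80),
            "b": base + 0.6 * rng.standard_normal(80),
            "c": base + 0.6 * rng.standard_normal(80),
        })
        ours = vif(X)
        design = sm.add_constant(X.to_numpy())
        theirs = [variance_inflation_factor(design, i + 1) for i in range(3)]
        np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=1e-8)

    def test_always_at_least_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("abcd"))
        assert (vif(X) >= 1.0).all()


class TestScaledOLS:
    def test_identity_gives_unit_coefficient(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        res = scaled_ols(x, pd.DataFrame({"x": x}))
        assert res.params[1] == pytest.approx(1.0)

    def test_irrelevant_orthogonal_predictor_leaves_others(self):
        # zero-mean columns orthogonal to each other and to the intercept
        rng = np.random.default_rng(5)
        a = np.tile([1.0, -1.0], 30)
        b = np.tile([1.0, 1.0, -1.0, -1.0], 15)
        y = a + 0.1 * rng.standard_normal(60)
        r1 = scaled_ols(y, pd.DataFrame({"a": a}))
        r2 = scaled_ols(y, pd.DataFrame({"a": a, "b": b}))
        assert r1.params[1] == pytest.approx(r2.params[1], abs=1e-10)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(500):
            X = pd.DataFrame({"x": rng.standard_normal(25)})
            y = rng.standard_normal(25)
            ps.append(scaled_ols(y, X).pvalues[1])
        ps = np.asarray(ps)
        # Kolmogorov-Smirnov band for n=500 at alpha ~ 1e-3
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_rank_deficiency_names_columns(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="aliased"):
            scaled_ols(x, pd.DataFrame({"a": x, "b": 2 * x}))


class TestTreeCovariance:
    def test_hand_built_tree(self):
        # ((A:1,B:1):2,C:3); shared(A,B)=2, depth=3
        C = tree_covariance("((A:1,B:1):2,C:3);")
        assert C.loc["A", "A"] == pytest.approx(3.0)
        assert C.loc["A", "B"] == pytest.approx(2.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_missing_taxa_listed(self):
        with pytest.raises(ValueError, match="missing from tree"):
            tree_covariance("((A:1,B:1):2,C:3);", taxa=["A", "D"])

    def test_pagel_scaling_preserves_diagonal(self):
        C = tree_covariance("((A:1,B:1):2,C:3);").to_numpy()
        V = pagel_covariance(C, 0.25)
        np.testing.assert_allclose(np.diag(V), np.diag(C))
        assert V[0, 1] == pytest.approx(0.25 * C[0, 1])


class TestPGLS:
    def test_lambda_zero_reduces_to_scaled_ols(self):
        nwk, df = synthetic.simulate_tree_traits(40, 1.0, [1.0, -0.5], 1.0, seed=7)
        gls = pgls_pagel(df["y"], df[["x1", "x2"]], nwk, lambda_mode=0.0)
        ols = scaled_ols(df["y"], df[["x1", "x2"]])
        np.testing.assert_allclose(gls.params.to_numpy(), ols.params, atol=1e-8)

    def test_star_tree_equals_ols_for_any_lambda(self):
        n = 20
        nwk = "(" + ",".join(f"s{i + 1}:1.0" for i in range(n)) + ");"
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x1": rng.standard_normal(n)}, index=[f"s{i + 1}" for i in range(n)])
        y = df["x1"] + rng.standard_normal(n)
        ols = scaled_ols(y, df)
        for lam in (0.0, 0.5, 1.0):
            gls = pgls_pagel(y, df, nwk, lambda_mode=lam)
            np.testing.assert_allclose(gls.params.to_numpy(), ols.params, atol=1e-8)

    def test_loglik_peaks_at_estimate(self):
        nwk, df = synthetic.simulate_tree_traits(60, 0.7, [1.0], 1.0, seed=9)
        fit = pgls_pagel(df["y"], df[["x1"]], nwk, lambda_mode="ML")
        for lam in (0.0, 1.0):
            fixed = pgls_pagel(df["y"], df[["x1"]], nwk, lambda_mode=lam)
            assert fit.loglik >= fixed.loglik - 1e-6

    def test_lambda_recovery_moderate_scale(self):
        lams = [pgls_pagel(*_sim(seed), lambda_mode="ML").lam for seed in range(25)]
        assert np.mean(lams) > 0.8

    def test_ci_covers_zero_under_independence(self):
        hits = 0
        for seed in range(20):
            nwk, df = synthetic.simulate_tree_traits(40, 0.0, [1.0], 1.0, seed=100 + seed)
            fit = pgls_pagel(df["y"], df[["x1"]], nwk, lambda_mode="ML")
            hits += fit.lam_ci[0] <= 0.0 <= fit.lam_ci[1]
        assert hits >= 16  # nominal 95% coverage, small-sample slack

    def test_mismatched_tips_rejected(self):
        nwk, df = synthetic.simulate_tree_traits(12, 0.5, [1.0], 1.0, seed=10)
        bad = df.rename(index={"s1": "not_in_tree"})
        with pytest.raises(ValueError, match="missing"):
            pgls_pagel(bad["y"], bad[["x1"]], nwk)


def _sim(seed):
    nwk, df = synthetic.simulate_tree_traits(80, 1.0, [1.0], 1.0, seed=seed)
    return df["y"], df[["x1"]], nwk


class TestBackwardEliminationCV:
    def _table(self, seed, n=150, betas=(1.0, 1.0, 0.0, 0.0, 0.0), noise=1.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        y = X.to_numpy() @ np.array(betas) + noise * rng.standard_normal(n)
        return y, X

    def test_loo_matches_hand_rolled_loop(self):
        """reps=1, k=n on a 12-row table equals an explicit LOO loop."""
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((12, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + 0.3 * rng.standard_normal(12)
        ladder = backward_elimination_cv(y, X, k=12, reps=1, seed=0)
        full = ladder[ladder["size"] == 2].iloc[0]

        errs = []
        Xc = np.column_stack([np.ones(12), X.to_numpy()])
        for i in range(12):
            tr = [j for j in range(12) if j != i]
            beta, *_ = np.linalg.lstsq(Xc[tr], y[tr], rcond=None)
            errs.append(y[i] - Xc[i] @ beta)
        errs = np.asarray(errs)
        assert full["rmse"] == pytest.approx(np.sqrt(np.mean(errs**2)), abs=1e-12)
        assert full["mae"] == pytest.approx(np.mean(np.abs(errs)), abs=1e-12)
        assert full["r2"] == pytest.approx(1 - np.sum(errs**2) / np.sum((y - y.mean()) ** 2), abs=1e-12)

    def test_relevant_predictor_retained(self):
        y, X = self._table(12, betas=(2.0, 0.0, 0.0, 0.0, 0.0), noise=0.5)
        ladder = backward_elimination_cv(y, X, reps=5, seed=1)
        best = ladder[ladder["selected"]].iloc[0]
        assert best["a"]

    def test_pure_noise_flat_ladder(self):
        y, X = self._table(13, betas=(0, 0, 0, 0, 0), noise=1.0)
        ladder = backward_elimination_cv(y, X, reps=5, seed=2)
        spread = ladder["rmse"].max() - ladder["rmse"].min()
        assert spread < 0.15 * ladder["rmse"].mean()

    def test_bit_reproducible_under_seed(self):
        y, X = self._table(14)
        a = backward_elimination_cv(y, X, reps=3, seed=5)
        b = backward_elimination_cv(y, X, reps=3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_rows_rejected(self):
        y, X = self._table(15, n=20)
        with pytest.raises(ValueError, match="n >= 3k"):
            backward_elimination_cv(y, X, k=10)


def test_correlation_matrix_symmetric():
    rng = np.random.default_rng(16)
    df = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("xyz"))
    corr = correlation_matrix(df)
    np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
    np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)


def test_filter_extreme_drops_out_of_band_rows():
    s = pd.Series([0.5, 1e-4, 20.0, 2e3], index=list("abcd"))
    kept = filter_extreme(s)
    assert list(kept.index) == ["a", "c"]
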