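"""OLS, partial-F stepwise selection and NIPALS PLS against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hsp90qsar import (
    choose_pls_components,
    fit_ols,
    fit_pls_nipals,
    predict,
    stepwise_select,
)


class TestFitOLS:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        model = fit_ols(x[:, None], 2 * x + 1)
        assert model.intercept == pytest.approx(1.0, abs=1e-12)
        assert list(model.coefficients.values())[0] == pytest.approx(2.0, abs=1e-12)
        assert model.r2_c == pytest.approx(1.0)
        assert model.se == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_columns_rejected_naming_dependent(self, rng):
        x = rng.standard_normal(10)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="'b'"):
            fit_ols(X, rng.standard_normal(10))

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        model = fit_ols(X, y)
        # independent oracle: solve the normal equations directly
        A = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        np.testing.assert_allclose(list(model.coefficients.values()), beta[1:], atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        model = fit_ols(X, y)
        resid = y - predict(model, X)
        assert abs(resid.sum()) < 1e-8
        for j in range(4):
            assert abs(resid @ X[:, j]) < 1e-8

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="n > k"):
            fit_ols(rng.standard_normal((4, 3)), rng.standard_normal(4))


class TestPredict:
    def test_intercept_only(self):
        model = fit_ols(np.arange(5.0)[:, None], 2 * np.arange(5.0))
        model.coefficients = {}
        out = predict(model, pd.DataFrame(index=range(3)))
        assert np.allclose(out, model.intercept)

    def test_hand_built_model(self):
        from hsp90qsar import FittedLinearModel

        model = FittedLinearModel(1.0, {"a": 2.0}, 2, 1.0, 0.0, "OLS")
        out = predict(model, pd.DataFrame({"a": [0.0, 0.5]}))
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_missing_column_named(self):
        from hsp90qsar import FittedLinearModel

        model = FittedLinearModel(0.0, {"Mor26e": 1.0}, 2, 1.0, 0.0, "OLS")
        with pytest.raises(KeyError, match="Mor26e"):
            predict(model, pd.DataFrame({"X5A": [1.0]}))

    def test_training_predictions_reproduce_r2c(self, rng):
        X = rng.standard_normal((25, 3))
        y = X[:, 0] + 0.5 * rng.standard_normal(25)
        model = fit_ols(X, y)
        yhat = predict(model, X)
        r2 = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(model.r2_c, abs=1e-12)


class TestStepwise:
    def test_dominant_predictor_selected_first(self, rng):
        n = 40
        X = rng.standard_normal((n, 10))
        y = 3 + 2 * X[:, 0] + 0.05 * rng.standard_normal(n)
        # oracle: x1 has the largest single-variable F by brute force
        fs = []
        for j in range(10):
            m = fit_ols(X[:, [j]], y)
            rss0 = ((y - y.mean()) ** 2).sum()
            rss1 = (1 - m.r2_c) * rss0
            fs.append((rss0 - rss1) / (rss1 / (n - 2)))
        assert int(np.argmax(fs)) == 0
        model = stepwise_select(X, y)
        assert "x1" in model.coefficients

    def test_pure_noise_gives_intercept_only(self, rng):
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        model = stepwise_select(X, y, p_enter=1e-6, p_remove=1e-5)
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(y.mean())

    def test_enter_threshold_must_be_below_removal(self, rng):
        with pytest.raises(ValueError, match="p_enter"):
            stepwise_select(rng.standard_normal((20, 3)), rng.standard_normal(20),
                            p_enter=0.10, p_remove=0.05)

    def test_column_permutation_invariance(self, rng):
        X = rng.standard_normal((50, 8))
        y = 1 + X[:, 2] - 2 * X[:, 5] + 0.2 * rng.standard_normal(50)
        Xf = pd.DataFrame(X, columns=[f"v{j}" for j in range(8)])
        sel1 = stepwise_select(Xf, y)
        perm = [4, 2, 7, 0, 5, 1, 6, 3]
        sel2 = stepwise_select(Xf.iloc[:, perm], y)
        assert set(sel1.coefficients) == set(sel2.coefficients)
        for k in sel1.coefficients:
            assert sel1.coefficients[k] == pytest.approx(sel2.coefficients[k], rel=1e-10)

    def test_max_terms_respected(self, rng):
        X = rng.standard_normal((60, 20))
        beta = np.linspace(1, 2, 10)
        y = X[:, :10] @ beta + 0.1 * rng.standard_normal(60)
        model = stepwise_select(X, y, max_terms=4)
        assert len(model.coefficients) <= 4


class TestPLS:
    def test_single_column_equals_simple_ols(self, rng):
        x = rng.standard_normal(15)
        y = 2 * x + 1 + 0.1 * rng.standard_normal(15)
        ols = fit_ols(x[:, None], y)
        pls = fit_pls_nipals(x[:, None], y, n_components=1)
        np.testing.assert_allclose(predict(pls, x[:, None]), predict(ols, x[:, None]), atol=1e-10)

    def test_full_components_equal_ols(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        ols = fit_ols(X, y)
        pls = fit_pls_nipals(X, y, n_components=4)
        np.testing.assert_allclose(predict(pls, X), predict(ols, X), atol=1e-8)

    def test_matches_reference_pls_implementation(self, rng):
        """Cross-check against scikit-learn's PLSRegression (independent oracle)."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((30, 8))
        y = 2 * X[:, 0] - X[:, 3] + 0.3 * rng.standard_normal(30)
        for a in (1, 2, 3):
            mine = fit_pls_nipals(X, y, n_components=a)
            ref = sklearn.PLSRegression(n_components=a, scale=True).fit(X, y)
            np.testing.assert_allclose(
                predict(mine, X), ref.predict(X).ravel(), atol=1e-10
            )

    def test_training_r2_nondecreasing_in_components(self, rng):
        X = rng.standard_normal((25, 6))
        y = X @ rng.standard_normal(6) + rng.standard_normal(25)
        r2s = [fit_pls_nipals(X, y, n_components=a).r2_c for a in range(1, 7)]
        assert all(b >= a - 1e-10 for a, b in zip(r2s, r2s[1:]))

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pls_nipals(rng.standard_normal((10, 2)), np.ones(10), n_components=1)

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        with pytest.raises(ValueError, match="constant"):
            fit_pls_nipals(X, rng.standard_normal(10), n_components=1)

    def test_components_beyond_rank_rejected(self, rng):
        x = rng.standard_normal(10)
        X = np.column_stack([x, 2 * x])  # rank 1
        with pytest.raises(ValueError, match="rank"):
            fit_pls_nipals(X, rng.standard_normal(10), n_components=2)

    def test_component_choice_maximizes_loo_q2(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 0] - X[:, 1] + 0.5 * rng.standard_normal(30)
        best, q2 = choose_pls_components(X, y, max_components=5)
        assert best == int(np.argmax(q2)) + 1
        assert len(q2) == 5
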