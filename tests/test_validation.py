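"""Cross-validation statistics, external R²p and Y-randomization behaviour."""

import numpy as np
import pandas as pd
import pytest

from hsp90qsar import (
    fit_ols,
    fit_pls_nipals,
    predict,
    q2_cv,
    q2_external,
    r2_prediction,
    y_randomization,
)


def ols_proc(Xf, yv):
    return fit_ols(Xf, yv)


class TestQ2CV:
    def test_noiseless_line_is_perfect(self):
        x = np.arange(6.0)
        q2, rmse = q2_cv(ols_proc, x[:, None], 2 * x + 1)
        assert q2 == pytest.approx(1.0, abs=1e-12)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            q2_cv(ols_proc, np.arange(6.0)[:, None], np.ones(6))

    def test_loo_matches_brute_force_refit_oracle(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(30)
        q2, rmse = q2_cv(ols_proc, X, y)
        # independent oracle: explicit per-sample lstsq refits
        press = 0.0
        for i in range(30):
            mask = np.ones(30, dtype=bool)
            mask[i] = False
            A = np.column_stack([np.ones(29), X[mask]])
            beta, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
            pred = beta[0] + X[i] @ beta[1:]
            press += (y[i] - pred) ** 2
        tss = ((y - y.mean()) ** 2).sum()
        assert q2 == pytest.approx(1 - press / tss, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(press / 30), abs=1e-12)

    def test_loo_q2_below_calibration_r2(self, rng):
        X = rng.standard_normal((30, 4))
        y = X[:, 0] + rng.standard_normal(30)
        model = fit_ols(X, y)
        q2, _ = q2_cv(ols_proc, X, y)
        assert q2 <= model.r2_c

    def test_leave_three_out_seeded_and_reproducible(self, rng):
        X = rng.standard_normal((30, 3))
        y = X[:, 0] * 2 + 0.3 * rng.standard_normal(30)
        a = q2_cv(ols_proc, X, y, leave_out=3, n_rounds=4, seed=9)
        b = q2_cv(ols_proc, X, y, leave_out=3, n_rounds=4, seed=9)
        assert a == b
        # triplet CV approximates LOO on a stable problem
        loo = q2_cv(ols_proc, X, y)[0]
        assert a[0] == pytest.approx(loo, abs=0.1)

    def test_refit_failure_names_fold(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(8)}, index=[f"c{i}" for i in range(8)])
        y = np.arange(8.0)

        def failing(Xf, yv):
            if "c3" not in Xf.index:
                raise ValueError("boom")
            return fit_ols(Xf, yv)

        with pytest.raises(RuntimeError, match="c3"):
            q2_cv(failing, X, y)


class TestR2Prediction:
    def test_perfect_predictions(self, rng):
        X = rng.standard_normal((5, 2))
        y = X @ np.array([1.0, 2.0]) + 3
        model = fit_ols(X, y)
        assert r2_prediction(model, X, y) == pytest.approx(1.0)

    def test_offset_invariance_documents_convention_weakness(self, rng):
        X = rng.standard_normal((10, 2))
        y = X @ np.array([1.0, 2.0]) + 3
        model = fit_ols(X, y)
        assert r2_prediction(model, X, y + 5.0) == pytest.approx(1.0)
        # the external-Q2 convention is not fooled by the same offset
        assert q2_external(model, X, y + 5.0, y.mean()) < 0.5

    def test_matches_direct_formula_oracle(self, rng):
        X = rng.standard_normal((12, 3))
        y = X[:, 0] + 0.5 * rng.standard_normal(12)
        model = fit_ols(X, y)
        Xv = rng.standard_normal((6, 3))
        yv = Xv[:, 0] + 0.5 * rng.standard_normal(6)
        pred = predict(model, Xv)
        num = ((yv - yv.mean()) * (pred - pred.mean())).sum()
        den = np.sqrt(((yv - yv.mean()) ** 2).sum() * ((pred - pred.mean()) ** 2).sum())
        assert r2_prediction(model, Xv, yv) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_constant_inputs_rejected(self, rng):
        X = rng.standard_normal((5, 1))
        model = fit_ols(X, X[:, 0] * 2)
        with pytest.raises(ValueError, match="constant observations"):
            r2_prediction(model, X, np.ones(5))
        zero = type(model)(1.0, {"x1": 0.0}, 5, 1.0, 0.0, "OLS")
        with pytest.raises(ValueError, match="constant predictions"):
            r2_prediction(zero, X, X[:, 0])


class TestYRandomization:
    def test_permutation_preserves_multiset_and_determinism(self, rng):
        X = rng.standard_normal((20, 2))
        y = X[:, 0] + 0.2 * rng.standard_normal(20)
        a = y_randomization(ols_proc, X, y, n_iter=5, seed=3)
        b = y_randomization(ols_proc, X, y, n_iter=5, seed=3)
        assert a.iterations == b.iterations
        # the permuted-activity multiset is checked inside via refits succeeding;
        # verify directly on the generator stream
        perm = np.random.default_rng(3).permutation(y)
        assert sorted(perm) == pytest.approx(sorted(y))

    def test_signal_model_beats_all_permutations(self, rng):
        X = rng.standard_normal((40, 4))
        y = X @ np.array([2.0, -1.5, 1.0, 0.5]) + rng.standard_normal(40)
        res = y_randomization(ols_proc, X, y, n_iter=10, seed=1)
        assert res.max_permuted_r2() < res.original[0]
        assert res.max_permuted_q2() < res.original[1]

    def test_null_calibrated_on_pure_noise(self):
        """On pure noise the original R² is just another draw from the permutation
        null: averaged over datasets, original and permuted R² agree."""
        orig, perm = [], []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 4))
            y = rng.standard_normal(30)
            res = y_randomization(ols_proc, X, y, n_iter=10, seed=seed, compute_q2=False)
            orig.append(res.original[0])
            perm.extend(r2 for r2, _ in res.iterations)
        assert np.mean(orig) == pytest.approx(np.mean(perm), abs=0.05)
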