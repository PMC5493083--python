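"""Cross-validation statistics, external prediction R², and the Y-randomization null.

Conventions (the QSAR standards used throughout):

* Q² = 1 − PRESS / Σ(y − ȳ)², with ȳ the mean of the **full** calibration
  set, not per-fold means; RMSE_CV = sqrt(PRESS / n).
* R²p is the squared product-moment correlation between observed and
  predicted validation activities.  Being shift- and scale-invariant it can
  exceed the calibration R²; the stricter external Q²F1 (PRESS about the
  calibration mean) is available via :func:`q2_external`.
* Y-randomization permutes the activity vector, refits, and records R² and
  Q²LOO; a model whose statistics are matched by the permuted ones is
  explaining chance correlation.

A "fit procedure" is any callable ``(X: DataFrame, y: array) -> FittedLinearModel``
— e.g. a fixed-subset OLS refit, the full stepwise selector, or a PLS fit —
so the same machinery validates every model family, with or without
re-selection inside the resampling loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .linear_models import FittedLinearModel, predict

__all__ = [
    "FitProcedure",
    "ValidationReport",
    "YRandomizationResult",
    "q2_cv",
    "r2_prediction",
    "q2_external",
    "y_randomization",
    "validation_report",
]

FitProcedure = Callable[[pd.DataFrame, np.ndarray], FittedLinearModel]


@dataclass
class ValidationReport:
    """Calibration and cross-validation statistics for one model."""

    method: str
    r2_c: float
    se: float
    q2: float
    rmse_cv: float
    r2_p: float | None
    leave_out: int
    n_cal: int
    n_val: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "r2_c": round(self.r2_c, 3),
            "se": round(self.se, 3),
            "q2": round(self.q2, 3),
            "rmse_cv": round(self.rmse_cv, 3),
            "r2_p": None if self.r2_p is None else round(self.r2_p, 3),
            "leave_out": self.leave_out,
            "n_cal": self.n_cal,
            "n_val": self.n_val,
        }


@dataclass
class YRandomizationResult:
    """R²/Q² of models refit on permuted activities, with the original for contrast."""

    iterations: list[tuple[float, float]]  # (r2, q2) per permutation
    original: tuple[float, float]
    seed: int

    def max_permuted_r2(self) -> float:
        return max(r2 for r2, _ in self.iterations)

    def max_permuted_q2(self) -> float:
        return max(q2 for _, q2 in self.iterations)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.iterations, columns=["r2", "q2"])
        frame.index = pd.RangeIndex(1, len(self.iterations) + 1, name="iteration")
        return frame


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])


def q2_cv(
    fit_procedure: FitProcedure,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    leave_out: int = 1,
    n_rounds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Leave-*leave_out*-out cross-validated (Q², RMSE_CV).

    ``leave_out=1`` is deterministic: each compound is predicted by a model
    refit without it.  ``leave_out>1`` randomly partitions the compounds into
    disjoint groups of that size (a smaller final group if n is not
    divisible), repeats the partition *n_rounds* times, and averages the
    statistics; the partition stream is seeded.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if y.std() == 0:
        raise ValueError("zero-variance response: Q² undefined")
    if leave_out < 1 or leave_out >= n:
        raise ValueError(f"leave_out must be in [1, {n - 1}]")
    tss = float(((y - y.mean()) ** 2).sum())

    def one_pass(groups: list[np.ndarray]) -> float:
        press = 0.0
        for g in groups:
            mask = np.ones(n, dtype=bool)
            mask[g] = False
            try:
                model = fit_procedure(Xf.iloc[mask], y[mask])
            except Exception as exc:
                held = list(Xf.index[g])
                raise RuntimeError(f"refit failed for fold holding out {held}: {exc}") from exc
            pred = predict(model, Xf.iloc[g])
            press += float(((y[g] - pred) ** 2).sum())
        return press

    if leave_out == 1:
        press = one_pass([np.array([i]) for i in range(n)])
        return 1 - press / tss, float(np.sqrt(press / n))

    rng = np.random.default_rng(seed)
    q2s, rmses = [], []
    for _ in range(n_rounds):
        perm = rng.permutation(n)
        groups = [perm[i : i + leave_out] for i in range(0, n, leave_out)]
        press = one_pass(groups)
        q2s.append(1 - press / tss)
        rmses.append(np.sqrt(press / n))
    return float(np.mean(q2s)), float(np.mean(rmses))


def r2_prediction(
    model: FittedLinearModel, X_val: pd.DataFrame | np.ndarray, y_val: np.ndarray
) -> float:
    """Squared correlation between observed and predicted validation activities (R²p).

    Note the known weakness of this convention: it is invariant to a constant
    offset or rescaling of the predictions (a systematically biased model can
    still score 1.0).  See :func:`q2_external` for the stricter alternative.
    """
    y_val = np.asarray(y_val, dtype=float)
    if len(y_val) < 3:
        raise ValueError("need at least 3 validation compounds")
    pred = predict(model, _as_frame(X_val))
    if np.std(pred) == 0:
        raise ValueError("constant predictions: R²p undefined")
    if np.std(y_val) == 0:
        raise ValueError("constant observations: R²p undefined")
    r = float(np.corrcoef(y_val, pred)[0, 1])
    return r * r


def q2_external(
    model: FittedLinearModel,
    X_val: pd.DataFrame | np.ndarray,
    y_val: np.ndarray,
    y_cal_mean: float,
) -> float:
    """External Q²F1 = 1 − Σ(y − ŷ)² / Σ(y − ȳ_cal)² over the validation set."""
    y_val = np.asarray(y_val, dtype=float)
    pred = predict(model, _as_frame(X_val))
    denom = float(((y_val - y_cal_mean) ** 2).sum())
    if denom == 0:
        raise ValueError("validation activities identical to the calibration mean")
    return 1 - float(((y_val - pred) ** 2).sum()) / denom


def y_randomization(
    fit_procedure: FitProcedure,
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_iter: int = 10,
    seed: int = 0,
    compute_q2: bool = True,
) -> YRandomizationResult:
    """Refit on permuted activity vectors to probe for chance correlation.

    Each iteration permutes y uniformly (seeded) and runs *fit_procedure* on
    the unchanged descriptor matrix; R²c and (optionally) Q²LOO of the
    permuted refits are recorded alongside the original model's values.
    Whether descriptors are re-selected per permutation is decided by the
    supplied procedure: pass a fixed-subset refit for the conventional test
    or the full selector for the stricter re-selection variant.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    def stats_for(yv: np.ndarray) -> tuple[float, float]:
        model = fit_procedure(Xf, yv)
        q2 = q2_cv(fit_procedure, Xf, yv, leave_out=1)[0] if compute_q2 else float("nan")
        return model.r2_c, q2

    original = stats_for(y)
    iterations = [stats_for(rng.permutation(y)) for _ in range(n_iter)]
    return YRandomizationResult(iterations=iterations, original=original, seed=seed)


def validation_report(
    fit_procedure: FitProcedure,
    X_cal: pd.DataFrame | np.ndarray,
    y_cal: np.ndarray,
    X_val: pd.DataFrame | np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    leave_out: int = 1,
    n_rounds: int = 10,
    seed: int = 0,
) -> tuple[FittedLinearModel, ValidationReport]:
    """Fit on the calibration set and assemble the full statistics panel."""
    Xf = _as_frame(X_cal)
    y_cal = np.asarray(y_cal, dtype=float)
    model = fit_procedure(Xf, y_cal)
    q2, rmse = q2_cv(fit_procedure, Xf, y_cal, leave_out=leave_out, n_rounds=n_rounds, seed=seed)
    r2p = None
    if X_val is not None and y_val is not None and len(y_val) >= 3:
        r2p = r2_prediction(model, X_val, np.asarray(y_val, dtype=float))
    report = ValidationReport(
        method=model.method,
        r2_c=model.r2_c,
        se=model.se,
        q2=q2,
        rmse_cv=rmse,
        r2_p=r2p,
        leave_out=leave_out,
        n_cal=len(y_cal),
        n_val=0 if y_val is None else len(y_val),
    )
    return model, report
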