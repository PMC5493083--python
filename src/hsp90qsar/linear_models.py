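"""Ordinary least squares, partial-F stepwise descriptor selection, and NIPALS PLS.

These are the regression engines behind the QSAR pipeline.  OLS and stepwise
regression operate on raw descriptor values with an explicit intercept, so
fitted coefficients are in original descriptor units (comparable to published
equation coefficients).  PLS autoscales internally (centering and unit
variance, standard chemometrics practice) but the returned model is expressed
back in original units.

Stepwise selection is the classic forward-entry / backward-removal procedure
on partial-F p-values, with SPSS's default thresholds (enter at p < 0.05,
remove at p > 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FittedLinearModel",
    "fit_ols",
    "stepwise_select",
    "fit_pls_nipals",
    "choose_pls_components",
    "predict",
]


@dataclass
class FittedLinearModel:
    """A fitted linear predictor: intercept plus named coefficients.

    ``r2_c`` is the squared correlation of the calibration fit (R²c) and
    ``se`` the standard error of regression, sqrt(RSS / (n − k − 1)).
    For PLS models ``k`` in the ``se`` formula is the number of latent
    components, the effective dimensionality of the fit.
    """

    intercept: float
    coefficients: dict[str, float]
    n_train: int
    r2_c: float
    se: float
    method: str  # "OLS", "STEPWISE_MLR" or "PLS"
    n_components: int | None = None

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r2_c <= 1 + 1e-9:
            raise ValueError(f"r2_c out of [0, 1]: {self.r2_c}")
        if self.se < 0:
            raise ValueError("se must be >= 0")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "n_train": self.n_train,
            "r2_c": self.r2_c,
            "se": self.se,
            "n_components": self.n_components,
        }


def _as_matrix(X: pd.DataFrame | np.ndarray, names: Sequence[str] | None = None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    return X, list(names)


def _first_dependent_column(X: np.ndarray, names: list[str]) -> str:
    """Name the first column that is linearly dependent on the intercept and
    the columns before it."""
    n = X.shape[0]
    design = np.ones((n, 1))
    for j, name in enumerate(names):
        cand = np.column_stack([design, X[:, j]])
        if np.linalg.matrix_rank(cand) <= design.shape[1]:
            return name
        design = cand
    return names[-1]


def _ols_rss(Xsub: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least-squares fit with intercept; returns (beta incl. intercept, RSS, rank)."""
    design = np.column_stack([np.ones(len(y)), Xsub])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid), int(rank)


def fit_ols(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
) -> FittedLinearModel:
    """Ordinary least squares with intercept on raw descriptor values.

    Requires more rows than coefficients (n > k + 1) and a full-column-rank
    design; a rank-deficient design raises ``ValueError`` naming the first
    dependent column.
    """
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, k = Xm.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 rows, got n={n}, k={k}")
    beta, rss, rank = _ols_rss(Xm, y)
    if rank < k + 1:
        raise ValueError(
            f"design matrix is rank deficient; column {_first_dependent_column(Xm, names)!r} "
            "is linearly dependent on earlier columns"
        )
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    se = float(np.sqrt(rss / (n - k - 1)))
    return FittedLinearModel(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        n_train=n,
        r2_c=min(max(r2, 0.0), 1.0),
        se=se,
        method="OLS",
    )


def predict(model: FittedLinearModel, X: pd.DataFrame | Mapping[str, float] | np.ndarray) -> np.ndarray:
    """Evaluate ``intercept + Σ coefficient × descriptor`` on new compounds.

    *X* may be a DataFrame (columns looked up by coefficient name), a mapping
    of descriptor name → value for a single compound, or a bare array whose
    columns are already in coefficient order.
    """
    names = model.descriptor_names
    if isinstance(X, Mapping):
        missing = [d for d in names if d not in X]
        if missing:
            raise KeyError(f"missing descriptor column(s): {missing}")
        vals = np.array([[float(X[d]) for d in names]])
    elif isinstance(X, pd.DataFrame):
        missing = [d for d in names if d not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor column(s): {missing}")
        vals = X[names].to_numpy(dtype=float) if names else np.empty((len(X), 0))
    else:
        vals = np.asarray(X, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.shape[1] != len(names):
            raise ValueError(
                f"expected {len(names)} descriptor columns, got {vals.shape[1]}"
            )
    coef = np.array([model.coefficients[d] for d in names])
    out = model.intercept + (vals @ coef if len(names) else np.zeros(len(vals)))
    return np.atleast_1d(out)


def stepwise_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_terms: int = 7,
    names: Sequence[str] | None = None,
) -> FittedLinearModel:
    """Forward-entry / backward-removal stepwise MLR on partial-F p-values.

    At each iteration the excluded descriptor with the smallest partial-F
    p-value enters if p < *p_enter* (ties broken by column order); then any
    included descriptor whose partial-F p-value exceeds *p_remove* is removed
    (largest p first).  Stops when a full pass changes nothing or the model
    reaches *max_terms* descriptors.  Deterministic given X and y.
    """
    if p_enter >= p_remove:
        raise ValueError("p_enter must be < p_remove (oscillation risk)")
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if max_terms >= n - 2:
        raise ValueError("max_terms must be < n - 2")

    rss_cache: dict[frozenset[int], float] = {}

    def rss_of(subset: tuple[int, ...]) -> tuple[float, int]:
        key = frozenset(subset)
        if key in rss_cache:
            return rss_cache[key], len(subset) + 1  # rank assumed ok when cached
        _, rss, rank = _ols_rss(Xm[:, list(subset)], y) if subset else (
            None,
            float(((y - y.mean()) ** 2).sum()),
            1,
        )
        rss_cache[key] = rss
        return rss, rank

    included: list[int] = []
    while True:
        changed = False
        # forward entry
        if len(included) < max_terms:
            rss_base, _ = rss_of(tuple(included))
            best_j, best_p = None, p_enter
            for j in range(p):
                if j in included:
                    continue
                cand = tuple(included) + (j,)
                if len(cand) + 1 >= n:
                    continue
                rss_full, rank = rss_of(cand)
                if rank < len(cand) + 1:
                    continue  # candidate collinear with current model
                df = n - len(cand) - 1
                if rss_full <= 0:
                    pval = 0.0
                else:
                    F = (rss_base - rss_full) / (rss_full / df)
                    pval = float(stats.f.sf(max(F, 0.0), 1, df))
                if pval < best_p:
                    best_j, best_p = j, pval
            if best_j is not None:
                included.append(best_j)
                changed = True
        # backward removal
        while len(included) > 1:
            rss_full, _ = rss_of(tuple(included))
            df = n - len(included) - 1
            worst_j, worst_p = None, p_remove
            for j in included:
                reduced = tuple(i for i in included if i != j)
                rss_red, _ = rss_of(reduced)
                if rss_full <= 0:
                    pval = 0.0
                else:
                    F = (rss_red - rss_full) / (rss_full / df)
                    pval = float(stats.f.sf(max(F, 0.0), 1, df))
                if pval > worst_p:
                    worst_j, worst_p = j, pval
            if worst_j is None:
                break
            included.remove(worst_j)
            changed = True
        if not changed:
            break

    if not included:
        ybar = float(y.mean())
        tss = float(((y - ybar) ** 2).sum())
        se = float(np.sqrt(tss / (n - 1))) if n > 1 else 0.0
        model = FittedLinearModel(
            intercept=ybar, coefficients={}, n_train=n, r2_c=0.0, se=se, method="STEPWISE_MLR"
        )
        return model
    model = fit_ols(Xm[:, included], y, names=[names[j] for j in included])
    model.method = "STEPWISE_MLR"
    return model


def _nipals_path(
    Xs: np.ndarray,
    yc: np.ndarray,
    n_components: int,
    tol: float,
    max_iter: int,
    allow_truncation: bool = False,
) -> np.ndarray:
    """NIPALS on autoscaled X / centered y; returns the (p × A) matrix whose
    column a-1 holds the cumulative scaled-space coefficient vector using the
    first a latent components.

    With a single response the NIPALS inner iteration (the y-score u equals y
    throughout) converges after its first weight update, so each component is
    extracted in closed form; *max_iter* must still permit at least one
    update and *tol* is the breakdown threshold on the weight norm.

    ``allow_truncation=True`` turns an extraction breakdown (X fully deflated:
    the requested count exceeds the effective rank) into a shorter path
    instead of an error — used by cross-validation folds, where callers cap
    the component count themselves.

    The cumulative coefficient vectors B_a = W_a (P_aᵀW_a)⁻¹ q_a are built
    incrementally via the modified weights W* = W (PᵀW)⁻¹ (PᵀW is unit upper
    triangular), avoiding a linear solve per component.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    Xa = Xs.copy()
    ya = yc.copy()
    p = Xs.shape[1]
    P = np.zeros((p, n_components))
    Wstar = np.zeros((p, n_components))
    B = np.zeros((p, n_components))
    b = np.zeros(p)
    n_extracted = n_components
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm <= tol:
            if allow_truncation and a > 0:
                n_extracted = a
                break
            raise ValueError(
                f"NIPALS breakdown: deflated X has no covariance with y at component {a + 1}"
            )
        w /= norm
        t = Xa @ w
        tt = t @ t
        if tt == 0:
            if allow_truncation and a > 0:
                n_extracted = a
                break
            raise ValueError(f"NIPALS breakdown: zero score vector at component {a + 1}")
        p_a = Xa.T @ t / tt
        q_a = (ya @ t) / tt
        # modified weight: w*_a = w_a − Σ_{j<a} (p_jᵀw_a) w*_j
        ws = w - Wstar[:, :a] @ (P[:, :a].T @ w) if a else w
        P[:, a] = p_a
        Wstar[:, a] = ws
        b = b + q_a * ws
        B[:, a] = b
        Xa = Xa - t[:, None] * p_a
        ya = ya - q_a * t
    for a in range(n_extracted, n_components):  # truncated path: deepest model reused
        B[:, a] = B[:, n_extracted - 1]
    return B


def fit_pls_nipals(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
    names: Sequence[str] | None = None,
) -> FittedLinearModel:
    """Partial least squares by NIPALS, returned in original descriptor units.

    Columns are autoscaled (centered, unit variance) internally; constant
    columns are rejected.  When *n_components* is omitted it is chosen to
    maximize leave-one-out Q², capped at min(6, rank of the training matrix)
    (see :func:`choose_pls_components`).
    """
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if y.std() == 0:
        raise ValueError("zero-variance response: PLS undefined")
    sx = Xm.std(axis=0, ddof=1)
    if np.any(sx == 0):
        bad = names[int(np.argmax(sx == 0))]
        raise ValueError(f"constant descriptor column {bad!r}: autoscaling undefined")
    mx = Xm.mean(axis=0)
    Xs = (Xm - mx) / sx
    rank = int(np.linalg.matrix_rank(Xs))
    if n_components is None:
        n_components, _ = choose_pls_components(Xm, y, max_components=min(6, rank), names=names)
    if not 1 <= n_components <= rank:
        raise ValueError(f"n_components must be in [1, rank={rank}], got {n_components}")
    my = y.mean()
    B = _nipals_path(Xs, y - my, n_components, tol, max_iter)
    b_scaled = B[:, -1]
    b = b_scaled / sx
    intercept = float(my - mx @ b)
    yhat = intercept + Xm @ b
    rss = float(((y - yhat) ** 2).sum())
    tss = float(((y - my) ** 2).sum())
    df = n - n_components - 1
    se = float(np.sqrt(rss / df)) if df > 0 else 0.0
    return FittedLinearModel(
        intercept=intercept,
        coefficients={nm: float(v) for nm, v in zip(names, b)},
        n_train=n,
        r2_c=min(max(1 - rss / tss, 0.0), 1.0),
        se=se,
        method="PLS",
        n_components=n_components,
    )


def _pls_cv_press_per_component(
    Xm: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    max_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> np.ndarray:
    """Cross-validated PRESS for every component count 1..max_components.

    One NIPALS run per fold yields predictions at every component count
    simultaneously (the coefficient path is cumulative), so model-size
    selection costs no more than a single CV pass.  Columns constant within
    a training fold carry no information there and are dropped for that fold;
    if a fold supports fewer components than requested its deepest model is
    reused for the missing counts.
    """
    n = Xm.shape[0]
    press = np.zeros(max_components)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, ytr = Xm[mask], y[mask]
        sx = Xtr.std(axis=0, ddof=1)
        keep = sx > 0
        mx = Xtr.mean(axis=0)
        Xs = (Xtr[:, keep] - mx[keep]) / sx[keep]
        a_max = max(1, min(max_components, int(keep.sum()), len(ytr) - 1))
        my = ytr.mean()
        B = _nipals_path(Xs, ytr - my, a_max, tol, max_iter, allow_truncation=True)
        Xq = (Xm[np.ix_(fold, keep)] - mx[keep]) / sx[keep]
        preds = my + Xq @ B  # (len(fold), a_max)
        full = np.column_stack(
            [preds] + [preds[:, -1]] * (max_components - a_max)
        )
        press += ((y[fold][:, None] - full) ** 2).sum(axis=0)
    return press


def _pls_loo_press_per_component(
    Xm: np.ndarray, y: np.ndarray, max_components: int, tol: float = 1e-10, max_iter: int = 500
) -> np.ndarray:
    """Leave-one-out PRESS for every component count 1..max_components."""
    folds = [np.array([i]) for i in range(Xm.shape[0])]
    return _pls_cv_press_per_component(Xm, y, folds, max_components, tol, max_iter)


def choose_pls_components(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_components: int = 6,
    names: Sequence[str] | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the PLS component count maximizing leave-one-out Q².

    Returns ``(best_count, q2_per_count)`` where ``q2_per_count[a-1]`` is the
    LOO Q² with *a* components.  Ties go to the smaller model.
    """
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    rank = int(np.linalg.matrix_rank(Xm - Xm.mean(axis=0)))
    a_max = max(1, min(max_components, rank))
    press = _pls_loo_press_per_component(Xm, y, a_max)
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1 - press / tss
    best = int(np.argmax(q2)) + 1
    return best, q2
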