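"""Leverage-based applicability domain: hat values, warning leverage, William's plot.

A prediction is trusted only for compounds inside the model's applicability
domain.  The leverage h of a compound is the corresponding diagonal element
of the hat matrix H = X(XᵀX)⁻¹Xᵀ of the intercept-augmented calibration
design: it measures how far the compound's descriptors lie from the
calibration centroid.  Compounds with h above the warning leverage
h* = 3(k+1)/n are structural outliers (extrapolation); compounds whose
standardized cross-model residual exceeds the residual limit (±2.5 SD for
MLR-type models, ±3.0 SD for PLS-type models here) are response outliers.
Plotting standardized residual against leverage is the William's plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linear_models import FittedLinearModel, predict

__all__ = ["DomainAssessment", "leverages", "warning_leverage", "williams_table"]


@dataclass
class DomainAssessment:
    """Per-compound leverage/residual table plus the global thresholds."""

    table: pd.DataFrame  # columns: role, leverage, std_residual, response_outlier, structural_outlier
    h_star: float
    residual_limit: float

    def outliers(self) -> pd.DataFrame:
        mask = self.table["response_outlier"] | self.table["structural_outlier"]
        return self.table[mask]


def leverages(
    X_train: pd.DataFrame | np.ndarray, X_query: pd.DataFrame | np.ndarray | None = None
) -> np.ndarray:
    """Leverage h_q = x_q (XᵀX)⁻¹ x_qᵀ with intercept-augmented row vectors.

    With ``X_query=None`` the self-leverages (hat-matrix diagonal) of the
    training design are returned.  Requires the augmented training design to
    have full column rank.
    """
    Xt = np.asarray(X_train, dtype=float)
    if Xt.ndim == 1:
        Xt = Xt[:, None]
    n, k = Xt.shape
    A = np.column_stack([np.ones(n), Xt])
    if np.linalg.matrix_rank(A) < k + 1:
        raise ValueError("training design (with intercept) is rank deficient")
    Xq = Xt if X_query is None else np.asarray(X_query, dtype=float)
    if Xq.ndim == 1:
        Xq = Xq[:, None]
    Aq = np.column_stack([np.ones(len(Xq)), Xq])
    # h = diag(Aq (AᵀA)⁻¹ Aqᵀ) via a solve, no explicit inverse
    G = A.T @ A
    return np.einsum("ij,ji->i", Aq, np.linalg.solve(G, Aq.T))


def warning_leverage(k: int, n: int) -> float:
    """Warning leverage h* = 3(k + 1)/n for k model descriptors and n compounds."""
    if k < 0 or n <= 0:
        raise ValueError("need k >= 0 and n > 0")
    return 3 * (k + 1) / n


def williams_table(
    model: FittedLinearModel,
    X_cal: pd.DataFrame,
    y_cal: np.ndarray,
    X_val: pd.DataFrame | None = None,
    y_val: np.ndarray | None = None,
    residual_limit: float = 2.5,
    h_star_basis: str = "total",
    sd_mode: str = "population",
) -> DomainAssessment:
    """Assemble the William's-plot table and outlier flags for a fitted model.

    Standardized residual = raw residual / s, where s is the standard
    deviation of the calibration residuals — population form (divisor n) by
    default, or the regression form sqrt(RSS/(n−k−1)) with
    ``sd_mode="residual_df"``.  ``h_star_basis`` selects the n in
    h* = 3(k+1)/n: ``"total"`` (calibration + validation, the convention
    matching the published threshold of 0.42 for k=6, n=50) or
    ``"calibration"``.
    """
    if h_star_basis not in {"total", "calibration"}:
        raise ValueError("h_star_basis must be 'total' or 'calibration'")
    if sd_mode not in {"population", "residual_df"}:
        raise ValueError("sd_mode must be 'population' or 'residual_df'")
    names = model.descriptor_names
    Xc = X_cal[names]
    y_cal = np.asarray(y_cal, dtype=float)
    resid_cal = y_cal - predict(model, Xc)
    n_cal, k = len(y_cal), len(names)
    if sd_mode == "population":
        s = float(np.sqrt((resid_cal**2).mean()))
    else:
        df = n_cal - k - 1
        s = float(np.sqrt((resid_cal**2).sum() / df)) if df > 0 else 0.0
    if s == 0:
        raise ValueError("zero residual variance: standardized residuals undefined")

    rows = [(str(i), "calibration", r) for i, r in zip(Xc.index, resid_cal)]
    h_all = [leverages(Xc)]
    n_total = n_cal
    if X_val is not None:
        Xv = X_val[names]
        y_val = np.asarray(y_val, dtype=float)
        resid_val = y_val - predict(model, Xv)
        rows += [(str(i), "validation", r) for i, r in zip(Xv.index, resid_val)]
        h_all.append(leverages(Xc, Xv))
        n_total += len(Xv)

    h = np.concatenate(h_all)
    n_star = n_total if h_star_basis == "total" else n_cal
    h_star = warning_leverage(k, n_star)
    std_resid = np.array([r for _, _, r in rows]) / s
    table = pd.DataFrame(
        {
            "role": [role for _, role, _ in rows],
            "leverage": h,
            "std_residual": std_resid,
            "response_outlier": np.abs(std_resid) > residual_limit,
            "structural_outlier": h > h_star,
        },
        index=pd.Index([cid for cid, _, _ in rows], name="compound_id"),
    )
    return DomainAssessment(table=table, h_star=h_star, residual_limit=residual_limit)


def plot_williams(assessment: DomainAssessment, ax=None):
    """Convenience William's plot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for role, marker in (("calibration", "o"), ("validation", "s")):
        sub = assessment.table[assessment.table["role"] == role]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=role)
    ax.axvline(assessment.h_star, linestyle="--", color="k")
    ax.axhline(assessment.residual_limit, linestyle=":", color="r")
    ax.axhline(-assessment.residual_limit, linestyle=":", color="r")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    return ax
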