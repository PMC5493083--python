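"""Descriptor-matrix reduction: constant/near-constant removal and collinearity pruning.

Raw descriptor matrices (DRAGON-style, a thousand-plus columns for a few dozen
compounds) carry many uninformative columns: descriptors that are constant or
nearly constant across the series, and blocks of mutually collinear
descriptors that destabilize regression.  The reduction here mirrors standard
QSAR practice: first drop invariant columns, then greedily break up collinear
pairs (|r| above a threshold, 0.9 by default), keeping from each pair the
member more correlated with the activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import QSARDataset

__all__ = ["PreprocessReport", "drop_invariant", "prune_collinear", "preprocess"]


@dataclass
class PreprocessReport:
    """What was removed and why."""

    dropped_constant: list[str] = field(default_factory=list)
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)  # (kept, dropped, |r|)
    n_remaining: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("constant", "", name, np.nan) for name in self.dropped_constant]
        rows += [("collinear", kept, dropped, r) for kept, dropped, r in self.dropped_collinear]
        return pd.DataFrame(rows, columns=["reason", "kept", "dropped", "abs_r"])


def _round_sig(x: np.ndarray, sig: int = 6) -> np.ndarray:
    """Round to `sig` significant figures (0 stays 0)."""
    out = x.copy()
    nz = x != 0
    mag = np.floor(np.log10(np.abs(x[nz])))
    factor = 10.0 ** (sig - 1 - mag)
    out[nz] = np.round(x[nz] * factor) / factor
    return out


def drop_invariant(
    dataset: QSARDataset,
    dominant_fraction: float = 0.95,
    variance_floor: float = 1e-8,
) -> tuple[QSARDataset, PreprocessReport]:
    """Remove constant and near-constant descriptor columns.

    A column is dropped when its most frequent value (values compared after
    rounding to 6 significant figures) occupies more than *dominant_fraction*
    of the rows, or when its variance is below *variance_floor*.
    """
    if not 0 < dominant_fraction <= 1:
        raise ValueError("dominant_fraction must be in (0, 1]")
    if variance_floor < 0:
        raise ValueError("variance_floor must be >= 0")
    n = dataset.n_compounds
    dropped: list[str] = []
    keep_idx: list[int] = []
    for j, name in enumerate(dataset.descriptor_names):
        col = dataset.values[:, j]
        rounded = _round_sig(col)
        _, counts = np.unique(rounded, return_counts=True)
        dominant = counts.max() / n
        if dominant > dominant_fraction or col.var() < variance_floor:
            dropped.append(name)
        else:
            keep_idx.append(j)
    if not keep_idx:
        raise ValueError("all descriptor columns removed as invariant; empty matrix")
    reduced = QSARDataset(
        list(dataset.compound_ids),
        [dataset.descriptor_names[j] for j in keep_idx],
        dataset.values[:, keep_idx],
        dataset.activities.copy(),
    )
    return reduced, PreprocessReport(dropped_constant=dropped, n_remaining=len(keep_idx))


def prune_collinear(
    dataset: QSARDataset,
    threshold: float = 0.9,
    activities: np.ndarray | None = None,
) -> tuple[QSARDataset, PreprocessReport]:
    """Greedily eliminate collinear descriptor pairs, keeping the activity-correlated member.

    While any pair of surviving columns has |Pearson r| > *threshold*, the pair
    with the largest |r| is resolved (ties broken by column order) by dropping
    the member whose |correlation with the activity| is smaller (ties: the
    later column is dropped).  The output matrix has max pairwise |r| ≤
    threshold.  Columns should be non-constant (run :func:`drop_invariant`
    first); a zero-variance column yields undefined correlations and is
    treated as uncorrelated.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    y = dataset.activities if activities is None else np.asarray(activities, dtype=float)
    if y.shape[0] != dataset.n_compounds:
        raise ValueError("activities not aligned with dataset rows")
    p = dataset.n_descriptors
    if p < 2:
        return dataset, PreprocessReport(n_remaining=p)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(dataset.values, rowvar=False)
        y_corr = np.array(
            [_safe_corr(dataset.values[:, j], y) for j in range(p)]
        )
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    corr = np.maximum(corr, corr.T)  # enforce exact symmetry (corrcoef is not bitwise symmetric)
    corr = np.triu(corr, k=1)  # pairs (i < j) only

    active = np.ones(p, dtype=bool)
    dropped_pairs: list[tuple[str, str, float]] = []
    names = dataset.descriptor_names
    while True:
        sub = corr * np.outer(active, active)
        best = sub.max()
        if best <= threshold:
            break
        # np.argmax returns the first flat index, i.e. the first pair in column order
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        if abs(y_corr[i]) > abs(y_corr[j]):
            keep, drop = i, j
        elif abs(y_corr[i]) < abs(y_corr[j]):
            keep, drop = j, i
        else:
            keep, drop = i, j  # tie: drop the later column
        active[drop] = False
        dropped_pairs.append((names[keep], names[drop], float(best)))

    keep_idx = [j for j in range(p) if active[j]]
    reduced = QSARDataset(
        list(dataset.compound_ids),
        [names[j] for j in keep_idx],
        dataset.values[:, keep_idx],
        dataset.activities.copy(),
    )
    return reduced, PreprocessReport(dropped_collinear=dropped_pairs, n_remaining=len(keep_idx))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def preprocess(
    dataset: QSARDataset,
    dominant_fraction: float = 0.95,
    variance_floor: float = 1e-8,
    collinearity_threshold: float = 0.9,
) -> tuple[QSARDataset, PreprocessReport]:
    """Invariant removal followed by collinearity pruning, with a merged report."""
    reduced, rep1 = drop_invariant(dataset, dominant_fraction, variance_floor)
    reduced, rep2 = prune_collinear(reduced, collinearity_threshold)
    return reduced, PreprocessReport(
        dropped_constant=rep1.dropped_constant,
        dropped_collinear=rep2.dropped_collinear,
        n_remaining=rep2.n_remaining,
    )
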