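"""Repeated calibration/validation partitions for combined data-splitting feature selection.

CDFS (combined data-splitting feature selection) re-draws the
calibration/validation partition several times, runs the descriptor selector
on each calibration set, and later pools the selected descriptors.  The
default geometry follows the modelled series: 9 of 50 compounds held out for
validation, five repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import QSARDataset

__all__ = ["SplitAssignment", "make_splits"]


@dataclass(frozen=True)
class SplitAssignment:
    """One calibration/validation partition (a repeat of the CDFS loop)."""

    repeat_index: int  # 1-based
    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation sets overlap")


def make_splits(
    dataset: QSARDataset,
    n_validation: int = 9,
    n_repeats: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> list[SplitAssignment]:
    """Draw *n_repeats* independent calibration/validation partitions.

    Each repeat holds out *n_validation* compounds drawn uniformly without
    replacement.  With ``stratified=True`` compounds are ranked by activity,
    cut into *n_validation* rank bins, and one compound is drawn per bin, so
    the validation set spans the activity range.  Repeat *r* uses the
    substream ``(seed, r)`` of the seeded generator: adding repeats never
    changes earlier splits, and a given seed is fully reproducible.
    """
    n = dataset.n_compounds
    if not 0 < n_validation < n:
        raise ValueError(f"n_validation must be in (0, {n}), got {n_validation}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    ids = np.array(dataset.compound_ids, dtype=object)
    splits: list[SplitAssignment] = []
    for r in range(1, n_repeats + 1):
        rng = np.random.default_rng([seed, r])
        if stratified:
            order = np.argsort(dataset.activities, kind="stable")
            bins = np.array_split(order, n_validation)
            val_idx = np.array([b[rng.integers(len(b))] for b in bins])
        else:
            val_idx = rng.choice(n, size=n_validation, replace=False)
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        splits.append(
            SplitAssignment(
                repeat_index=r,
                calibration_ids=tuple(ids[~val_mask]),
                validation_ids=tuple(ids[val_mask]),
                seed=seed,
            )
        )
    return splits
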