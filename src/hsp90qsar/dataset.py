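"""Core data containers, descriptor-table I/O and activity-unit conversion.

The central container is :class:`QSARDataset`: a dense compounds × descriptors
matrix together with an aligned activity vector (pIC50).  Compound identifiers
are opaque strings (the source series uses alphanumeric labels such as
``"75a"`` or ``"81d"``), descriptor names are unique column labels.

Activity values are pIC50 on a millimolar scale, i.e.
``pIC50 = -log10(IC50 in mM)``.  This is unconventional (micromolar or molar
scales are more common in the QSAR literature) but is the scale the source
activity tables use; the unit is an explicit, overridable parameter of the
conversion helpers.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "QSARDataset",
    "DescriptorCatalog",
    "FixtureActivityTable",
    "read_descriptor_table",
    "write_descriptor_table",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "load_fixture_table5",
    "load_descriptor_catalog",
]

# multiplicative factor taking a value in μM to the given concentration unit
_UM_TO_UNIT = {"M": 1e-6, "mM": 1e-3, "uM": 1.0, "nM": 1e3}


@dataclass(frozen=True)
class CompoundRecord:
    """A single compound: identifier, pIC50 activity, optional docking group."""

    compound_id: str
    activity: float
    group: str | None = None  # "A", "B" or "C" when a docking group is known

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be a non-empty string")
        if not math.isfinite(self.activity):
            raise ValueError(f"activity of {self.compound_id!r} is not finite")
        if self.group is not None and self.group not in {"A", "B", "C"}:
            raise ValueError(f"group must be A, B or C, got {self.group!r}")


@dataclass
class QSARDataset:
    """Dense descriptor matrix plus aligned activities, keyed by compound ID.

    Invariants (enforced on construction): no missing or non-finite entries,
    unique compound IDs, unique descriptor names, consistent shapes.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # (n_compounds, n_descriptors)
    activities: np.ndarray  # (n_compounds,)

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        n, p = len(self.compound_ids), len(self.descriptor_names)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n} compounds x {p} descriptors"
            )
        if self.activities.shape != (n,):
            raise ValueError("activities length inconsistent with compound list")
        if len(set(self.compound_ids)) != n:
            dupes = sorted({c for c in self.compound_ids if self.compound_ids.count(c) > 1})
            raise ValueError(f"duplicate compound IDs: {dupes}")
        if len(set(self.descriptor_names)) != p:
            dupes = sorted({d for d in self.descriptor_names if self.descriptor_names.count(d) > 1})
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite descriptor value at compound "
                f"{self.compound_ids[i]!r}, descriptor {self.descriptor_names[j]!r}"
            )
        if not np.all(np.isfinite(self.activities)):
            i = int(np.argwhere(~np.isfinite(self.activities))[0])
            raise ValueError(f"non-finite activity for compound {self.compound_ids[i]!r}")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def X(self) -> pd.DataFrame:
        """Descriptor matrix as a DataFrame indexed by compound ID."""
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )

    def y(self) -> pd.Series:
        return pd.Series(self.activities, index=self.compound_ids, name="pIC50")

    def select_descriptors(self, names: Sequence[str]) -> "QSARDataset":
        missing = [d for d in names if d not in self.descriptor_names]
        if missing:
            raise KeyError(f"unknown descriptors: {missing}")
        idx = [self.descriptor_names.index(d) for d in names]
        return QSARDataset(
            list(self.compound_ids), list(names), self.values[:, idx], self.activities.copy()
        )

    def select_compounds(self, ids: Sequence[str]) -> "QSARDataset":
        missing = [c for c in ids if c not in self.compound_ids]
        if missing:
            raise KeyError(f"unknown compounds: {missing}")
        idx = [self.compound_ids.index(c) for c in ids]
        return QSARDataset(
            list(ids), list(self.descriptor_names), self.values[idx, :], self.activities[idx]
        )


@dataclass(frozen=True)
class DescriptorCatalog:
    """Name → (family, description) lookup for the published-model descriptors."""

    entries: dict[str, tuple[str, str]]

    def __contains__(self, name: str) -> bool:
        return _normalize_name(name) in {_normalize_name(k) for k in self.entries}

    def family(self, name: str) -> str:
        return self._lookup(name)[0]

    def description(self, name: str) -> str:
        return self._lookup(name)[1]

    def _lookup(self, name: str) -> tuple[str, str]:
        norm = _normalize_name(name)
        for key, val in self.entries.items():
            if _normalize_name(key) == norm:
                return val
        raise KeyError(f"descriptor {name!r} not in catalog")


@dataclass(frozen=True)
class FixtureActivityTable:
    """The packaged activity tables of the source compound series.

    ``activity`` has one row per compound (50 rows): experimental pIC50 and
    the pIC50 predicted by the published MLR and GA-PLS equations.
    ``ic50_um`` carries the subset of compounds with a printed IC50 in μM.
    """

    activity: pd.DataFrame  # index compound_id; experimental/mlr/gapls pIC50
    ic50_um: pd.DataFrame  # index compound_id; column ic50_um


def _normalize_name(name: str) -> str:
    """Whitespace/underscore-insensitive descriptor-name key ("dipole z" == "dipole_z")."""
    return "".join(name.split()).replace("_", "").lower()


def ic50_to_pic50(ic50: float | np.ndarray, unit: str = "mM") -> float | np.ndarray:
    """Convert an IC50 in μM to pIC50 = −log10(IC50 expressed in *unit*).

    The default ``unit="mM"`` matches the activity scale of the compound
    series modelled here (e.g. 0.153 μM → 3.82).  Vectorized over arrays.
    """
    if unit not in _UM_TO_UNIT:
        raise ValueError(f"unknown concentration unit {unit!r}; choose from {sorted(_UM_TO_UNIT)}")
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be strictly positive")
    out = -np.log10(arr * _UM_TO_UNIT[unit])
    return float(out) if np.isscalar(ic50) else out


def pic50_to_ic50(pic50: float | np.ndarray, unit: str = "mM") -> float | np.ndarray:
    """Inverse of :func:`ic50_to_pic50`; returns an IC50 in μM."""
    if unit not in _UM_TO_UNIT:
        raise ValueError(f"unknown concentration unit {unit!r}; choose from {sorted(_UM_TO_UNIT)}")
    arr = np.asarray(pic50, dtype=float)
    out = 10.0 ** (-arr) / _UM_TO_UNIT[unit]
    return float(out) if np.isscalar(pic50) else out


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_descriptor_table(
    path: str | Path,
    activity_column: str = "pIC50",
    id_column: str | None = None,
) -> QSARDataset:
    """Read a compounds × descriptors CSV/TSV into a :class:`QSARDataset`.

    The file must have a header row; the ID column is the first column unless
    *id_column* names another.  Every remaining column except
    *activity_column* is treated as a descriptor.  Row and column order are
    preserved.  Missing, duplicate-ID and non-numeric cells raise ``ValueError``
    naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column is None:
        id_column = frame.columns[0]
    if id_column not in frame.columns:
        raise ValueError(f"ID column {id_column!r} not found in {path.name}")
    if activity_column not in frame.columns:
        raise ValueError(f"activity column {activity_column!r} not found in {path.name}")

    ids = frame[id_column].tolist()
    seen: set[str] = set()
    for cid in ids:
        if cid in seen:
            raise ValueError(f"duplicate compound ID {cid!r} in {path.name}")
        seen.add(cid)

    numeric_cols = [c for c in frame.columns if c not in (id_column,)]
    parsed: dict[str, list[float]] = {}
    for col in numeric_cols:
        vals = []
        for cid, cell in zip(ids, frame[col]):
            cell = cell.strip()
            if cell == "":
                raise ValueError(f"missing value at row {cid!r}, column {col!r}")
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {cid!r}, column {col!r}"
                ) from None
        parsed[col] = vals

    descriptor_names = [c for c in numeric_cols if c != activity_column]
    values = np.column_stack([parsed[c] for c in descriptor_names]) if descriptor_names else np.empty((len(ids), 0))
    return QSARDataset(ids, descriptor_names, values, np.asarray(parsed[activity_column]))


def write_descriptor_table(
    dataset: QSARDataset, path: str | Path, activity_column: str = "pIC50"
) -> None:
    """Write a dataset to CSV in the layout :func:`read_descriptor_table` accepts.

    Values are written with ``repr``-level precision so a write/read
    round-trip reproduces the dataset bit-exactly.
    """
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["compound_id", activity_column, *dataset.descriptor_names])
    for i, cid in enumerate(dataset.compound_ids):
        writer.writerow(
            [cid, repr(dataset.activities[i].item()), *(repr(v.item()) for v in dataset.values[i])]
        )
    path.write_text(buf.getvalue(), encoding="utf-8")


def _data_path(name: str):
    return resources.files("hsp90qsar.data").joinpath(name)


def load_fixture_table5() -> FixtureActivityTable:
    """Load the packaged activity tables (experimental and predicted pIC50; IC50 in μM).

    Returns exactly 50 activity records, values as printed to two decimals.
    """
    with resources.as_file(_data_path("table5_pic50.csv")) as p:
        activity = pd.read_csv(p, dtype={"compound_id": str}).set_index("compound_id")
    with resources.as_file(_data_path("table7_ic50.csv")) as p:
        ic50 = pd.read_csv(p, dtype={"compound_id": str}).set_index("compound_id")
    if len(activity) != 50:
        raise RuntimeError("packaged activity table corrupted: expected 50 records")
    if (ic50["ic50_um"] <= 0).any():
        raise RuntimeError("packaged IC50 table corrupted: non-positive concentration")
    return FixtureActivityTable(activity=activity, ic50_um=ic50)


def load_descriptor_catalog() -> DescriptorCatalog:
    """Catalog of the 25 descriptors in the five elected MLR models plus the
    five additional descriptors of the GA-PLS equation."""
    with resources.as_file(_data_path("descriptor_catalog.csv")) as p:
        frame = pd.read_csv(p)
    return DescriptorCatalog(
        entries={r["name"]: (r["family"], r["description"]) for _, r in frame.iterrows()}
    )
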