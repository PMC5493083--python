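"""End-to-end CDFS orchestration: split, select, validate, pool, refit, audit.

Combined data-splitting feature selection (CDFS) runs the chosen descriptor
selector (stepwise MLR or GA-PLS) once per calibration/validation split,
pools the descriptors selected across splits, and refits the selector
restricted to the pooled set on a designated split's calibration compounds to
produce a single *general model*.  The general model is then put through the
full validation battery: LOO Q², external R²p, Y-randomization, and the
leverage applicability domain.

Every random draw is derived from one master seed via named substreams, so a
report is exactly reproducible and adding repeats never perturbs earlier
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .dataset import QSARDataset
from .domain import DomainAssessment, williams_table
from .ga import Chromosome, GAConfig, evolve
from .linear_models import FittedLinearModel, fit_ols, fit_pls_nipals, stepwise_select
from .preprocess import PreprocessReport, preprocess
from .splitting import SplitAssignment, make_splits
from .validation import (
    ValidationReport,
    YRandomizationResult,
    validation_report,
    y_randomization,
)

__all__ = ["SplitModelRecord", "CDFSReport", "run_cdfs"]


def _child_seed(master: int, *tags: int) -> int:
    """A reproducible 31-bit substream seed derived from the master seed."""
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] % (2**31))


@dataclass
class SplitModelRecord:
    """The model elected on one calibration/validation split."""

    repeat_index: int
    split: SplitAssignment
    model: FittedLinearModel
    report: ValidationReport


@dataclass
class CDFSReport:
    """Everything a CDFS run produces, plus a reproducibility manifest."""

    split_models: list[SplitModelRecord]
    descriptor_union: list[str]
    general_model: FittedLinearModel
    general_report: ValidationReport
    y_rand: YRandomizationResult
    domain: DomainAssessment
    preprocess_report: PreprocessReport | None
    manifest: dict

    def split_table(self) -> pd.DataFrame:
        """Per-split statistics table (the analog of a best-models summary)."""
        rows = []
        for rec in self.split_models:
            d = rec.report.to_dict()
            d["repeat"] = rec.repeat_index
            d["descriptors"] = ", ".join(rec.model.descriptor_names)
            rows.append(d)
        return pd.DataFrame(rows).set_index("repeat")

    def to_json(self) -> str:
        payload = {
            "manifest": self.manifest,
            "splits": [
                {
                    "repeat": rec.repeat_index,
                    "validation_ids": list(rec.split.validation_ids),
                    "model": rec.model.to_dict(),
                    "report": rec.report.to_dict(),
                }
                for rec in self.split_models
            ],
            "descriptor_union": self.descriptor_union,
            "general_model": self.general_model.to_dict(),
            "general_report": self.general_report.to_dict(),
            "y_randomization": {
                "original": list(self.y_rand.original),
                "iterations": [list(t) for t in self.y_rand.iterations],
                "seed": self.y_rand.seed,
            },
            "domain": {
                "h_star": self.domain.h_star,
                "residual_limit": self.domain.residual_limit,
                "n_response_outliers": int(self.domain.table["response_outlier"].sum()),
                "n_structural_outliers": int(self.domain.table["structural_outlier"].sum()),
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _fixed_subset_procedure(selector: str, names: list[str]):
    """Refit procedure on a frozen descriptor subset (for CV and Y-randomization)."""
    if selector == "gapls":
        def proc(Xf: pd.DataFrame, yv: np.ndarray) -> FittedLinearModel:
            return fit_pls_nipals(Xf[names], yv)
    else:
        def proc(Xf: pd.DataFrame, yv: np.ndarray) -> FittedLinearModel:
            return fit_ols(Xf[names], yv)
    return proc


def run_cdfs(
    dataset: QSARDataset,
    n_validation: int = 9,
    n_repeats: int = 5,
    selector: Literal["stepwise", "gapls"] = "stepwise",
    seed: int = 0,
    preprocess_first: bool = True,
    dominant_fraction: float = 0.95,
    variance_floor: float = 1e-8,
    collinearity_threshold: float = 0.9,
    stratified: bool = False,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_terms: int = 7,
    ga_config: GAConfig | None = None,
    y_rand_iter: int = 10,
    general_split: int | Literal["all"] = 1,
) -> CDFSReport:
    """Run the full CDFS workflow and return a :class:`CDFSReport`.

    *general_split* designates the split whose calibration set the general
    model is refit on (1-based; default the first split, giving a calibration
    N of n − n_validation).  ``"all"`` refits on every compound instead —
    note this changes the calibration N the report prints.
    """
    if selector not in {"stepwise", "gapls"}:
        raise ValueError("selector must be 'stepwise' or 'gapls'")

    pre_report = None
    if preprocess_first:
        dataset, pre_report = preprocess(
            dataset, dominant_fraction, variance_floor, collinearity_threshold
        )

    splits = make_splits(dataset, n_validation, n_repeats, seed=_child_seed(seed, 1), stratified=stratified)
    Xall = dataset.X()
    yall = dataset.y()

    def select_on(X_cal: pd.DataFrame, y_cal: np.ndarray, repeat: int, restrict: list[str] | None):
        cols = restrict if restrict is not None else list(X_cal.columns)
        if selector == "stepwise":
            return stepwise_select(X_cal[cols], y_cal, p_enter, p_remove, max_terms)
        cfg = ga_config or GAConfig()
        cfg = GAConfig(**{**cfg.__dict__, "seed": _child_seed(seed, 2, repeat)})
        sub = QSARDataset(list(X_cal.index), cols, X_cal[cols].to_numpy(), y_cal)
        best, _ = evolve(sub, cfg)
        names = best.selected_names(cols)
        return fit_pls_nipals(X_cal[names], y_cal)

    split_models: list[SplitModelRecord] = []
    for sp in splits:
        X_cal, y_cal = Xall.loc[list(sp.calibration_ids)], yall.loc[list(sp.calibration_ids)].to_numpy()
        X_val, y_val = Xall.loc[list(sp.validation_ids)], yall.loc[list(sp.validation_ids)].to_numpy()
        try:
            model = select_on(X_cal, y_cal, sp.repeat_index, restrict=None)
            proc = _fixed_subset_procedure(selector, model.descriptor_names)
            _, report = validation_report(proc, X_cal[model.descriptor_names], y_cal, X_val, y_val)
        except Exception as exc:
            raise RuntimeError(f"split {sp.repeat_index}, selection/validation stage: {exc}") from exc
        split_models.append(SplitModelRecord(sp.repeat_index, sp, model, report))

    # pooled descriptor union, in dataset column order
    union = [
        d for d in dataset.descriptor_names
        if any(d in rec.model.coefficients for rec in split_models)
    ]

    if general_split == "all":
        gen_cal_ids = list(dataset.compound_ids)
        gen_val_ids: list[str] = []
    else:
        sp = splits[int(general_split) - 1]
        gen_cal_ids = list(sp.calibration_ids)
        gen_val_ids = list(sp.validation_ids)
    X_cal, y_cal = Xall.loc[gen_cal_ids], yall.loc[gen_cal_ids].to_numpy()
    X_val = Xall.loc[gen_val_ids] if gen_val_ids else None
    y_val = yall.loc[gen_val_ids].to_numpy() if gen_val_ids else None

    try:
        general_model = select_on(X_cal, y_cal, 0, restrict=union)
        gen_proc = _fixed_subset_procedure(selector, general_model.descriptor_names)
        _, general_report = validation_report(
            gen_proc, X_cal[general_model.descriptor_names], y_cal, X_val, y_val
        )
    except Exception as exc:
        raise RuntimeError(f"general-model stage: {exc}") from exc

    try:
        y_rand = y_randomization(
            gen_proc,
            X_cal[general_model.descriptor_names],
            y_cal,
            n_iter=y_rand_iter,
            seed=_child_seed(seed, 3),
        )
    except Exception as exc:
        raise RuntimeError(f"Y-randomization stage: {exc}") from exc

    try:
        domain = williams_table(
            general_model,
            X_cal,
            y_cal,
            X_val,
            y_val,
            residual_limit=2.5 if selector == "stepwise" else 3.0,
        )
    except Exception as exc:
        raise RuntimeError(f"applicability-domain stage: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "master_seed": seed,
        "selector": selector,
        "n_validation": n_validation,
        "n_repeats": n_repeats,
        "n_compounds": dataset.n_compounds,
        "n_descriptors_after_preprocess": dataset.n_descriptors,
        "general_split": general_split,
        "general_calibration_n": len(gen_cal_ids),
        "stratified": stratified,
        "p_enter": p_enter,
        "p_remove": p_remove,
        "max_terms": max_terms,
        "y_randomization_iterations": y_rand_iter,
        "substream_seeds": {
            "splits": _child_seed(seed, 1),
            "y_randomization": _child_seed(seed, 3),
        },
    }

    report = CDFSReport(
        split_models=split_models,
        descriptor_union=union,
        general_model=general_model,
        general_report=general_report,
        y_rand=y_rand,
        domain=domain,
        preprocess_report=pre_report,
        manifest=manifest,
    )
    assert set(general_model.descriptor_names) <= set(union)
    return report
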