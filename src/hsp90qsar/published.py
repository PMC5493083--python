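"""The two published Hsp90-inhibition prediction equations as fixed predictors.

Both equations map six molecular descriptors to pIC50 (millimolar scale) for
3,4-isoxazolediamide Hsp90 inhibitors.  The general MLR model came from
stepwise selection over the pooled CDFS descriptor union; the GA-PLS model
from genetic-algorithm subset search with a PLS fitness.  Coefficients are
stored exactly as printed; note the TIE coefficient is printed as
0.001 (±0.00), so predictions involving large TIE values inherit that
truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .dataset import _normalize_name

__all__ = ["PublishedEquation", "predict_published", "list_published", "MLR_GENERAL", "GAPLS"]


@dataclass(frozen=True)
class PublishedEquation:
    """A fixed, citable linear pIC50 predictor with its reported statistics."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    # (n_calibration, R²c, S.E., Q²LOO, RMSE_CV) as reported
    reported_stats: tuple[int, float, float, float, float]

    def predict(self, descriptors: Mapping[str, float]) -> float:
        lookup = {_normalize_name(k): float(v) for k, v in descriptors.items()}
        total = self.intercept
        for name, coef in self.coefficients.items():
            key = _normalize_name(name)
            if key not in lookup:
                raise KeyError(f"missing required descriptor {name!r} for equation {self.name}")
            total += coef * lookup[key]
        return total


MLR_GENERAL = PublishedEquation(
    name="MLR_GENERAL",
    intercept=16.977,
    coefficients={
        "X5A": -176.806,
        "HATS4u": -4.366,
        "Mor26p": -1.951,
        "TIE": 0.001,
        "dipole z": 0.227,
        "Mor26e": 0.863,
    },
    reported_stats=(41, 0.771, 0.267, 0.637, 0.297),
)

GAPLS = PublishedEquation(
    name="GAPLS",
    intercept=9.018,
    coefficients={
        "X5A": -114.521,
        "GATS4e": -1.406,
        "E3u": -1.586,
        "MATS7e": -2.615,
        "G1u": 38.705,
        "RDF075m": 0.048,
    },
    reported_stats=(41, 0.755, 0.249, 0.653, 0.266),
)

_EQUATIONS = {"MLR_GENERAL": MLR_GENERAL, "GAPLS": GAPLS}
_ALIASES = {"mlr": "MLR_GENERAL", "mlr_general": "MLR_GENERAL", "gapls": "GAPLS", "ga-pls": "GAPLS"}


def list_published() -> dict[str, PublishedEquation]:
    """Catalog of the published equations, keyed by canonical name."""
    return dict(_EQUATIONS)


def predict_published(name: str, descriptors: Mapping[str, float]) -> float:
    """Evaluate a published equation on a named descriptor map.

    Descriptor-name matching is whitespace/underscore-insensitive
    ("dipole z" == "dipole_z").  Raises ``KeyError`` naming any missing
    descriptor and ``ValueError`` for an unknown equation.
    """
    key = _ALIASES.get(name.lower(), name)
    if key not in _EQUATIONS:
        raise ValueError(f"unknown equation {name!r}; choose from {sorted(_EQUATIONS)}")
    return _EQUATIONS[key].predict(descriptors)
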