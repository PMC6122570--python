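"""Area-based Ki67 index, the count-based truth, and their calibration.

The area index A = 100 * (positive nucleus pixel area) / (total nucleus
pixel area) is a surrogate for the Ki67 index T = 100 * n_positive /
(n_positive + n_negative) that avoids detecting individual nuclei.
Within tumor regions A tracks T linearly (positive and negative tumor
nuclei have near-identical size distributions), so a degree-1 OLS fit
T ~ c1*A + c2 calibrates it; higher-degree polynomial variants exist for
the whole-image comparison, where contamination by non-tumor nuclei
breaks the linear relationship.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import NucleusSpec

__all__ = [
    "AreaIndex",
    "TrueIndex",
    "CalibrationModel",
    "UndefinedIndexError",
    "compute_area_index",
    "compute_true_index",
    "fit_calibration",
    "apply_calibration",
]


class UndefinedIndexError(ValueError):
    """The index is undefined (no nucleus area / no tumor nuclei).

    Raised instead of returning 0 or 100: an empty ROI is a data error,
    not a 0% proliferation.
    """


@dataclass(frozen=True)
class AreaIndex:
    value: float
    positive_area_px: int
    negative_area_px: int
    scope: str  # "within_tumor" | "whole_image"


@dataclass(frozen=True)
class TrueIndex:
    value: float
    n_positive: int
    n_negative: int


def compute_area_index(masks, tumor_mask: np.ndarray | None = None) -> AreaIndex:
    """Positive-area percentage from a positive/negative mask pair.

    ``masks`` may be a SegmentationMasks or a (positive, negative) pair
    of boolean arrays.  With a tumor mask, both masks are intersected
    with it first (scope within_tumor); otherwise scope is whole_image.
    """
    if hasattr(masks, "positive_mask"):
        pos, neg = masks.positive_mask, masks.negative_mask
    else:
        pos, neg = masks
    pos = np.asarray(pos, dtype=bool)
    neg = np.asarray(neg, dtype=bool)
    if pos.shape != neg.shape:
        raise ValueError("mask shapes differ")
    if np.any(pos & neg):
        raise ValueError("positive and negative masks overlap")
    scope = "whole_image"
    if tumor_mask is not None:
        tm = np.asarray(tumor_mask, dtype=bool)
        pos = pos & tm
        neg = neg & tm
        scope = "within_tumor"
    p, n = int(pos.sum()), int(neg.sum())
    if p + n == 0:
        raise UndefinedIndexError("no nucleus pixels: area index undefined")
    return AreaIndex(100.0 * p / (p + n), p, n, scope)


def compute_true_index(annotations: Iterable[NucleusSpec]) -> TrueIndex:
    """Count-based Ki67 index from annotations; non-tumor nuclei excluded."""
    n_pos = n_neg = 0
    for nuc in annotations:
        if nuc.label == "positive":
            n_pos += 1
        elif nuc.label == "negative":
            n_neg += 1
    if n_pos + n_neg == 0:
        raise UndefinedIndexError("no tumor nuclei: true index undefined")
    return TrueIndex(100.0 * n_pos / (n_pos + n_neg), n_pos, n_neg)


@dataclass
class CalibrationModel:
    """Polynomial OLS calibration T ~ poly(A) with fit diagnostics.

    ``coefficients`` is in ascending order (intercept first); for a
    degree-1 model, ``c1`` is the slope and ``c2`` the intercept.  RMSE
    uses the residual-degrees-of-freedom convention sqrt(SSE/(n-p-1)),
    the "root MSE" printed by standard regression software.
    """

    degree: int
    coefficients: list[float]
    conf_int: list[list[float]]  # per coefficient, 95% t-based
    n: int
    rmse: float
    r_square: float
    adj_r_square: float

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")

    @property
    def c1(self) -> float:
        if self.degree != 1:
            raise AttributeError("c1/c2 notation applies to the linear model only")
        return self.coefficients[1]

    @property
    def c2(self) -> float:
        if self.degree != 1:
            raise AttributeError("c1/c2 notation applies to the linear model only")
        return self.coefficients[0]

    def predict(self, a) -> np.ndarray:
        """Raw polynomial evaluation (no clamping)."""
        a = np.asarray(a, dtype=float)
        return np.polynomial.polynomial.polyval(a, np.asarray(self.coefficients))

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "degree": self.degree,
            "coefficients": list(self.coefficients),
            "ci": [list(c) for c in self.conf_int],
            "n": self.n,
            "rmse": self.rmse,
            "r_square": self.r_square,
            "adj_r_square": self.adj_r_square,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "CalibrationModel":
        d = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls(
            int(d["degree"]), list(d["coefficients"]), [list(c) for c in d["ci"]],
            int(d["n"]), float(d["rmse"]), float(d["r_square"]), float(d["adj_r_square"]),
        )


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        a = pairs.iloc[:, 0].to_numpy(dtype=float)
        t = pairs.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array of (A, T)")
        a, t = arr[:, 0], arr[:, 1]
    return a, t


def fit_calibration(pairs, degree: int = 1) -> CalibrationModel:
    """OLS fit of T on a polynomial in A, with 95% t-based coefficient CIs."""
    a, t = _as_pairs(pairs)
    n = a.size
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if n <= degree + 1:
        raise ValueError(f"need more than {degree + 1} points for degree {degree}")
    if np.ptp(a) == 0:
        raise ValueError("constant A: calibration is unidentifiable")
    design = np.vander(a, degree + 1, increasing=True)
    res = sm.OLS(t, design).fit()
    return CalibrationModel(
        degree=degree,
        coefficients=[float(c) for c in res.params],
        conf_int=[[float(lo), float(hi)] for lo, hi in res.conf_int(alpha=0.05)],
        n=int(n),
        rmse=float(np.sqrt(res.mse_resid)),  # SSE/(n - p - 1)
        r_square=float(res.rsquared),
        adj_r_square=float(res.rsquared_adj),
    )


def apply_calibration(model: CalibrationModel, a):
    """Calibrated index: polynomial evaluation clamped to [0, 100].

    Clamping handles the small-A regime where a negative intercept would
    otherwise yield a (meaningless) negative percentage.
    """
    if model is None or not model.coefficients:
        raise ValueError("calibration model is not fitted")
    out = np.clip(model.predict(a), 0.0, 100.0)
    return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out
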