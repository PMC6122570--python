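"""Method-agreement statistics: RMSE, R², Lin's CCC, Bland-Altman.

Quantifies how well an estimate of the Ki67 index agrees with the
count-based ground truth, both for raw area-based estimates and after a
polynomial recalibration.  Lin's concordance correlation coefficient
combines precision (Pearson correlation) with accuracy (penalty for
location and scale shift); Bland-Altman analysis reports the mean
difference (bias) and 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .index import CalibrationModel, fit_calibration

__all__ = [
    "CCCResult",
    "BlandAltmanResult",
    "AgreementReport",
    "rmse",
    "lin_ccc",
    "bland_altman",
    "build_agreement_report",
]

_DEGREE_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}
_NAME_DEGREES = {v: k for k, v in _DEGREE_NAMES.items()}


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    n: int
    differences: np.ndarray = field(repr=False, compare=False, default=None)
    means: np.ndarray = field(repr=False, compare=False, default=None)


def _check_pair(truth, estimate, n_min: int = 2) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=float).ravel()
    e = np.asarray(estimate, dtype=float).ravel()
    if t.size != e.size:
        raise ValueError(f"length mismatch: {t.size} vs {e.size}")
    if t.size < n_min:
        raise ValueError(f"need at least {n_min} pairs")
    return t, e


def rmse(truth, estimate, dof_adjust: int | None = None) -> float:
    """Root mean square error of estimate vs truth.

    Plain convention sqrt(mean d²) by default; with ``dof_adjust=p`` the
    regression convention sqrt(SSE / (n - p - 1)) for an estimate fitted
    with p slope parameters.
    """
    t, e = _check_pair(truth, estimate)
    sse = float(((e - t) ** 2).sum())
    n = t.size
    if dof_adjust is None:
        return float(np.sqrt(sse / n))
    if n < dof_adjust + 2:
        raise ValueError("too few points for the requested dof adjustment")
    return float(np.sqrt(sse / (n - dof_adjust - 1)))


def lin_ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a CI.

    ccc = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population (1/n)
    moments.  The CI uses the Fisher z-transform with Lin's asymptotic
    standard error, back-transformed; for |ccc| numerically 1 the CI
    degenerates to the point itself.
    """
    x, y = _check_pair(x, y, n_min=3)
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = float(((x - mx) ** 2).mean())
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    if sx2 == 0 or sy2 == 0:
        raise ValueError("constant input vector: CCC undefined")
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-12 or abs(r) < 1e-12:
        return CCCResult(float(ccc), float(ccc), float(ccc), n)
    u2 = (mx - my) ** 2 / np.sqrt(sx2 * sy2)
    one_m = 1.0 - ccc**2
    se_z = np.sqrt(
        (
            (1.0 - r**2) * ccc**2 / (one_m * r**2)
            + 2.0 * ccc**3 * (1.0 - ccc) * u2 / (r * one_m**2)
            - ccc**4 * u2**2 / (2.0 * r**2 * one_m**2)
        )
        / (n - 2)
    )
    from scipy.stats import norm

    z = np.arctanh(ccc)
    q = norm.ppf(1.0 - alpha / 2.0)
    lo, hi = np.tanh(z - q * se_z), np.tanh(z + q * se_z)
    return CCCResult(float(ccc), float(lo), float(hi), n)


def bland_altman(truth, estimate) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of (estimate − truth).

    The limits are bias ± 1.96 · SD of the differences (sample SD,
    n − 1 denominator); per-pair averages are returned for plotting.
    """
    t, e = _check_pair(truth, estimate)
    d = e - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=t.size,
        differences=d,
        means=(t + e) / 2.0,
    )


@dataclass
class AgreementReport:
    """Per-method agreement table plus the fitted calibration models."""

    table: pd.DataFrame
    models: dict[str, CalibrationModel]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.table.to_json(orient="records", indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _row(method: str, variant: str, t, e, model: CalibrationModel | None) -> dict:
    if model is None:
        r = float(np.corrcoef(t, e)[0, 1]) if np.ptp(e) > 0 else np.nan
        row_rmse = rmse(t, e)
        r2, adj = (r**2 if np.isfinite(r) else np.nan), np.nan
    else:
        row_rmse, r2, adj = model.rmse, model.r_square, model.adj_r_square
    c = lin_ccc(t, e)
    ba = bland_altman(t, e)
    return {
        "method": method,
        "variant": variant,
        "n": len(t),
        "rmse": row_rmse,
        "r_square": r2,
        "adj_r_square": adj,
        "ccc": c.ccc,
        "ccc_ci_low": c.ci_low,
        "ccc_ci_high": c.ci_high,
        "bias": ba.bias,
        "loa_low": ba.loa_low,
        "loa_high": ba.loa_high,
    }


def build_agreement_report(
    pairs: pd.DataFrame,
    model_specs: Mapping[str, int | str | None],
    truth_col: str = "T",
) -> AgreementReport:
    """Raw and post-model agreement statistics per estimate column.

    ``model_specs`` maps estimate column names to a polynomial degree
    (1-3, or "linear"/"quadratic"/"cubic"), or None for raw-only.  For
    each column a raw row is emitted, then (if a degree is given) the
    column is recalibrated by OLS against the truth and a post-model row
    is emitted from the fitted values.
    """
    if truth_col not in pairs.columns:
        raise ValueError(f"missing truth column {truth_col!r}")
    t = pairs[truth_col].to_numpy(dtype=float)
    rows, models = [], {}
    for col, spec in model_specs.items():
        if col not in pairs.columns:
            raise ValueError(f"unknown estimate column {col!r}")
        degree = _NAME_DEGREES.get(spec, spec)
        if degree is not None and degree not in (1, 2, 3):
            raise ValueError(f"unknown model spec {spec!r} for column {col!r}")
        e = pairs[col].to_numpy(dtype=float)
        rows.append(_row(col, "raw", t, e, None))
        if degree is not None:
            model = fit_calibration(np.column_stack([e, t]), degree=degree)
            fitted = model.predict(e)
            rows.append(_row(col, _DEGREE_NAMES[degree], t, fitted, model))
            models[col] = model
    return AgreementReport(pd.DataFrame(rows), models)
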