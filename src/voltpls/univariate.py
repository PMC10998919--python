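"""Per-analyte straight-line calibration.

Ordinary least-squares calibration lines with R², blank-SD-based detection
limits (LOD = 3·S_b/m, LOQ = 10·S_b/m) and a contiguous-span linear-range
heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "FitResult",
    "LinearRange",
    "blank_sd",
    "detect_linear_range",
    "fit_calibration",
    "fit_line",
    "lod",
    "loq",
]


@dataclass
class CalibrationCurve:
    """Paired (concentration, response) points plus replicate blanks."""

    concentrations: np.ndarray
    responses: np.ndarray
    blanks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must be paired")
        if self.concentrations.size < 3:
            raise ValueError("a calibration curve needs at least 3 points")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.unique(self.concentrations).size < 2:
            raise ValueError("at least 2 distinct concentrations required")
        if self.blanks is not None:
            self.blanks = np.asarray(self.blanks, dtype=float)


@dataclass(frozen=True)
class LinearRange:
    """Widest concentration span passing the linearity criterion."""

    low: float
    high: float
    r_squared: float
    meets_threshold: bool = True

    def __iter__(self):
        yield self.low
        yield self.high


@dataclass(frozen=True)
class FitResult:
    """Summary of one univariate calibration.

    ``slope_m`` in current units per µM, ``s_b`` the blank standard
    deviation in current units, ``lod``/``loq`` in µM with
    ``loq = (10/3)·lod`` by construction.
    """

    slope_m: float
    intercept: float
    r_squared: float
    s_b: float | None
    lod: float | None
    loq: float | None
    linear_range: LinearRange

    def to_dict(self) -> dict:
        return {
            "slope_m": self.slope_m,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "s_b": self.s_b,
            "lod_uM": self.lod,
            "loq_uM": self.loq,
            "linear_range_uM": [self.linear_range.low, self.linear_range.high],
            "linear_range_meets_threshold": self.linear_range.meets_threshold,
        }


def fit_line(curve: CalibrationCurve) -> tuple[float, float, float]:
    """OLS straight line: returns (slope, intercept, R²)."""
    res = stats.linregress(curve.concentrations, curve.responses)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def blank_sd(replicate_blanks) -> float:
    """Sample standard deviation (n−1 denominator) of replicate blanks."""
    blanks = np.asarray(replicate_blanks, dtype=float)
    if blanks.size < 3:
        raise ValueError("blank SD needs at least 3 replicates")
    return float(np.std(blanks, ddof=1))


def _check_slope(slope_m: float, s_b: float) -> None:
    if slope_m <= 0:
        raise ValueError("calibration slope must be positive")
    if s_b < 0:
        raise ValueError("blank SD must be non-negative")


def lod(s_b: float, slope_m: float) -> float:
    """Limit of detection, 3·S_b/m, in µM."""
    _check_slope(slope_m, s_b)
    return 3.0 * s_b / slope_m


def loq(s_b: float, slope_m: float) -> float:
    """Limit of quantitation, 10·S_b/m, in µM."""
    _check_slope(slope_m, s_b)
    return 10.0 * s_b / slope_m


def detect_linear_range(
    curve: CalibrationCurve, r2_min: float = 0.995
) -> LinearRange:
    """Widest contiguous concentration span whose OLS refit has R² ≥ r2_min.

    Spans are contiguous runs of at least three points in concentration
    order with at least two distinct concentrations.  Ties on span width are
    broken toward more points, then toward the lower endpoint.  If no span
    qualifies, the best-R² span is returned with ``meets_threshold=False``
    and a warning.
    """
    if curve.concentrations.size < 4:
        raise ValueError("linear-range detection needs at least 4 points")
    order = np.argsort(curve.concentrations, kind="stable")
    conc = curve.concentrations[order]
    resp = curve.responses[order]
    n = conc.size
    best = None          # (span, n_points, -low, i, j, r2) for qualifying spans
    fallback = None      # (r2, span, i, j) best span regardless of threshold
    for i in range(n - 2):
        for j in range(i + 2, n):
            sub_c = conc[i : j + 1]
            sub_r = resp[i : j + 1]
            if np.unique(sub_c).size < 2:
                continue
            res = stats.linregress(sub_c, sub_r)
            r2 = float(res.rvalue**2)
            span = sub_c[-1] - sub_c[0]
            if fallback is None or (r2, span) > fallback[:2]:
                fallback = (r2, span, i, j)
            if r2 >= r2_min:
                key = (span, j - i + 1, -sub_c[0])
                if best is None or key > best[0]:
                    best = (key, i, j, r2)
    if best is not None:
        _, i, j, r2 = best
        return LinearRange(float(conc[i]), float(conc[j]), r2, True)
    r2, _, i, j = fallback
    warnings.warn(
        f"no contiguous span reaches R² >= {r2_min}; reporting best span "
        f"(R² = {r2:.4f})",
        stacklevel=2,
    )
    return LinearRange(float(conc[i]), float(conc[j]), r2, False)


def fit_calibration(curve: CalibrationCurve, r2_min: float = 0.995) -> FitResult:
    """Full univariate summary: line, R², S_b, LOD/LOQ and linear range."""
    slope, intercept, r2 = fit_line(curve)
    if curve.concentrations.size >= 4:
        lin = detect_linear_range(curve, r2_min)
    else:
        lin = LinearRange(
            float(curve.concentrations.min()), float(curve.concentrations.max()), r2
        )
    if curve.blanks is not None:
        s_b = blank_sd(curve.blanks)
        return FitResult(slope, intercept, r2, s_b, lod(s_b, slope), loq(s_b, slope), lin)
    return FitResult(slope, intercept, r2, None, None, None, lin)
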