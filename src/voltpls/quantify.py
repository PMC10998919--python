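"""Real-sample quantitation arithmetic.

Standard-addition extrapolation, spiked-recovery percentages and replicate
relative standard deviation — the downstream bookkeeping applied to
PLS-predicted concentrations when analysing spiked biofluid samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RecoveryRecord",
    "StandardAdditionSeries",
    "recovery_percent",
    "rsd",
    "standard_addition_estimate",
]


@dataclass
class StandardAdditionSeries:
    """Spike levels and the paired measured responses/concentrations.

    ``added`` must increase strictly from 0 (the unspiked sample first).
    ``dilution_factor`` converts the in-cell estimate back to the original
    sample (e.g. 30 for a 30-fold dilution).
    """

    added: np.ndarray
    measured: np.ndarray
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.added = np.asarray(self.added, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        if self.added.shape != self.measured.shape:
            raise ValueError("added and measured must be paired")
        if self.added.size < 3:
            raise ValueError("a standard-addition series needs >= 3 points")
        if self.added[0] != 0.0:
            raise ValueError("the first addition must be 0 (unspiked sample)")
        if np.any(np.diff(self.added) <= 0):
            raise ValueError("additions must be strictly increasing")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")


def standard_addition_estimate(series: StandardAdditionSeries) -> float:
    """Concentration of the original sample by x-intercept extrapolation.

    Fits measured ~ added by OLS and returns |x-intercept| × dilution
    factor.  A non-positive slope means the series carries no usable
    signal and is rejected.
    """
    res = stats.linregress(series.added, series.measured)
    if res.slope <= 0:
        raise ValueError(
            f"standard-addition slope must be positive (got {res.slope:.4g})"
        )
    x_intercept = -res.intercept / res.slope
    return abs(float(x_intercept)) * series.dilution_factor


def recovery_percent(found_before: float, added: float, found_after: float) -> float:
    """Spiked recovery: 100 × found_after / (found_before + added).

    Returned unrounded; reports round to the precision of the table they
    reproduce.
    """
    if added <= 0:
        raise ValueError("added amount must be positive")
    denom = found_before + added
    if denom <= 0:
        raise ValueError("found_before + added must be positive")
    return 100.0 * found_after / denom


def rsd(values) -> float:
    """Relative standard deviation, 100 × sample SD / |mean|, in percent."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("RSD needs at least 2 replicate values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * np.std(values, ddof=1) / abs(mean))


@dataclass(frozen=True)
class RecoveryRecord:
    """One row of a spiked-recovery table."""

    component: str
    found_before: float
    added: float
    found_after: float
    recovery_pct: float
    rsd_pct: float | None = None

    def __post_init__(self) -> None:
        if self.rsd_pct is not None and self.rsd_pct < 0:
            raise ValueError("rsd_pct must be >= 0")

    @classmethod
    def from_measurements(
        cls,
        component: str,
        found_before: float,
        added: float,
        found_after_replicates,
        decimals: int | None = None,
    ) -> "RecoveryRecord":
        reps = np.asarray(found_after_replicates, dtype=float)
        found_after = float(reps.mean())
        rec = recovery_percent(found_before, added, found_after)
        if decimals is not None:
            rec = round(rec, decimals)
        return cls(
            component,
            found_before,
            added,
            found_after,
            rec,
            rsd(reps) if reps.size >= 2 else None,
        )

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "found_before_uM": self.found_before,
            "added_uM": self.added,
            "found_after_uM": self.found_after,
            "recovery_pct": self.recovery_pct,
            "rsd_pct": self.rsd_pct,
        }
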