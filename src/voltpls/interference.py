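"""Interference tolerance-ratio analysis.

Determines, for a fitted PLS model, the largest interferent-to-analyte
concentration ratio (Ci/Ca) whose effect on the predicted concentration
stays within a relative-deviation threshold (±5% by convention), by
bisection on noiseless simulated sweeps.  Non-electroactive species (no
peak, zero broadband gain) never perturb the prediction and report the cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls import PLSModel, predict
from .processing import FilterSpec, fft_denoise, subtract_blank
from .simulate import (
    ConditionSet,
    ElectrodeProfile,
    GridSpec,
    NoiseModel,
    PeakSpec,
    Voltammogram,
    gaussian_peak,
    generate_voltammogram,
)

__all__ = [
    "InterferenceConfig",
    "InterferentModel",
    "ToleranceResult",
    "demo_interferents",
    "relative_prediction_deviation",
    "solve_tolerance",
    "tolerance_ratio",
]


@dataclass(frozen=True)
class InterferentModel:
    """Signal contribution of one interfering species.

    ``peak`` models an electroactive interferent (its sensitivity is the
    added current per µM at its own potential); ``broadband_gain`` adds a
    flat, non-specific current per µM across the whole window.  Both zero
    describes a non-electroactive species.
    """

    name: str
    peak: PeakSpec | None = None
    broadband_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.broadband_gain < 0:
            raise ValueError("broadband_gain must be >= 0")

    def currents(self, potentials: np.ndarray, conc: float) -> np.ndarray:
        signal = np.full(potentials.shape, self.broadband_gain * conc)
        if self.peak is not None:
            signal = signal + self.peak.sensitivity_m * conc * gaussian_peak(
                potentials, self.peak.center_potential, self.peak.width
            )
        return signal


@dataclass
class InterferenceConfig:
    """Simulation context shared by all deviation evaluations."""

    profile: ElectrodeProfile
    conditions: ConditionSet | None = None
    grid: GridSpec | None = None
    filter_spec: FilterSpec | None = None

    def __post_init__(self) -> None:
        self.conditions = self.conditions or ConditionSet()
        self.grid = self.grid or GridSpec()


def _noiseless(seed: int = 0) -> NoiseModel:
    return NoiseModel(white_sd=0.0, drift_amplitude=2.0, seed=seed)


def _process(v: Voltammogram, blank: Voltammogram, spec: FilterSpec | None):
    if spec is not None:
        v = fft_denoise(v, spec)
        blank = fft_denoise(blank, spec)
    return subtract_blank(v, blank).currents


def _predict_conc(model: PLSModel, currents: np.ndarray) -> np.ndarray:
    return predict(model, currents[None, :])[0]


def relative_prediction_deviation(
    model: PLSModel,
    base_conc: dict,
    interferent: InterferentModel,
    ratio: float,
    config: InterferenceConfig,
    analyte: str,
    denominator: str = "baseline",
) -> dict[str, float]:
    """Per-analyte |Δprediction| / prediction under an added interferent.

    The interferent concentration is ``ratio × base_conc[analyte]`` (Ci/Ca
    relative to the analyte under study).  Simulation is noiseless;
    ``denominator`` chooses the interferent-free prediction ("baseline",
    default) or the true concentration ("true") as the reference.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    names = model.target_names or config.profile.analyte_names
    ca = float(base_conc[analyte])
    if ca <= 0:
        raise ValueError("base analyte concentration must be positive")
    blank = generate_voltammogram(
        {n: 0.0 for n in config.profile.analyte_names},
        config.profile, config.conditions, _noiseless(), config.grid,
    )
    scan = generate_voltammogram(
        base_conc, config.profile, config.conditions, _noiseless(), config.grid
    )
    base_pred = _predict_conc(model, _process(scan, blank, config.filter_spec))
    perturbed = scan.with_currents(
        scan.currents + interferent.currents(scan.potentials, ratio * ca)
    )
    pert_pred = _predict_conc(model, _process(perturbed, blank, config.filter_spec))
    out = {}
    for i, name in enumerate(names):
        ref = base_pred[i] if denominator == "baseline" else float(base_conc[name])
        if ref == 0:
            raise ValueError(f"zero reference prediction for {name}")
        out[name] = float(abs(pert_pred[i] - base_pred[i]) / abs(ref))
    return out


@dataclass(frozen=True)
class ToleranceResult:
    """Maximum tolerated Ci/Ca for one analyte/interferent pair."""

    analyte: str
    interferent: str
    ratio: float
    capped: bool
    deviation_at_ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "interferent": self.interferent,
            "ratio": self.ratio,
            "capped": self.capped,
            "deviation_at_ratio": self.deviation_at_ratio,
        }


def solve_tolerance(
    deviation_fn, threshold: float, cap: float, rel_tol: float = 0.01
) -> tuple[float, bool, float]:
    """Bisection for deviation(ratio) = threshold on a monotone deviation.

    Returns (ratio, capped, deviation_at_ratio).  The final bracket is
    verified: deviation just below the root stays under the threshold and
    just above stays over it.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if cap <= 0:
        raise ValueError("cap must be positive")
    d_cap = deviation_fn(cap)
    if d_cap < threshold:
        return cap, True, d_cap
    lo, hi = 0.0, cap
    d_mid = d_cap
    mid = cap
    while hi - lo > rel_tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        d_mid = deviation_fn(mid)
        if d_mid < threshold:
            lo = mid
        else:
            hi = mid
    # bracket check: the solution separates under- from over-threshold
    if lo > 0 and deviation_fn(lo) > threshold * (1 + 1e-9):
        raise ArithmeticError("deviation is not monotone around the solution")
    return 0.5 * (lo + hi), False, d_mid


def tolerance_ratio(
    model: PLSModel,
    analyte: str,
    interferent: InterferentModel,
    config: InterferenceConfig,
    threshold: float = 0.05,
    cap: float = 1000.0,
    base_conc: dict | None = None,
    denominator: str = "baseline",
) -> ToleranceResult:
    """Largest Ci/Ca keeping the analyte's prediction deviation ≤ threshold.

    Bisection to 1% relative tolerance; results reaching ``cap`` are
    flagged ``capped`` (the table convention "> cap").  A tolerance below
    ratio 1 — interference already above threshold at equimolar level — is
    reported with a warning.
    """
    base_conc = base_conc or {n: 5.0 for n in config.profile.analyte_names}

    def deviation(r: float) -> float:
        return relative_prediction_deviation(
            model, base_conc, interferent, r, config, analyte, denominator
        )[analyte]

    ratio, capped, dev = solve_tolerance(deviation, threshold, cap)
    if not capped and ratio < 1.0:
        warnings.warn(
            f"{interferent.name} already deviates {analyte} beyond "
            f"{threshold:.0%} below the equimolar ratio",
            stacklevel=2,
        )
    return ToleranceResult(analyte, interferent.name, ratio, capped, dev)


def demo_interferents() -> tuple[InterferentModel, ...]:
    """Illustrative, non-calibrated interferent set (synthetic gains).

    The gains are hand-picked for demonstration of the procedure only and
    carry no quantitative relation to any real sensor: an ascorbic-acid-like
    electroactive species near the UA/MOR window, a weakly adsorbing
    saccharide, and a non-electroactive cation.
    """
    return (
        InterferentModel("ascorbic_acid_like", PeakSpec(0.31, 0.05, width=0.05)),
        InterferentModel("saccharide_like", broadband_gain=2e-4),
        InterferentModel("inorganic_cation", broadband_gain=0.0),
    )
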