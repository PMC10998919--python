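"""Synthetic square-wave voltammetry signals.

This module emulates the signal phenomenology of a g-C3N4–CNT modified
glassy-carbon sensor for morphine (MOR), methadone (MET) and uric acid
(UA): additive Gaussian anodic peaks at analyte-specific potentials, peak
heights affine in concentration, a slowly drifting background with optional
white noise, and condition-dependent attenuation (solution pH, accumulation
time, square-wave frequency and amplitude).  It stands in for the
instrument, so the downstream FFT processing and calibration stages can be
exercised without hardware.

Units: potentials in volts, concentrations in micromolar (µM), currents in
arbitrary instrument units consistent with the embedded calibration slopes.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ANALYTES",
    "AnalyteDef",
    "ConditionSet",
    "ElectrodeProfile",
    "GridSpec",
    "MixtureDesign",
    "NoiseModel",
    "PeakSpec",
    "Voltammogram",
    "background_current",
    "condition_multiplier",
    "gaussian_peak",
    "generate_design",
    "generate_voltammogram",
    "paper_profile",
    "peak_signal",
]

#: Canonical analyte order used throughout the package.
ANALYTES = ("MOR", "MET", "UA")

#: Mixture-design CSV column for each analyte.
DESIGN_COLUMNS = {"MOR": "mor_uM", "MET": "met_uM", "UA": "ua_uM"}


@dataclass(frozen=True)
class GridSpec:
    """Uniform potential grid for a sweep.

    Defaults cover the 0–1.1 V anodic window in 2 mV steps (551 points).
    """

    start: float = 0.0
    stop: float = 1.1
    step: float = 0.002

    def __post_init__(self) -> None:
        if not (self.step > 0 and self.stop > self.start):
            raise ValueError("grid requires stop > start and step > 0")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def potentials(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


@dataclass(frozen=True)
class PeakSpec:
    """One anodic peak: Gaussian position/width plus its calibration line.

    ``sensitivity_m`` and ``offset_b`` are the slope and intercept of the
    peak-height-vs-concentration line (current units per µM / current
    units), so a noiseless univariate refit of simulated scans returns the
    embedded calibration equation exactly.
    """

    center_potential: float
    sensitivity_m: float
    offset_b: float = 0.0
    width: float = 0.030

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.sensitivity_m <= 0:
            raise ValueError("peak sensitivity must be > 0")


@dataclass(frozen=True)
class AnalyteDef:
    """An analyte: its peaks and the linear range it is calibrated over."""

    name: str
    peaks: tuple[PeakSpec, ...]
    linear_range: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        low, high = self.linear_range
        if not low < high:
            raise ValueError("linear_range must satisfy low < high")
        expected = {"MOR": 2, "MET": 1, "UA": 1}.get(self.name.upper())
        if expected is not None and len(self.peaks) != expected:
            raise ValueError(
                f"{self.name} must carry exactly {expected} peak(s), "
                f"got {len(self.peaks)}"
            )


@dataclass(frozen=True)
class ElectrodeProfile:
    """Per-analyte peak positions, widths and sensitivities of one sensor."""

    label: str
    analytes: tuple[AnalyteDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "analytes", tuple(self.analytes))

    def analyte(self, name: str) -> AnalyteDef:
        for a in self.analytes:
            if a.name.upper() == name.upper():
                return a
        raise KeyError(f"no analyte {name!r} in profile {self.label!r}")

    @property
    def analyte_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.analytes)


@dataclass(frozen=True)
class ConditionSet:
    """Measurement conditions.

    Defaults are the optimum operating point of the emulated sensor:
    pH 8, 120 s accumulation, 256 Hz square-wave frequency, 20 mV amplitude.
    """

    ph: float = 8.0
    accumulation_time: float = 120.0
    frequency: float = 256.0
    amplitude: float = 20.0

    def __post_init__(self) -> None:
        for name in ("ph", "accumulation_time", "frequency", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Background drift and white measurement noise.

    ``drift_amplitude`` scales a deterministic slow background (quadratic
    ramp plus one sinusoid of period ``drift_period`` volts); ``white_sd``
    is the SD of i.i.d. Gaussian noise added per grid point.  Identical
    ``seed`` gives an identical realization.
    """

    white_sd: float = 0.15
    drift_amplitude: float = 2.0
    drift_period: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be > 0")


@dataclass
class Voltammogram:
    """One potential sweep: uniform increasing grid plus a current vector."""

    potentials: np.ndarray
    currents: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.ndim != 1 or self.currents.ndim != 1:
            raise ValueError("potentials and currents must be 1-D")
        if self.potentials.size != self.currents.size:
            raise ValueError("potentials and currents must have equal length")
        if self.potentials.size < 2:
            raise ValueError("a voltammogram needs at least two points")
        steps = np.diff(self.potentials)
        if np.any(steps <= 0):
            raise ValueError("potential grid must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > 1e-9 * step):
            raise ValueError("potential grid must be uniform")

    @property
    def grid_step(self) -> float:
        return float(self.potentials[1] - self.potentials[0])

    def with_currents(self, currents: np.ndarray, **meta) -> "Voltammogram":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Voltammogram(self.potentials.copy(), currents, new_meta)


# --------------------------------------------------------------------------
# Sensor profiles
# --------------------------------------------------------------------------

def _modified_profile() -> ElectrodeProfile:
    return ElectrodeProfile(
        label="modified",
        analytes=(
            AnalyteDef(
                "MOR",
                peaks=(
                    PeakSpec(0.39, 0.7839, 0.6571),
                    PeakSpec(0.81, 1.4612, 1.6195),
                ),
                linear_range=(1.5, 15.0),
            ),
            AnalyteDef("MET", peaks=(PeakSpec(0.73, 2.1876, 2.084),),
                       linear_range=(1.0, 15.0)),
            AnalyteDef("UA", peaks=(PeakSpec(0.34, 1.3644, -0.097),),
                       linear_range=(1.0, 20.0)),
        ),
    )


#: Sensitivity scaling of the plain-CNT electrode relative to the modified
#: one.  The unmodified sensor shows the same peaks at slightly shifted
#: potentials with lower currents; 0.6 is a qualitative factor for
#: comparison demos only.
_UNMODIFIED_SCALE = 0.6


def _unmodified_profile() -> ElectrodeProfile:
    s = _UNMODIFIED_SCALE
    return ElectrodeProfile(
        label="unmodified",
        analytes=(
            AnalyteDef(
                "MOR",
                peaks=(
                    PeakSpec(0.42, 0.7839 * s, 0.6571 * s),
                    PeakSpec(0.83, 1.4612 * s, 1.6195 * s),
                ),
                linear_range=(1.5, 15.0),
            ),
            AnalyteDef("MET", peaks=(PeakSpec(0.79, 2.1876 * s, 2.084 * s),),
                       linear_range=(1.0, 15.0)),
            AnalyteDef("UA", peaks=(PeakSpec(0.33, 1.3644 * s, 0.0),),
                       linear_range=(1.0, 20.0)),
        ),
    )


_PROFILES = {"modified": _modified_profile, "unmodified": _unmodified_profile}


def paper_profile(label: str) -> ElectrodeProfile:
    """Return a built-in sensor profile.

    ``"modified"`` is the g-C3N4–CNT-GCE sensor (peak potentials 0.39/0.81 V
    for MOR, 0.73 V MET, 0.34 V UA, with its published calibration lines);
    ``"unmodified"`` is the plain CNT-GCE (0.42/0.83, 0.79, 0.33 V) with
    scaled-down sensitivities for qualitative comparison.
    """
    try:
        return _PROFILES[label]()
    except KeyError:
        valid = ", ".join(sorted(_PROFILES))
        raise ValueError(f"unknown profile {label!r}; valid labels: {valid}") from None


# --------------------------------------------------------------------------
# Condition response
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _ConditionResponse:
    ph_floor: float            # no measurable response below this pH
    time_plateau_s: float      # response stable from here on
    freq_plateau_hz: tuple[float, float]
    amp_plateau_mv: tuple[float, float]


_PH_OPT = 8.0
_FREQ_MAX_HZ = 564.0          # upper end of the scanned frequency range
_FREQ_FALL = 0.4              # fractional loss from plateau end to _FREQ_MAX_HZ
_AMP_FALL_PER_MV = 0.05       # fractional loss per mV beyond the plateau
_PH_FALL_PER_UNIT = 0.05      # slight decay above the pH optimum

_PEAK_CONDITIONS = {
    ("MOR", 0): _ConditionResponse(4.0, 120.0, (256.0, 354.0), (15.0, 25.0)),
    ("MOR", 1): _ConditionResponse(6.0, 120.0, (177.0, 256.0), (15.0, 25.0)),
    ("MET", 0): _ConditionResponse(6.0, 120.0, (177.0, 256.0), (15.0, 25.0)),
    ("UA", 0): _ConditionResponse(5.0, 90.0, (256.0, 443.0), (10.0, 20.0)),
}


def _ph_factor(ph: float, floor: float) -> float:
    if ph < floor:
        return 0.0
    if ph <= _PH_OPT:
        return (ph - floor) / (_PH_OPT - floor)
    return max(0.0, 1.0 - _PH_FALL_PER_UNIT * (ph - _PH_OPT))


def _time_factor(t: float, plateau: float) -> float:
    return min(1.0, max(0.0, t / plateau))


def _plateau_factor(x: float, lo: float, hi: float, fall_rate: float) -> float:
    if x <= lo:
        return max(0.0, x / lo)
    if x <= hi:
        return 1.0
    return max(0.0, 1.0 - fall_rate * (x - hi))


def condition_multiplier(
    conditions: ConditionSet, analyte: str, peak_index: int = 0
) -> float:
    """Fractional peak-height attenuation under non-optimal conditions.

    Returns 1.0 at the optimum (pH 8, 120 s, 256 Hz, 20 mV) and on each
    peak's observed plateau, decays monotonically outside it, and is a hard
    zero below the per-peak no-response pH (e.g. MET shows no signal below
    pH 6).  The result is clamped to [0, 1].
    """
    try:
        resp = _PEAK_CONDITIONS[(analyte.upper(), peak_index)]
    except KeyError:
        raise ValueError(
            f"no condition response defined for {analyte!r} peak {peak_index}"
        ) from None
    f = _ph_factor(conditions.ph, resp.ph_floor)
    f *= _time_factor(conditions.accumulation_time, resp.time_plateau_s)
    f *= _plateau_factor(
        conditions.frequency, *resp.freq_plateau_hz,
        fall_rate=_FREQ_FALL / (_FREQ_MAX_HZ - resp.freq_plateau_hz[1]),
    )
    f *= _plateau_factor(
        conditions.amplitude, *resp.amp_plateau_mv, fall_rate=_AMP_FALL_PER_MV
    )
    return float(min(1.0, max(0.0, f)))


# --------------------------------------------------------------------------
# Signal synthesis
# --------------------------------------------------------------------------

def gaussian_peak(potentials: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Gaussian peak profile over the potential grid."""
    return np.exp(-((potentials - center) ** 2) / (2.0 * width**2))


def background_current(potentials: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Deterministic slow background: quadratic ramp plus one sinusoid."""
    potentials = np.asarray(potentials, dtype=float)
    span = potentials[-1] - potentials[0]
    x = (potentials - potentials[0]) / span
    return noise.drift_amplitude * (
        x**2 + 0.5 * np.sin(2.0 * np.pi * (potentials - potentials[0]) / noise.drift_period)
    )


def _conc_mapping(
    conc, profile: ElectrodeProfile
) -> dict[str, float]:
    if isinstance(conc, Mapping):
        unknown = set(conc) - {a.upper() for a in profile.analyte_names} - set(
            profile.analyte_names
        )
        if unknown:
            raise ValueError(f"unknown analytes in concentration mapping: {unknown}")
        out = {a: float(conc.get(a, conc.get(a.upper(), 0.0)))
               for a in profile.analyte_names}
    elif isinstance(conc, Sequence) and not isinstance(conc, str):
        if len(conc) != len(profile.analytes):
            raise ValueError(
                f"expected {len(profile.analytes)} concentrations, got {len(conc)}"
            )
        out = {a: float(c) for a, c in zip(profile.analyte_names, conc)}
    else:
        raise TypeError("conc must be a mapping or a sequence of concentrations")
    for name, c in out.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
    return out


def peak_signal(
    conc,
    profile: ElectrodeProfile,
    conditions: ConditionSet | None = None,
    potentials: np.ndarray | None = None,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Pure peak-sum signal (no background, no noise) for a mixture.

    Each peak contributes height ``(m·c + b) × condition_multiplier`` when
    its analyte's concentration ``c`` is positive, and nothing at ``c = 0``
    (a blank shows no faradaic signal; the intercept ``b`` only exists once
    the analyte is present, so noiseless refits return the embedded
    calibration lines exactly).
    """
    conditions = conditions or ConditionSet()
    if potentials is None:
        potentials = (grid or GridSpec()).potentials()
    conc_map = _conc_mapping(conc, profile)
    lo, hi = potentials[0], potentials[-1]
    signal = np.zeros_like(potentials, dtype=float)
    for analyte in profile.analytes:
        c = conc_map[analyte.name]
        if c == 0.0:
            continue
        for idx, peak in enumerate(analyte.peaks):
            if not lo <= peak.center_potential <= hi:
                raise ValueError(
                    f"peak of {analyte.name} at {peak.center_potential} V lies "
                    f"outside the scan window [{lo}, {hi}] V"
                )
            mult = condition_multiplier(conditions, analyte.name, idx)
            height = (peak.sensitivity_m * c + peak.offset_b) * mult
            signal += height * gaussian_peak(potentials, peak.center_potential, peak.width)
    return signal


def generate_voltammogram(
    conc,
    profile: ElectrodeProfile,
    conditions: ConditionSet | None = None,
    noise: NoiseModel | None = None,
    grid: GridSpec | None = None,
) -> Voltammogram:
    """Simulate one sweep of a mixture on the given sensor.

    ``current(E) = background(E) + Σ peaks + white noise``; with
    ``white_sd = 0`` the result is deterministic, and an all-zero mixture
    returns the background alone.  The white-noise realization is fixed by
    ``noise.seed``.
    """
    conditions = conditions or ConditionSet()
    noise = noise or NoiseModel()
    grid = grid or GridSpec()
    potentials = grid.potentials()
    currents = background_current(potentials, noise)
    currents = currents + peak_signal(conc, profile, conditions, potentials)
    if noise.white_sd > 0:
        rng = np.random.default_rng(noise.seed)
        currents = currents + rng.normal(0.0, noise.white_sd, potentials.size)
    conc_map = _conc_mapping(conc, profile)
    meta = {"profile": profile.label, "conc_uM": conc_map, "seed": noise.seed}
    return Voltammogram(potentials, currents, meta)


# --------------------------------------------------------------------------
# Mixture designs
# --------------------------------------------------------------------------

@dataclass
class MixtureDesign:
    """Table of (sample_id, role, MOR/MET/UA concentration) rows."""

    table: pd.DataFrame

    _COLUMNS = ("sample_id", "role", "mor_uM", "met_uM", "ua_uM")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        self.table = self.table.loc[:, list(self._COLUMNS)].reset_index(drop=True)
        bad_roles = set(self.table["role"]) - {"train", "test"}
        if bad_roles:
            raise ValueError(f"invalid roles in design: {sorted(bad_roles)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")

    def _role_frame(self, role: str) -> pd.DataFrame:
        return self.table[self.table["role"] == role].reset_index(drop=True)

    @property
    def train(self) -> pd.DataFrame:
        return self._role_frame("train")

    @property
    def test(self) -> pd.DataFrame:
        return self._role_frame("test")

    def concentrations(self, role: str | None = None) -> np.ndarray:
        """(n, 3) concentration matrix in MOR, MET, UA order."""
        frame = self.table if role is None else self._role_frame(role)
        return frame[[DESIGN_COLUMNS[a] for a in ANALYTES]].to_numpy(dtype=float)

    def rows(self, role: str | None = None):
        """Yield (sample_id, {analyte: conc}) pairs."""
        frame = self.table if role is None else self._role_frame(role)
        for _, row in frame.iterrows():
            yield row["sample_id"], {a: float(row[DESIGN_COLUMNS[a]]) for a in ANALYTES}


def generate_design(
    n_train: int,
    n_test: int,
    profile: ElectrodeProfile,
    seed: int,
    method: str = "uniform",
) -> MixtureDesign:
    """Random mixture design spanning each analyte's linear range.

    ``method="uniform"`` draws i.i.d. uniform concentrations;
    ``method="lhs"`` uses a seeded Latin hypercube for better coverage.
    Reproducible: the same seed yields an identical table.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    ranges = np.array([profile.analyte(a).linear_range for a in ANALYTES])
    n = n_train + n_test
    if method == "uniform":
        rng = np.random.default_rng(seed)
        unit = rng.random((n, 3))
    elif method == "lhs":
        unit = qmc.LatinHypercube(d=3, seed=seed).random(n)
    else:
        raise ValueError(f"unknown design method {method!r}; use 'uniform' or 'lhs'")
    conc = ranges[:, 0] + unit * (ranges[:, 1] - ranges[:, 0])
    ids = [f"train{i + 1:02d}" for i in range(n_train)] + [
        f"test{i + 1:02d}" for i in range(n_test)
    ]
    roles = ["train"] * n_train + ["test"] * n_test
    table = pd.DataFrame(
        {
            "sample_id": ids,
            "role": roles,
            "mor_uM": conc[:, 0],
            "met_uM": conc[:, 1],
            "ua_uM": conc[:, 2],
        }
    )
    return MixtureDesign(table)
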