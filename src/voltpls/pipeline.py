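"""End-to-end experiment orchestration.

Ties the stages together — simulate a mixture design, process the sweeps
into features, fit univariate calibrations and the PLS model, validate,
run a standard-addition demonstration and an interference scan — under a
single seed, and collects everything into a JSON-serializable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .interference import (
    InterferenceConfig,
    demo_interferents,
    tolerance_ratio,
)
from .pls import (
    fit_pls,
    loo_rmsecv,
    predict,
    select_n_lv,
    validation_metrics,
)
from .processing import FilterSpec, build_feature_matrix, peak_height, subtract_blank, fft_denoise
from .quantify import StandardAdditionSeries, recovery_percent, rsd, standard_addition_estimate
from .simulate import (
    ANALYTES,
    ConditionSet,
    ElectrodeProfile,
    GridSpec,
    MixtureDesign,
    NoiseModel,
    Voltammogram,
    generate_design,
    generate_voltammogram,
    paper_profile,
)
from .univariate import CalibrationCurve, fit_calibration

__all__ = [
    "RunReport",
    "run_paper_emulation",
    "simulate_design_scans",
    "simulate_univariate_curve",
]

logger = logging.getLogger("voltpls")

_SEED_CAP = 2**31 - 1


def _seed_stream(seed: int):
    """Deterministic stream of sub-seeds derived from one master seed."""
    rng = np.random.default_rng(seed)
    while True:
        yield int(rng.integers(0, _SEED_CAP))


def simulate_design_scans(
    design: MixtureDesign,
    profile: ElectrodeProfile,
    conditions: ConditionSet,
    noise: NoiseModel,
    grid: GridSpec,
    seed: int,
) -> tuple[list[Voltammogram], Voltammogram]:
    """One sweep per design row plus a blank, each with its own sub-seed."""
    seeds = _seed_stream(seed)
    blank = generate_voltammogram(
        {a: 0.0 for a in profile.analyte_names},
        profile, conditions, dataclasses.replace(noise, seed=next(seeds)), grid,
    )
    blank.meta["sample_id"] = "blank"
    scans = []
    for sample_id, conc in design.rows():
        v = generate_voltammogram(
            conc, profile, conditions,
            dataclasses.replace(noise, seed=next(seeds)), grid,
        )
        v.meta["sample_id"] = sample_id
        scans.append(v)
    return scans, blank


def simulate_univariate_curve(
    analyte: str,
    peak_index: int,
    concentrations,
    profile: ElectrodeProfile,
    conditions: ConditionSet | None = None,
    noise: NoiseModel | None = None,
    grid: GridSpec | None = None,
    filter_spec: FilterSpec | None = None,
    n_blanks: int = 10,
    seed: int = 0,
) -> CalibrationCurve:
    """Single-analyte calibration series measured at the peak potential.

    Each standard is a separately seeded sweep; the response is the
    (optionally low-pass filtered) blank-subtracted current at the peak
    center.  Replicate blanks are measured the same way against a common
    reference blank.  With ``filter_spec=None`` and zero noise the refit
    reproduces the embedded calibration line exactly.
    """
    conditions = conditions or ConditionSet()
    noise = noise or NoiseModel()
    grid = grid or GridSpec()
    peak = profile.analyte(analyte).peaks[peak_index]
    seeds = _seed_stream(seed)

    def scan(c: float) -> Voltammogram:
        v = generate_voltammogram(
            {analyte: c}, profile, conditions,
            dataclasses.replace(noise, seed=next(seeds)), grid,
        )
        return fft_denoise(v, filter_spec) if filter_spec is not None else v

    reference = scan(0.0)
    responses = [
        peak_height(subtract_blank(scan(float(c)), reference), peak.center_potential)
        for c in concentrations
    ]
    blanks = [
        peak_height(subtract_blank(scan(0.0), reference), peak.center_potential)
        for _ in range(n_blanks)
    ]
    return CalibrationCurve(np.asarray(concentrations, float), np.asarray(responses),
                            np.asarray(blanks))


@dataclass
class RunReport:
    """Serializable record of one end-to-end run."""

    data: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.data, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunReport":
        return cls(json.loads(Path(path).read_text()))


def _log_parameters(config: RunConfig) -> None:
    for section, value in sorted(config.to_dict().items()):
        logger.info("config %s = %r", section, value)


def _univariate_stage(config, profile, seeds) -> dict:
    out = {}
    for analyte in profile.analytes:
        low, high = analyte.linear_range
        levels = np.linspace(low, high, 8)
        for idx in range(len(analyte.peaks)):
            curve = simulate_univariate_curve(
                analyte.name, idx, levels, profile,
                config.conditions, config.noise, config.grid,
                filter_spec=config.filter, seed=next(seeds),
            )
            label = (
                analyte.name if len(analyte.peaks) == 1
                else f"{analyte.name} peak {idx + 1}"
            )
            out[label] = fit_calibration(curve).to_dict()
    return out


def _standard_addition_stage(config, profile, model, blank, seeds) -> dict:
    """Spiked-sample demonstration: predict, extrapolate, recover."""
    base = {"MOR": 2.0, "MET": 1.5, "UA": 6.0}
    additions = np.array([0.0, 2.0, 4.0, 6.0])
    n_replicates = 5

    def predict_sample(conc, scan_seed) -> np.ndarray:
        v = generate_voltammogram(
            conc, profile, config.conditions,
            dataclasses.replace(config.noise, seed=scan_seed), config.grid,
        )
        v = fft_denoise(v, config.filter)
        row = subtract_blank(v, blank).currents
        return predict(model, row[None, :])[0]

    preds = np.array([
        predict_sample({a: base[a] + add for a in ANALYTES}, next(seeds))
        for add in additions
    ])
    replicate_preds = np.array([
        predict_sample(base, next(seeds)) for _ in range(n_replicates)
    ])
    out = {}
    for i, analyte in enumerate(ANALYTES):
        series = StandardAdditionSeries(additions, preds[:, i])
        estimate = standard_addition_estimate(series)
        found_before = float(preds[0, i])
        found_after = float(preds[2, i])
        out[analyte] = {
            "true_uM": base[analyte],
            "standard_addition_estimate_uM": estimate,
            "found_before_uM": found_before,
            "added_uM": float(additions[2]),
            "found_after_uM": found_after,
            "recovery_pct": recovery_percent(found_before, additions[2], found_after),
            "rsd_pct": rsd(replicate_preds[:, i]),
        }
    return out


def _interference_stage(config, profile, model) -> list[dict]:
    icfg = InterferenceConfig(profile, config.conditions, config.grid, config.filter)
    results = []
    for interferent in demo_interferents():
        for analyte in ANALYTES:
            res = tolerance_ratio(model, analyte, interferent, icfg)
            results.append(res.to_dict())
    return results


def run_paper_emulation(config: RunConfig) -> RunReport:
    """Full seeded pipeline: design → sweeps → features → calibrations →
    PLS validation → standard-addition and interference demonstrations."""
    _log_parameters(config)
    profile = paper_profile(config.profile)
    seeds = _seed_stream(config.seed)

    design = generate_design(
        config.design.n_train, config.design.n_test, profile,
        seed=next(seeds), method=config.design.method,
    )
    scans, blank = simulate_design_scans(
        design, profile, config.conditions, config.noise, config.grid, next(seeds)
    )
    features = build_feature_matrix(scans, config.filter, blank)
    id_to_row = {sid: i for i, sid in enumerate(features.sample_ids)}
    x_train = features.values[[id_to_row[s] for s in design.train["sample_id"]]]
    x_test = features.values[[id_to_row[s] for s in design.test["sample_id"]]]
    y_train = design.concentrations("train")
    y_test = design.concentrations("test")

    univariate = _univariate_stage(config, profile, seeds)

    curve = loo_rmsecv(x_train, y_train, config.pls.max_lv, target_names=ANALYTES)
    n_lv = config.pls.n_lv or select_n_lv(curve)
    model = fit_pls(x_train, y_train, n_lv, target_names=ANALYTES)
    report = validation_metrics(model, x_train, y_train, x_test, y_test, curve)

    blank_filtered = fft_denoise(blank, config.filter)
    standard_addition = _standard_addition_stage(
        config, profile, model, blank_filtered, seeds
    )
    interference = _interference_stage(config, profile, model)

    data = {
        "software": {"name": "voltpls", "version": __version__},
        "seed": config.seed,
        "parameters": config.to_dict(),
        "design": {
            "n_train": int(len(design.train)),
            "n_test": int(len(design.test)),
            "method": config.design.method,
        },
        "univariate": univariate,
        "pls": report.to_dict(),
        "standard_addition": standard_addition,
        "interference": interference,
        "units": {
            "concentration": "uM",
            "potential": "V",
            "current": "instrument units",
            "errors": "uM",
        },
    }
    return RunReport(data)
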