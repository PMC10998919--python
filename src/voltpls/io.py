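"""CSV readers/writers for voltammograms, designs and feature matrices.

All formats are plain text: one sweep per file with a ``potential_V,current``
header; mixture designs as ``sample_id,role,mor_uM,met_uM,ua_uM``; feature
matrices with a ``sample_id`` column followed by one column per grid point.
Floats are written with 17 significant digits so a write/read round trip is
exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .processing import FeatureMatrix
from .simulate import MixtureDesign, Voltammogram

__all__ = [
    "read_design_csv",
    "read_feature_csv",
    "read_voltammogram_csv",
    "write_design_csv",
    "write_feature_csv",
    "write_voltammogram_csv",
]

_FLOAT_FMT = "%.17g"
_SCAN_COLUMNS = ("potential_V", "current")


def write_voltammogram_csv(v: Voltammogram, path) -> None:
    frame = pd.DataFrame({"potential_V": v.potentials, "current": v.currents})
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_voltammogram_csv(path) -> Voltammogram:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    for col in _SCAN_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(frame) < 2:
        raise ValueError(f"{path}: a voltammogram needs at least two rows")
    potentials = frame["potential_V"].to_numpy(dtype=float)
    steps = np.diff(potentials)
    bad = np.flatnonzero(steps <= 0)
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(
            f"{path}: potential grid not strictly increasing at line {bad[0] + 3}"
        )
    return Voltammogram(
        potentials,
        frame["current"].to_numpy(dtype=float),
        {"sample_id": path.stem},
    )


def write_design_csv(design: MixtureDesign, path) -> None:
    design.table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_design_csv(path) -> MixtureDesign:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    return MixtureDesign(frame)


def write_feature_csv(features: FeatureMatrix, path) -> None:
    labels = [f"{p:.6g}" for p in features.column_grid]
    frame = pd.DataFrame(features.values, columns=labels)
    frame.insert(0, "sample_id", list(features.sample_ids))
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_csv(path) -> FeatureMatrix:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: missing column 'sample_id'")
    ids = tuple(str(s) for s in frame["sample_id"])
    data = frame.drop(columns="sample_id")
    grid = np.array([float(c) for c in data.columns])
    return FeatureMatrix(data.to_numpy(dtype=float), ids, grid)
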