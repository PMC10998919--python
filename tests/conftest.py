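import numpy as np
import pytest

import voltpls as vp


@pytest.fixture(scope="session")
def modified_profile():
    return vp.paper_profile("modified")


@pytest.fixture(scope="session")
def unmodified_profile():
    return vp.paper_profile("unmodified")


@pytest.fixture(scope="session")
def grid():
    return vp.GridSpec()


@pytest.fixture(scope="session")
def conditions():
    return vp.ConditionSet()


@pytest.fixture
def quiet_noise():
    """Drifting background, no white noise: deterministic sweeps."""
    return vp.NoiseModel(white_sd=0.0, drift_amplitude=2.0, seed=0)


@pytest.fixture(scope="session")
def trained_model(modified_profile, conditions, grid):
    """PLS model fitted on a noiseless 17/12 design (rank-3 signal)."""
    design = vp.generate_design(17, 12, modified_profile, seed=42)
    scans, blank = vp.simulate_design_scans(
        design, modified_profile, conditions,
        vp.NoiseModel(white_sd=0.0, drift_amplitude=2.0), grid, seed=7,
    )
    features = vp.build_feature_matrix(scans, vp.FilterSpec(), blank)
    idx = {s: i for i, s in enumerate(features.sample_ids)}
    x = features.values[[idx[s] for s in design.train["sample_id"]]]
    y = design.concentrations("train")
    return vp.fit_pls(x, y, 3, target_names=vp.ANALYTES)


@pytest.fixture(scope="session")
def interference_config(modified_profile, conditions, grid):
    return vp.InterferenceConfig(
        modified_profile, conditions, grid, vp.FilterSpec()
    )
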