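"""Shared fixtures: canonical synthetic ground truths used across the suite."""

import numpy as np
import pytest

from protstab import GroundTruth

# reference parameter sets for the free and inhibitor-bound enzyme
APO = {"dG0": 3.7, "m": 3.12}
HOLO = {"dG0": 15.33, "m": 4.96}
APO_ACTIVATION = {"dH": 20.0, "dS": 0.071, "dCp": 0.62}
HOLO_ACTIVATION = {"dH": 23.1, "dS": 0.071, "dCp": 1.00}


@pytest.fixture
def apo_isotherm_truth():
    return GroundTruth("isotherm", {
        **APO,
        "signal_native": 350.0,
        "signal_denatured": 355.0,
        "denaturant_grid": np.linspace(0.0, 4.5, 30),
    })


@pytest.fixture
def holo_isotherm_truth():
    return GroundTruth("isotherm", {
        **HOLO,
        "signal_native": 350.0,
        "signal_denatured": 355.0,
        "denaturant_grid": np.linspace(0.0, 5.5, 30),
    })


@pytest.fixture
def melt_truth():
    return GroundTruth("melt", {
        "tm": 58.0, "amplitude": 1.0, "slope": 2.0, "baseline": -1.0,
        "temperature_grid": np.linspace(25.0, 90.0, 66),
    })


@pytest.fixture
def eyring_truth():
    return GroundTruth("eyring_series", {
        **APO_ACTIVATION, "T0": 298.0,
        "temperature_grid": np.linspace(278.0, 303.0, 6),
    })


@pytest.fixture
def saxs_q_grid():
    return np.linspace(0.008, 0.30, 120)
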