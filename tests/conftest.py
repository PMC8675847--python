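import numpy as np
import pytest

from dectquant import (
    DualEnergyCalibration,
    PhantomSpec,
    ScanProtocol,
    SensitivityMatrix,
    build_phantom,
    forward_project,
    vial_label_volume,
)
from dectquant.synthetic import DEFAULT_PHANTOM_GRID

#: The five calibration-phantom vial concentrations, μg/ml.
VIAL_CONCS_UG = (250.0, 500.0, 1000.0, 1500.0, 2000.0)

#: The worked-example sensitivity system: e_w = 1 at both energies,
#: gold slopes 5 and 7 HU'·ml/mg, zero intercepts.
EXAMPLE_SENSITIVITY = SensitivityMatrix(
    e_au_low=5.0, e_au_high=7.0, intercept_low=0.0, intercept_high=0.0
)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(vial_concentrations=VIAL_CONCS_UG)


@pytest.fixture(scope="session")
def phantom_grid():
    return DEFAULT_PHANTOM_GRID


@pytest.fixture(scope="session")
def phantom_truth(phantom_spec, phantom_grid):
    return build_phantom(phantom_spec, phantom_grid)


@pytest.fixture(scope="session")
def vial_labels(phantom_spec, phantom_grid):
    return vial_label_volume(phantom_spec, phantom_grid)


@pytest.fixture(scope="session")
def noiseless_phantom_image(phantom_truth):
    protocol = ScanProtocol(noise_sd=0.0, seed=0)
    return forward_project(phantom_truth, protocol=protocol)


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_phantom_image, vial_labels):
    return DualEnergyCalibration.from_image(
        noiseless_phantom_image, vial_labels, VIAL_CONCS_UG
    ).fit()
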