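from pathlib import Path

import pytest

from bariatric_cea import ModelParameters, base_case_results, calibrate_parameters

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture()
def params() -> ModelParameters:
    """Uncalibrated base-case inputs."""
    return ModelParameters()


@pytest.fixture(scope="session")
def calibrated() -> ModelParameters:
    """Base-case inputs with the mortality link and baseline utility calibrated."""
    return calibrate_parameters()


@pytest.fixture(scope="session")
def base_results(calibrated):
    """Calibrated incremental outcomes at horizons 1..7."""
    return base_case_results(calibrated, range(1, 8))
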