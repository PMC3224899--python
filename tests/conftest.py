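import numpy as np
import pytest

from vtrial.model import ModelParameters
from vtrial.protocols import load_protocol
from vtrial.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters.default()


@pytest.fixture(scope="session")
def proto_a():
    return load_protocol("glucontrol_a")


@pytest.fixture(scope="session")
def proto_b():
    return load_protocol("glucontrol_b")


@pytest.fixture(scope="session")
def small_cohort(params):
    """Six synthetic patients treated with the intensive protocol for 48 h."""
    cfg = CohortConfig(n_patients=6, seed=7, protocol="glucontrol_a",
                       stay_h=48.0)
    records, truth, patients = generate_cohort(cfg, params=params)
    return cfg, records, truth, patients
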