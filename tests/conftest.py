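import numpy as np
import pytest

from dkisim import AcquisitionProtocol, NoiseModel, control_spec, emt_spec


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced grid for pipeline-level tests."""
    return AcquisitionProtocol(matrix_x=32, matrix_y=32, n_slices=3)


@pytest.fixture(scope="session")
def b_values(protocol):
    return np.asarray(protocol.b_values)


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(kind="none", sigma=0.0)


@pytest.fixture(scope="session")
def control():
    return control_spec()


@pytest.fixture(scope="session")
def emt():
    return emt_spec()
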