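import numpy as np
import pytest

from hsoed import make_circuit, make_input


@pytest.fixture(scope="session")
def unbuffered():
    return make_circuit("unbuffered")


@pytest.fixture(scope="session")
def buffered():
    return make_circuit("buffered")


@pytest.fixture(scope="session")
def step20():
    return make_input("step", 20.0)


@pytest.fixture(scope="session")
def coarse_grid():
    """Short, coarse time grid that keeps solver calls cheap."""
    return np.linspace(0.0, 600.0, 25)
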