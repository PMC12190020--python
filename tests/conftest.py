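import numpy as np
import pytest

from cuprackit.datasets import (
    load_solvent_screen,
    load_solvent_screen_frame,
    load_trolox_calibration,
)


@pytest.fixture(scope="session")
def screen_table():
    """The bundled seven-composition solvent-screen design."""
    return load_solvent_screen()


@pytest.fixture(scope="session")
def screen_frame():
    return load_solvent_screen_frame()


@pytest.fixture(scope="session")
def calibration_frame():
    """The bundled six-level triplicate Trolox calibration."""
    return load_trolox_calibration()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
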