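import math

import pytest

from armstat import ArmGeometry, RunConfig, fixture_grid


@pytest.fixture(scope="session")
def geom() -> ArmGeometry:
    """Canonical equal-length geometry (R = 1)."""
    return ArmGeometry()


@pytest.fixture(scope="session")
def grid():
    """The canonical 10x10 joint-angle grid with pi/10 steps."""
    return fixture_grid(RunConfig())


@pytest.fixture(scope="session")
def pi() -> float:
    return math.pi
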