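import pytest

import copolyscan as cps


@pytest.fixture(scope="session")
def box5():
    return cps.SimulationBox(Lx=5, Ly=5, Lz=5, z_min=-2)


@pytest.fixture(scope="session")
def thin_membrane(box5):
    """A 1-layer tail / 1-layer head membrane that fits a 5^3 box."""
    return cps.planar_membrane(box5, tail_thickness=1, head_thickness=1)


@pytest.fixture(scope="session")
def membrane():
    """The default bilayer: 6 tail layers + 2 head layers per side in 32^3."""
    return cps.planar_membrane()


@pytest.fixture(scope="session")
def micelle():
    """The default core-shell micelle: core radius 13, shell 3, in 32^3."""
    return cps.spherical_micelle()
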