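import math

import numpy as np
import pytest

from crnkit import ChemSystem, Geometry
from crnkit.fixtures import h2_species, h_library


def ideal_ethane() -> Geometry:
    """Staggered ethane, r_CC = 1.54 A, r_CH = 1.09 A, tetrahedral angles."""
    rcc, rch = 1.54, 1.09
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([0.0, 0.0, rcc])
    coords = [c1, c2]
    ang = math.radians(109.5)
    for base, sign, off in [(c1, -1, 0.0), (c2, 1, 60.0)]:
        for k in range(3):
            phi = math.radians(off + 120.0 * k)
            v = np.array(
                [
                    math.sin(ang) * math.cos(phi),
                    math.sin(ang) * math.sin(phi),
                    sign * math.cos(ang),
                ]
            )
            coords.append(base + rch * v)
    return Geometry(["C", "C", "H", "H", "H", "H", "H", "H"], np.array(coords))


@pytest.fixture
def ethane_geometry() -> Geometry:
    return ideal_ethane()


@pytest.fixture
def h2_system() -> ChemSystem:
    return ChemSystem.from_species([h2_species()])


@pytest.fixture
def hh_library():
    return h_library()
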