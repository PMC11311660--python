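import numpy as np
import pytest

from noesypop.geometry import AtomRecord, ConformerGeometry
from noesypop.relaxation import SpectrometerContext


@pytest.fixture
def rng():
    return np.random.default_rng(20240728)


@pytest.fixture
def ctx():
    """500.17 MHz field, 50 ps correlation time (extreme-narrowing side)."""
    return SpectrometerContext(tau_c=50e-12)


def make_geometry(cid, atom_specs):
    """atom_specs: iterable of (label, element, (x, y, z))."""
    return ConformerGeometry(
        conformer_id=cid,
        atoms=[
            AtomRecord(label, element, np.asarray(pos, dtype=float))
            for label, element, pos in atom_specs
        ],
    )


@pytest.fixture
def butane_like():
    """Four-atom chain with a -60 degree torsion (gauche)."""
    import math

    phi = math.radians(-60.0)
    return make_geometry(
        "butane",
        [
            ("C1", "C", (1.0, 0.0, -1.0)),
            ("C2", "C", (0.0, 0.0, 0.0)),
            ("C3", "C", (0.0, 0.0, 1.5)),
            ("C4", "C", (math.cos(phi), math.sin(phi), 2.5)),
        ],
    )


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
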