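import numpy as np
import pytest

from memgeom import GeometrySpec, PoreSpec, TransitionParams
from memgeom.synthetic import make_pore_bundle, make_tm_helix


@pytest.fixture(scope="session")
def default_params():
    return TransitionParams()


@pytest.fixture(scope="session")
def tm_helix():
    """31-residue ideal TM helix (CA trace) with its spanfile."""
    return make_tm_helix(n_res=31, seed=7)


@pytest.fixture(scope="session")
def pore_bundle():
    """4-helix bundle around a 5 Å pore: (structure, pore, spanfile)."""
    return make_pore_bundle(n_helices=4, pore_radius=5.0, seed=11)


@pytest.fixture(scope="session")
def all_geometries():
    return {
        "slab": GeometrySpec.slab(),
        "ellipsoid": GeometrySpec.ellipsoid(30.0),
        "micelle": GeometrySpec.micelle(),
        "vesicle": GeometrySpec.vesicle(120.0),
        "double_vesicle": GeometrySpec.double_vesicle(1000.0, 40.0),
    }


def finite_difference_gradient(field, pos, h=1e-4):
    """Central-difference gradient of a batched scalar field, shape (N, 3)."""
    pos = np.atleast_2d(pos)
    grad = np.zeros_like(pos)
    for axis in range(3):
        step = np.zeros(3)
        step[axis] = h
        grad[:, axis] = (field(pos + step) - field(pos - step)) / (2.0 * h)
    return grad
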