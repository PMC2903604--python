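import numpy as np
import pytest

from bonesim.fe_core import DensityField, MeshSpec, build_mesh


@pytest.fixture(scope="session")
def small_mesh():
    """8x8 remodelable elements with the default 2-element frame."""
    return build_mesh(MeshSpec(nx=8, ny=8, width_mm=0.2, height_mm=0.2))


@pytest.fixture(scope="session")
def default_mesh():
    return build_mesh(MeshSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_density(mesh, rng, lo=0.05, hi=1.0):
    m = DensityField.uniform(mesh, 1.0).m
    m[mesh.remodelable] = rng.uniform(lo, hi, mesh.n_remodelable)
    return DensityField(m)
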