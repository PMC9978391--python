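import numpy as np
import pytest

from dwisr.io import DWIVolume
from dwisr.phantom import (
    PhantomSpec,
    TensorCompartment,
    default_gradient_table,
    generate_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def gradient_table():
    """Desk-scale four-shell table: 1 x b=0 + 6 directions x 3 shells."""
    return default_gradient_table()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small crossing-fiber phantom without noise (session-cached)."""
    spec = PhantomSpec(grid_shape=(24, 24, 12), noise_sigma=0.0, seed=0)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def dense_gradient_table():
    """Four shells sampled along 21 hemisphere directions (icosphere level 1)."""
    from dwisr.gqi import tessellate_sphere

    dirs = tessellate_sphere(1).directions
    return default_gradient_table(directions=dirs)


def single_voxel_volume(bvals, bvecs, compartments, s0=100.0):
    """1x1x1 DWIVolume with the analytic multi-tensor signal."""
    from dwisr.phantom import simulate_voxel_signal

    sig = np.array(
        [simulate_voxel_signal(compartments, s0, b, g) for b, g in zip(bvals, bvecs)]
    )
    return DWIVolume(
        data=sig.reshape(1, 1, 1, -1),
        voxel_size=(1.0, 1.0, 1.0),
        bvals=bvals,
        bvecs=bvecs,
    )


@pytest.fixture
def make_single_voxel():
    return single_voxel_volume


@pytest.fixture
def fiber_compartment():
    return [TensorCompartment((1.0, 0.0, 0.0))]
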