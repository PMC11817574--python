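import numpy as np
import pytest

import petadc as pa


def make_grid(values, spacing=(1.0, 1.0, 1.0), units="suv"):
    return pa.VoxelGrid(np.asarray(values, dtype=float), spacing, units=units)


def ramp_grid(shape=(3, 3, 1), spacing=(1.0, 1.0, 1.0), units="suv"):
    """Volume whose voxel values are 1..N in C order."""
    n = int(np.prod(shape))
    return make_grid(np.arange(1, n + 1, dtype=float).reshape(shape), spacing, units)


def full_roi(shape, zone="PZ"):
    return pa.ROIMask(np.ones(shape, dtype=bool), zone=zone)


@pytest.fixture(scope="session")
def default_spec():
    return pa.PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_subject():
    spec = pa.PhantomSpec.noiseless()
    return spec, pa.generate_subject(spec, 0.8, 16.75, seed=11)


@pytest.fixture(scope="session")
def default_subject(default_spec):
    return pa.generate_subject(default_spec, 0.8, 12.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject compact cohort with all three PET methods."""
    spec = pa.PhantomSpec.compact()
    return pa.generate_cohort(spec, n_subjects=6, n_pz=4, coupling_rho=-0.5, seed=3)
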