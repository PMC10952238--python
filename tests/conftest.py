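"""Shared fixtures: small phantom instances reused across the suite.

Everything is generated at run time from fixed seeds; heavy objects are
session-scoped so expensive stages (k-space simulation, reconstructions)
run once.
"""

import numpy as np
import pytest

from lrmcperf.phantom import PhantomSpec, make_phantom, sample_kspace


@pytest.fixture(scope="session")
def desk_spec():
    """The reduced study instance: 64 matrix, 30 frames, 4 coils, 27 spokes."""
    return PhantomSpec.desk(seed=1)


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return make_phantom(desk_spec)


@pytest.fixture(scope="session")
def desk_kspace(desk_phantom):
    return sample_kspace(desk_phantom)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Smallest legal phantom for fast structural checks."""
    spec = PhantomSpec(matrix_size=32, n_frames=8, n_coils=2,
                       spokes_per_frame=13, samples_per_spoke=64,
                       motion_amplitude_px=2.0, resp_drift_px=0.0, seed=4)
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
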