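"""Shared fixtures: cached simulator bundles and assembled primary maps.

Scene construction and rendering are deterministic, so expensive bundles are
built once per session and shared read-only across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from smartscan.engine import AcquisitionLog, _acquire_frame
from smartscan.fixtures import make_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _frame(bundle, t=0):
    return _acquire_frame(
        bundle.backend(), bundle.grid, bundle.channels, bundle.n_z_primary, t, 0, AcquisitionLog()
    )


@pytest.fixture(scope="session")
def metaphase_bundle():
    return make_fixture("metaphase", seed=1)


@pytest.fixture(scope="session")
def metaphase_maps(metaphase_bundle):
    return _frame(metaphase_bundle)


@pytest.fixture(scope="session")
def fish_bundle():
    return make_fixture("fish", seed=1)


@pytest.fixture(scope="session")
def fish_maps(fish_bundle):
    return _frame(fish_bundle)


@pytest.fixture(scope="session")
def micropattern_bundle():
    return make_fixture("micropattern", seed=1)


@pytest.fixture(scope="session")
def micropattern_maps(micropattern_bundle):
    return _frame(micropattern_bundle)
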