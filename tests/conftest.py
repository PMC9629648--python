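"""Shared fixtures: small synthetic systems built once per session."""

import numpy as np
import pytest

from hopfpert.connectome import edr_kernel, euclidean_distances
from hopfpert.synthetic import (
    SyntheticSpec,
    make_coupling,
    make_parcellation,
    make_pseudo_empirical,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def parc(spec):
    return make_parcellation(spec)


@pytest.fixture(scope="session")
def coupling(spec, parc):
    return make_coupling(spec, parc)


@pytest.fixture(scope="session")
def dist(parc):
    return euclidean_distances(parc)


@pytest.fixture(scope="session")
def edr_weights(spec, dist):
    return edr_kernel(dist, spec.lambda_decay)


@pytest.fixture(scope="session")
def omega(spec):
    return spec.draw_omega(np.random.default_rng(5))


@pytest.fixture(scope="session")
def small_pseudo(parc, coupling):
    """Tiny pseudo-empirical cohort for fitting tests."""
    small = SyntheticSpec(seed=1, n_subjects=3, n_volumes=150)
    return make_pseudo_empirical(small, parc, coupling)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
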