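"""Shared fixtures: coarse phantoms for unit tests, one full study run.

The full five-run study (both phantom shapes, default mesh densities) is
computed once per session and shared between the end-to-end sanity tests
and the acceptance tests; the coarse phantoms keep forward-solver and
Jacobian tests in the seconds range.
"""

import numpy as np
import pytest

from deitbone import forward, phantom, pipeline


@pytest.fixture(scope="session")
def coarse_cylinder():
    """Small (~11k element) concentric cylinder phantom."""
    return phantom.build_phantom("cylinder", mesh_density=0.016)


@pytest.fixture(scope="session")
def protocol():
    return forward.build_protocol()


@pytest.fixture(scope="session")
def coarse_system(coarse_cylinder):
    """Factorized CEM system for the homogeneous boneless cylinder."""
    sigma0 = phantom.make_boneless(coarse_cylinder, phantom.CFG1_HOMOGENEOUS)
    return forward.CEMSystem(coarse_cylinder, sigma0.sigma)


@pytest.fixture(scope="session")
def study_results():
    """The five phantom/configuration runs at default study conditions."""
    return pipeline.run_study(pipeline.PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
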