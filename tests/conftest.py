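"""Shared fixtures: reference parameters and reusable simulated sessions.

Expensive simulations are session-scoped so several tests can share them.
"""

import numpy as np
import pytest

import hiertask as ht

REFERENCE_OMEGA = 0.92


@pytest.fixture(scope="session")
def tree():
    return ht.build_tree()


@pytest.fixture(scope="session")
def det_params():
    return ht.DetectionParams()


@pytest.fixture(scope="session")
def evid(det_params):
    return det_params.evidence


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def heuristic_log(det_params):
    """A moderately sized heuristic-agent session shared across tests."""
    return ht.run_heuristic_agent(
        ht.HeuristicParams(REFERENCE_OMEGA, det_params), 3000,
        np.random.default_rng(777))


@pytest.fixture(scope="session")
def detection_queries(det_params):
    """Query table simulated under the detection model."""
    return ht.generate_query_dataset(det_params, 20000,
                                     np.random.default_rng(2024))
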