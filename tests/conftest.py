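"""Shared fixtures: parameter sets and a lazy cache of protocol simulations.

Full protocol-A simulations take a couple of seconds each; tests that need
them share one cached run per (tissue, substrate, protocol) so the suite
stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitoresp import (
    ThermoContext,
    default_catalog,
    load_tissue_parameters,
)
from mitoresp.protocols import protocol_A, protocol_B, run_schedule

SIM_RTOL = 1.0e-7
SIM_ATOL = 1.0e-9


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def heart():
    return load_tissue_parameters("heart")


@pytest.fixture(scope="session")
def cortex():
    return load_tissue_parameters("cortex")


@pytest.fixture(scope="session")
def om():
    return load_tissue_parameters("om")


@pytest.fixture(scope="session")
def tissues(heart, cortex, om):
    return {"heart": heart, "cortex": cortex, "om": om}


@pytest.fixture(scope="session")
def sim_cache(tissues):
    """Lazy cache of protocol simulations keyed (tissue, substrate, protocol)."""
    cache: dict[tuple[str, str, str], object] = {}

    def get(tissue: str, substrate: str, protocol: str = "A"):
        key = (tissue, substrate, protocol)
        if key not in cache:
            sched = (
                protocol_A(tissue, substrate)
                if protocol == "A"
                else protocol_B(tissue, substrate)
            )
            cache[key] = run_schedule(
                tissues[tissue], sched, rtol=SIM_RTOL, atol=SIM_ATOL
            )
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(20230725)


def random_positive_state(rng, scale=1.0):
    """A random admissible state vector (non-negative, pools arbitrary)."""
    from mitoresp.states import IDX, N_STATES

    y = rng.uniform(0.01, 5.0, N_STATES) * scale
    y[IDX["dpsi"]] = rng.uniform(60.0, 200.0)
    y[IDX["O2_e"]] = rng.uniform(0.05, 0.4)
    return y
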