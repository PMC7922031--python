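"""Shared fixtures.

Expensive multi-day simulations are session-scoped and reused across tests;
they run at relaxed solver tolerances that still keep the checked properties
far inside their asserted bounds.
"""

import numpy as np
import pytest

from pbpkddi import (
    DoseEvent,
    StudyProtocol,
    carbamazepine_epoxide_model,
    carbamazepine_model,
    reference_individual,
    simulate_study,
)
from pbpkddi.engine.system import BoundDose, SolverConfig, build_system, integrate

CBZ = "carbamazepine"
CBZE = "carbamazepine-10,11-epoxide"


@pytest.fixture(scope="session")
def individual():
    return reference_individual()


@pytest.fixture()
def cbz():
    return carbamazepine_model()


@pytest.fixture()
def cbze():
    return carbamazepine_epoxide_model()


@pytest.fixture(scope="session")
def coarse_cfg():
    return SolverConfig(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def single_dose_result(coarse_cfg):
    """400 mg oral solution, 96 h observation, all observables."""
    protocol = StudyProtocol(
        events=[DoseEvent(CBZ, 400.0, 0.0, "solution")],
        sampling_times_h=np.arange(0.5, 96.1, 0.5).tolist(),
        analytes=[
            (CBZ, "plasma"),
            (CBZ, "saliva"),
            (CBZ, "urine_fe"),
            (CBZE, "plasma"),
        ],
    )
    return simulate_study(protocol, config=coarse_cfg)


@pytest.fixture(scope="session")
def tid14(individual, coarse_cfg):
    """Raw trajectory of 400 mg three-times-daily over 14 days."""
    doses = [
        BoundDose(CBZ, time_min=8 * 60.0 * i, amount_mg=400.0)
        for i in range(3 * 14)
    ]
    system = build_system(
        individual,
        [carbamazepine_model(), carbamazepine_epoxide_model()],
        doses,
        coarse_cfg,
    )
    grid = np.linspace(0.0, 14 * 24 * 60.0, 300)
    traj = integrate(system, grid)
    return system, grid, traj
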