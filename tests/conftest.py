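import numpy as np
import pytest

from hetnma import (
    NetworkDataset,
    SimulationDesign,
    Treatment,
    TreatmentClass,
    prostate_fixture,
    sigma_common,
    simulate_network,
)


@pytest.fixture(scope="session")
def prostate():
    return prostate_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def three_treatment_sim():
    """A small simulated 3-treatment network with known truth."""
    treatments = [
        Treatment(0, "A", TreatmentClass.CONTROL),
        Treatment(1, "B", TreatmentClass.NONPHARMACOLOGICAL),
        Treatment(2, "C", TreatmentClass.NONPHARMACOLOGICAL),
    ]
    design = SimulationDesign(
        treatments=treatments,
        study_arms=[[0, 1], [0, 2], [1, 2], [0, 1, 2], [0, 1], [0, 2]],
        d=np.array([0.4, -0.2]),
        Sigma=sigma_common(0.04, 2),
        n_per_arm=200,
    )
    return simulate_network(design, seed=7)
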