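import numpy as np
import pytest

from ferrokin.compartment_model import (
    build_topology,
    diet_parameters,
    rate_matrix,
)
from ferrokin.observation_processing import dataset_from_trajectory
from ferrokin.synthetic_data import StudyDesign, generate_dataset


@pytest.fixture(scope="session")
def topology():
    return build_topology()


@pytest.fixture(scope="session")
def adequate():
    return diet_parameters("adequate")


@pytest.fixture(scope="session")
def deficient():
    return diet_parameters("deficient")


@pytest.fixture(scope="session")
def loaded():
    return diet_parameters("loaded")


@pytest.fixture(scope="session")
def dense_noisefree_dataset(adequate):
    """Noise-free dense dataset from the adequate best fit, SD set to 1.

    Not renormalized: the generating model's own body-loss curve is kept so
    that parameter recovery is exact."""
    timepoints = tuple(np.geomspace(0.5, 28.0, 40))
    design = StudyDesign(timepoints=timepoints, n_animals=1, cv=0.0,
                         dose_jitter=0.0)
    dataset, _ = generate_dataset(adequate.best_fit, design, normalize=False)
    df = dataset.observations.copy()
    df["sd_pct_dose"] = 1.0
    from dataclasses import replace
    return replace(dataset, observations=df)


@pytest.fixture(scope="session")
def noisy_dataset(adequate):
    """Default study design (8 timepoints, n=5, 30% CV), normalized."""
    dataset, _ = generate_dataset(adequate.best_fit, StudyDesign(seed=3))
    return dataset


def rk4_trajectory(topology, rates, times, step=1e-3):
    """Independent fixed-step RK4 oracle for the linear tracer system."""
    A = rate_matrix(topology, rates)
    x = np.zeros(len(topology.compartments))
    x[topology.index(topology.central)] = 100.0
    out = np.empty((len(times), len(x)))
    t = 0.0
    for i, target in enumerate(times):
        while t < target - 1e-12:
            h = min(step, target - t)
            k1 = A @ x
            k2 = A @ (x + h / 2 * k1)
            k3 = A @ (x + h / 2 * k2)
            k4 = A @ (x + h * k3)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i] = x
    return out


@pytest.fixture(scope="session")
def rk4_oracle():
    return rk4_trajectory
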