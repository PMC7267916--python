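"""Shared fixtures: small synthetic spaces and cohorts.

Everything is generated in-process with fixed seeds; session scope keeps
the suite fast since cohort generation and feature extraction dominate.
"""

import warnings

import numpy as np
import pytest

from resttask.cohort import make_cohort
from resttask.space import make_space

# mixture fits on small maps legitimately trip the small-sample warning
warnings.filterwarnings("ignore", message="fewer than 1000 values")


SMALL = dict(
    n_vertices_per_hemisphere=150,
    n_subcortical_structures=6,
    k_networks=4,
    n_runs=4,
    n_timepoints=100,
    n_parcels_per_hemisphere=10,
)


@pytest.fixture(scope="session")
def space():
    return make_space(150, 6, seed=1)


@pytest.fixture(scope="session")
def noisy_cohort():
    """8 subjects with inter-subject variability and time-series noise."""
    return make_cohort(8, seed=11, contrasts={"lin": "linear"}, **SMALL)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """10 identical, noise-free subjects with a linear task link."""
    return make_cohort(
        10,
        seed=5,
        subject_variability=0.0,
        ts_noise_sd=0.0,
        task_noise_sd=0.0,
        contrasts={"lin": "linear"},
        **{**SMALL, "n_runs": 1, "n_timepoints": 20},
    )


@pytest.fixture(scope="session")
def nonlinear_cohort():
    """Subjects whose task maps come from a saturating nonlinear link."""
    return make_cohort(
        50,
        seed=2,
        task_noise_sd=0.1,
        ts_noise_sd=0.0,
        contrasts={"nl": "nonlinear"},
        **{**SMALL, "n_runs": 1, "n_timepoints": 10},
    )


def corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation between two map stacks."""
    az = (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)
    bz = (b - b.mean(1, keepdims=True)) / b.std(1, keepdims=True)
    return az @ bz.T / a.shape[1]
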