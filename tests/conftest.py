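import numpy as np
import pandas as pd
import pytest

from reactivepdl1 import SimulationParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return SimulationParams()


@pytest.fixture
def reactive_params():
    """Pure reactive regime: no constitutive minority, single CNV state."""
    return SimulationParams(frac_constitutive=0.0, frac_amp=0.0, frac_del=0.0)


@pytest.fixture
def small_cohort(default_params):
    return generate_cohort(default_params.with_(n_samples=200, seed=7))


@pytest.fixture
def random_expression(rng):
    """Seeded 10x10 expression matrix with barcode-free sample ids."""
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{j}" for j in range(10)]
    return pd.DataFrame(rng.normal(size=(10, 10)), index=genes,
                        columns=samples)


@pytest.fixture
def survival_frame():
    """Six subjects, distinct event times, binary covariate."""
    clinical = pd.DataFrame({
        "sample_id": [f"P{i}" for i in range(6)],
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 1, 1, 1, 1],
        "cohort": "c",
    })
    covariate = pd.Series([1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
                          index=clinical["sample_id"], name="x")
    return clinical, covariate
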