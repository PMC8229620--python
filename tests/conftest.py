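import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import thiolkin as tk

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: Observed SH (% of initial) for the untreated control at 12 °C, days 0-6.
CONTROL_12C_DAYS = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0])
CONTROL_12C_SH = np.array([100.0, 93.63, 82.86, 66.33, 52.72, 24.81])


@pytest.fixture(scope="session")
def control_holdout_series():
    return CONTROL_12C_DAYS.copy(), CONTROL_12C_SH.copy()


@pytest.fixture(scope="session")
def table1_rates():
    return tk.load_fixture("table1_rates")


@pytest.fixture(scope="session")
def table1_params():
    return tk.load_fixture("table1_params")


@pytest.fixture(scope="session")
def table4():
    return tk.load_fixture("table4_predicted")


@pytest.fixture(scope="session")
def fixture_models(table1_params):
    arrhenius, loglogistic = tk.models_from_table1(table1_params)
    return arrhenius, loglogistic


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Full study design, zero replicate noise: every fit should be exact."""
    return tk.generate(tk.SyntheticConfig(seed=0, noise_sd=0.0, replicates=1))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Full study design with the default 2 % replicate noise."""
    return tk.generate(tk.SyntheticConfig(seed=42, noise_sd=2.0))


def make_dataset(rows):
    """Build a KineticDataset from (treatment, temp, time, replicate, sh) tuples."""
    frame = pd.DataFrame(
        rows, columns=["treatment", "temperature_C", "time_d", "replicate", "sh_percent"]
    )
    return tk.KineticDataset(frame)
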