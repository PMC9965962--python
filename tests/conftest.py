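import numpy as np
import pandas as pd
import pytest

from paee.synthetic import SimulationConfig, generate_participants


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but complete synthetic study configuration."""
    return SimulationConfig(seed=7, n_boys=6, n_girls=6)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = generate_participants(small_config)
    return cohort, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def regression_dataset() -> pd.DataFrame:
    """A well-specified linear dataset: paee = 0.001*cpm - 0.112 + noise."""
    gen = np.random.default_rng(11)
    n = 200
    cpm = np.clip(gen.normal(400, 170, n), 5, None)
    frame = pd.DataFrame(
        {
            "cpm": cpm,
            "sex_code": gen.integers(0, 2, n),
            "age": gen.normal(12, 0.7, n),
            "weight": gen.normal(35, 7, n),
            "height": gen.normal(1.45, 0.1, n),
        }
    )
    frame["bmi"] = frame.weight / frame.height**2
    frame["ffm"] = frame.weight * 0.73
    frame["fm"] = frame.weight * 0.27
    frame["paee"] = 0.001 * cpm - 0.112 + gen.normal(0, 0.13, n)
    return frame
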