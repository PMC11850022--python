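import numpy as np
import pytest

import catstep as cs


@pytest.fixture(scope="session")
def design_ca5():
    return cs.build_design("EXP1_3", ca_index=5)


@pytest.fixture(scope="session")
def exp4_design():
    return cs.build_design("EXP4")


@pytest.fixture(scope="session")
def small_cohort():
    """A small training/transfer cohort reused across analysis tests."""
    return cs.simulate_cohort(
        cs.default_cohort_config("EXP1", n_participants=10, seed=42)
    )


@pytest.fixture(scope="session")
def exp4_cohort():
    """A small five-condition control-task cohort."""
    return cs.simulate_cohort(
        cs.default_cohort_config("EXP4", n_participants=6, seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
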