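import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from synpair.sbi import TrainingSet, build_training_set, train_posterior
from synpair.simulator import SimulationConfig
from synpair.summary import TEConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ----------------------------------------------------------------------
# shared, expensive SBI fixture (used by the posterior-recovery and
# condition-shift acceptance checks).  Scale is reduced relative to the
# full study (training attempts and simulation length) to keep the whole
# suite inside a desk-scale run; thresholds are untouched.
# ----------------------------------------------------------------------

SBI_SIM_CONFIG = SimulationConfig(duration=4000.0)
SBI_TE_CONFIG = TEConfig(n_perm=100)
SBI_N_TRAIN = 1000
SBI_N_HELD = 240


@pytest.fixture(scope="session")
def sbi_training_set() -> TrainingSet:
    return build_training_set(SBI_N_TRAIN, SBI_SIM_CONFIG, seed=101,
                              te_config=SBI_TE_CONFIG)


@pytest.fixture(scope="session")
def sbi_held_out() -> TrainingSet:
    """Independent simulated observations for coverage / calibration."""
    return build_training_set(SBI_N_HELD, SBI_SIM_CONFIG, seed=202,
                              te_config=SBI_TE_CONFIG)


@pytest.fixture(scope="session")
def sbi_posterior(sbi_training_set):
    return train_posterior(sbi_training_set, min_valid=300, random_state=7)
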