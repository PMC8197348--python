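import numpy as np
import pytest

from eegcbf.pipeline import build_feature_table
from eegcbf.synth import GeneratorConfig, simulate_cohort

#: number of epochs per animal in the published cohort (group 0, group 1)
TABLE2_COUNTS = {
    "animal_1": (0, 15),
    "animal_2": (40, 1),
    "animal_3": (0, 28),
    "animal_4": (0, 12),
    "animal_5": (44, 1),
    "animal_6": (0, 14),
    "animal_7": (2, 35),
    "animal_8": (33, 0),
}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def feature_table(cohort):
    return build_feature_table(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast two-class cohort with shortened stage durations."""
    cfg = GeneratorConfig(
        seed=7,
        n_animals=3,
        baseline_duration_s=20.0,
        untreated_vf_duration_s=12.0,
        block_duration_s=15.0,
        monitoring_duration_s=10.0,
        force_non_rosc=True,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    # the shortened blocks still exceed the 10-s flow-averaging window
    return build_feature_table(small_cohort)
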