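import numpy as np
import pytest

from iscee.data_model import SubjectProfile
from iscee.presets import all_preset_feature_names
from iscee.synthetic import SimConfig, simulate_cohort, simulate_feature_table

#: union of every feature used by the classifier or any shipped EE preset;
#: restricting the bank to these keeps cohort-scale fixtures fast.
PRESET_FEATURES = sorted(all_preset_feature_names())


@pytest.fixture(scope="session")
def reference_subject():
    return SubjectProfile(id="ref", age=30, sex="male", weight=70, height=1.75)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two subjects, two activities, full signals kept — for I/O round-trips."""
    cfg = SimConfig(
        n_subjects=2, seed=11, fs=25.0, windows_per_activity=2,
        activities={"rest": ("sedentary", 0.9, 0.2),
                    "walking_4kmh": ("walking", 4.0, 0.9)},
        dropout_rate=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_table():
    """Feature table of a mid-size cohort (8 subjects, preset features only)."""
    cfg = SimConfig(n_subjects=8, seed=1, fs=25.0)
    table, info = simulate_feature_table(cfg, features=PRESET_FEATURES)
    return table, info


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
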