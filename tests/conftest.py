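import logging

import numpy as np
import pytest

from gaitrecover.feature_construction import FusionConfig
from gaitrecover.segmentation import segment_cohort
from gaitrecover.synthetic_cohort import (
    SubjectProfile,
    generate_cohort,
    generate_trial,
)

# unaffected-side exclusions and tie-break warnings are routine in tests
logging.getLogger("gaitrecover").setLevel(logging.ERROR)


def make_profile(
    subject_id="pat01",
    group="patient",
    affected_side="left",
    severity=0.5,
    timepoint="w6",
    cadence_hz=1.8,
):
    if group == "control":
        return SubjectProfile(
            subject_id, "control", "none", {"control_single": 0.0}, cadence_hz,
            stairs_capable={"control_single": True},
        )
    return SubjectProfile(
        subject_id, "patient", affected_side, {timepoint: severity}, cadence_hz,
        stairs_capable={timepoint: True},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """4 controls + 4 patients, walking only, strong signal, no dropouts."""
    return generate_cohort(
        4, 4, 2.0, 1.0, seed=11, activities=("walk",), dropouts=False
    )


@pytest.fixture(scope="session")
def small_strides(small_cohort):
    return segment_cohort(small_cohort.trials)


@pytest.fixture()
def walk_trial():
    profile = make_profile(severity=0.5)
    return generate_trial(profile, "walk", "w6", n_cycles=8, seed=5)


@pytest.fixture()
def stairs_trial():
    profile = make_profile(severity=0.5)
    return generate_trial(profile, "stairs_up", "w6", n_cycles=8, seed=5)


@pytest.fixture()
def fusion_config():
    return FusionConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
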