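"""Shared fixtures.

The expensive default study (5 subjects x 2 objects x 12 transports x
3 repetitions) is generated once per session and shared by the
event-detection and end-to-end tests; small studies are used
everywhere else.
"""

import numpy as np
import pytest

from wristkin import (
    ArmModel,
    StudyDesign,
    center_by_subject,
    detect_events,
    generate_study,
    preprocess_study,
)
from wristkin.kinematics import extract_joint_angles


@pytest.fixture(scope="session")
def arm_model():
    return ArmModel()


@pytest.fixture(scope="session")
def tiny_design():
    """1 subject, 1 object, 2 slots -> 2 transports x 3 reps = 6 trials."""
    return StudyDesign(n_subjects=1, objects=("cylinder",), slots=("DL", "UR"))


@pytest.fixture(scope="session")
def noise_free_design():
    return StudyDesign(
        n_subjects=1, objects=("cylinder", "sphere"), slots=("DL", "UR"),
        pos_noise_cm=0.0, angle_noise_deg=0.0, timing_jitter=0.0, repetition_noise_deg=0.0, path_noise_deg=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_study(noise_free_design):
    return generate_study(noise_free_design, 7)


@pytest.fixture(scope="session")
def small_study():
    """2 subjects x 2 objects x 2 slots, default noise: 24 trials."""
    design = StudyDesign(n_subjects=2, slots=("DL", "UR"))
    return generate_study(design, 11)


@pytest.fixture(scope="session")
def small_centered(small_study):
    nts = preprocess_study([extract_joint_angles(tr) for tr in small_study])
    detect_events(nts)
    cen, _ = center_by_subject(nts)
    return cen


@pytest.fixture(scope="session")
def default_study():
    """The full default study (360 trials)."""
    return generate_study(StudyDesign(), 42)


@pytest.fixture(scope="session")
def default_centered(default_study):
    """Default study through the full preprocessing chain."""
    nts = preprocess_study([extract_joint_angles(tr) for tr in default_study])
    detect_events(nts)
    cen, _ = center_by_subject(nts)
    return cen


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))
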