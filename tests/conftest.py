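"""Shared fixtures: small synthetic geometries and datasets.

Everything is generated at session scope where reuse is safe (read-only
objects); sizes are kept small so the full suite runs quickly.
"""

import numpy as np
import pytest

from triaxmeg.geometry import SensorArray, build_sensor_array, local_frame
from triaxmeg.io import HeadModel
from triaxmeg.simulate import (
    make_beta_epochs,
    make_head_model,
    make_phantom_recording,
    make_phantom_truth,
    phantom_head_model,
)


@pytest.fixture(scope="session")
def adult_head() -> HeadModel:
    return make_head_model("adult")


@pytest.fixture(scope="session")
def two_year_head() -> HeadModel:
    return make_head_model("two_year")


@pytest.fixture(scope="session")
def adult_array(adult_head):
    return build_sensor_array(adult_head)


@pytest.fixture(scope="session")
def phantom_head():
    return phantom_head_model()


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise- and perturbation-free phantom run with its truth."""
    truth = make_phantom_truth(perturb=False, noise_density=0.0)
    rec, truth = make_phantom_recording(truth)
    return rec, truth


@pytest.fixture(scope="session")
def phantom_array(phantom_clean):
    _rec, truth = phantom_clean
    return SensorArray.from_poses(truth.slot_poses_true)


@pytest.fixture(scope="session")
def beta_setup():
    """Small beta-epoch dataset with a known azimuthal source."""
    head = make_head_model("adult")
    array = build_sensor_array(head, n=30)
    u = np.array([-0.55, 0.25, 0.80])
    u /= np.linalg.norm(u)
    pos = (head.brain_radius - 0.005) * u
    ori = local_frame(pos[None, :], head.sphere_center)[0, 2, :]
    epochs = make_beta_epochs(head, array, pos, ori, n_trials=20, seed=11)
    return head, array, pos, ori, epochs
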