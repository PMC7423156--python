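"""Shared fixtures: small synthetic fields plus the session-scoped studies.

The expensive end-to-end studies (blueprint comparison, identity run,
parcellation cohorts) are computed once per session and shared between the
module tests and the acceptance tests.
"""

import numpy as np
import pytest

from tractoprint import study
from tractoprint.tracking import OrientationField, TrackingParams, TractProtocol

ROOT_SEED = 1


def uniform_field(shape, direction, dispersion_deg=0.0, voxel_size=1.0):
    """Orientation field with one identical orientation everywhere."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    orientations = np.zeros(shape + (1, 3))
    orientations[..., 0, :] = direction
    weights = np.ones(shape + (1,))
    return OrientationField(
        orientations=orientations, weights=weights,
        isotropic=np.zeros(shape, dtype=bool),
        dispersion_deg=dispersion_deg, voxel_size=voxel_size)


@pytest.fixture(scope="session")
def x_field():
    return uniform_field((20, 20, 20), [1.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def bp_study():
    return study.run_blueprint_study(ROOT_SEED)


@pytest.fixture(scope="session")
def identity_divmap():
    return study.run_identity_study(ROOT_SEED)


@pytest.fixture(scope="session")
def parc_study():
    return study.run_parcellation_study(ROOT_SEED)


@pytest.fixture(scope="session")
def parc_split_study():
    return study.run_parcellation_study(ROOT_SEED, split=True, n_subjects=1)


def free_protocol(shape, params=None, **kwargs):
    """Whole-grid seed, no masks: unconstrained propagation helper."""
    return TractProtocol(
        name="free", seed_mask=np.ones(shape, dtype=bool),
        params=params or TrackingParams(n_samples=1, max_steps=10,
                                        step_length=0.5,
                                        mode="deterministic"),
        **kwargs)
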