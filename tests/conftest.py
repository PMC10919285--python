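"""Shared fixtures: phantom cohorts and (expensive) pipeline products.

Session scope keeps the costly objects — the 16-muscle augmented cohort
and the per-muscle shape models — computed once for the whole run.
"""

import numpy as np
import pytest

from musclesegkit.augmentation import (
    AugmentationPlan,
    augment_cohort,
    build_ssms,
    build_targets,
)
from musclesegkit.phantom import PhantomSpec, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def cohort16():
    """The full-scale study cohort: 10 subjects, 16 muscles, 48x48x96."""
    spec = PhantomSpec(grid_shape=(48, 48, 96), n_muscles=16)
    return generate_cohort(spec, 10, seed=11)


@pytest.fixture(scope="session")
def augmented16(cohort16):
    """Default-plan augmentation of the study cohort (27 registrations)."""
    return augment_cohort(cohort16, AugmentationPlan(), ssm_particles=128,
                          ssm_iters=8, seed=1)


@pytest.fixture(scope="session")
def cohort6():
    """Quality-oracle cohort: 6 thicker muscles on the same grid."""
    spec = PhantomSpec(grid_shape=(48, 48, 96), n_muscles=6)
    return generate_cohort(spec, 10, seed=11)


@pytest.fixture(scope="session")
def ssms6(cohort6):
    return build_ssms(cohort6, particles=128, iters=8, seed=1)


@pytest.fixture(scope="session")
def targets6(cohort6, ssms6):
    return build_targets(cohort6, AugmentationPlan(), ssms=ssms6)


@pytest.fixture(scope="session")
def small_subject():
    """A small single subject for cheap unit tests."""
    spec = PhantomSpec(grid_shape=(24, 24, 24), n_muscles=4, seed=3)
    return generate_subject(spec, subject_id="small")


@pytest.fixture(scope="session")
def binary_cohort():
    """Single-compartment phantoms for the scaled-down training task."""
    spec = PhantomSpec(grid_shape=(48, 48, 32), n_muscles=1, noise_sigma=0.05)
    return generate_cohort(spec, 5, seed=5)


def ellipsoid_cloud(a, b, c, center=(24.0, 24.0, 24.0), n=1500, seed=0):
    """Uniform-ish point samples on an axis-aligned ellipsoid surface."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * np.array([a, b, c]) + np.asarray(center)


@pytest.fixture(scope="session")
def ellipsoid_cohort():
    """10 ellipsoid surfaces varying along one semi-axis (a 1-parameter
    shape family)."""
    scales = [-2.0, -1.5, -1.0, -0.5, 0.0, 0.25, 0.5, 1.0, 1.5, 2.0]
    return [ellipsoid_cloud(10 * (1 + 0.1 * t), 8, 14, seed=5) for t in scales]
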