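import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# third-party chatter that is irrelevant to the contracts under test
warnings.filterwarnings("ignore", message="n_jobs value 1 overridden")
warnings.filterwarnings("ignore", message="The number of connected components")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def continuum_table():
    """Default imbalanced (3:2:1) continuum table, mixing 0.2."""
    from spinemorph.synthetic import generate_feature_continuum

    return generate_feature_continuum(
        {"mushroom": 60, "stubby": 40, "thin": 20}, mixing_fraction=0.2, seed=1
    )


@pytest.fixture(scope="session")
def separated_table():
    """Pure-archetype table (mixing 0): three well-separated classes."""
    from spinemorph.synthetic import generate_feature_continuum

    return generate_feature_continuum(
        {"mushroom": 30, "stubby": 30, "thin": 30}, mixing_fraction=0.0, seed=2
    )


@pytest.fixture(scope="session")
def image_set():
    from spinemorph.synthetic import generate_spine_image_set

    return generate_spine_image_set(18, noise_sd=0.05, psf_sigma=1.5, seed=1)


@pytest.fixture(scope="session")
def clean_crops():
    """Noise- and blur-free crops with unjittered geometry (ground truth)."""
    from spinemorph.synthetic import generate_spine_image_set

    return generate_spine_image_set(
        6, noise_sd=0.0, psf_sigma=0.0, seed=3, param_jitter=0.0, pixel_size=1.0
    )


def blobs(n_per, centers, sd=0.5, seed=0, d=None):
    """Isotropic Gaussian blobs helper shared across tests."""
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if d is not None and centers.shape[1] != d:
        raise ValueError("center dimension mismatch")
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, sd, size=(n_per, centers.shape[1])))
        labels.extend([i] * n_per)
    return np.vstack(pts), np.array(labels)


@pytest.fixture
def make_blobs():
    return blobs
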