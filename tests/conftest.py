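import numpy as np
import pytest

from acetoseg import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(20231596)


def random_homography(rng, scale=0.2, perspective=1e-3):
    """A random well-conditioned 3x3 homography (h33 = 1)."""
    H = np.eye(3)
    H[:2, :2] += rng.uniform(-scale, scale, (2, 2))
    H[:2, 2] = rng.uniform(-20, 20, 2)
    H[2, :2] = rng.uniform(-perspective, perspective, 2)
    return H


@pytest.fixture(scope="session")
def tiny_cases():
    """Six small noiseless-ish cases for fast training tests (24x24)."""
    params = simdata.SimParams(
        image_size=(24, 24), n_cases=6, seed=7,
        perturbation_scale=0.03, noise_sd=0.005,
        n_lesions_range=(1, 2), n_confusers_range=(1, 2),
    )
    return simdata.generate_dataset(params)


@pytest.fixture(scope="session")
def clean_case():
    """One noiseless, unperturbed case: before/after differ only at lesions."""
    params = simdata.SimParams(
        image_size=(48, 48), perturbation_scale=0.0, noise_sd=0.0
    )
    return simdata.generate_case(params, 3)
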