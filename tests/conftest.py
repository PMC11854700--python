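import numpy as np
import pytest

from hipsono import apex
from hipsono.phantom import PhantomParams, generate_cohort, generate_phantom

#: artifact-free generator settings used wherever exact geometry matters
CLEAN_KWARGS = dict(
    speckle_scale=0.0,
    reverb_count=0,
    blur_sigma_px=0.0,
    distractor_count=0,
    noise_floor_sd=0.0,
)

#: sampling ranges for training/eval cohorts
COHORT_RANGES = {
    "apex": ((80.0, 176.0), (100.0, 180.0)),
    "iliac_angle_deg": (80.0, 100.0),
    "alpha_deg": (45.0, 75.0),
}


def clean_params(**overrides) -> PhantomParams:
    kwargs = dict(CLEAN_KWARGS)
    kwargs.update(overrides)
    return PhantomParams(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def clean_phantom():
    return generate_phantom(clean_params())


@pytest.fixture(scope="session")
def trained_estimator():
    """A small trained apex model shared across tests (~15 s to fit)."""
    cohort = generate_cohort(120, ranges=COHORT_RANGES, seed=100, base=clean_params())
    dataset = [(img.astype(float), truth.apex) for img, truth, _ in cohort]
    return apex.train_apex_estimator(dataset, apex.TrainConfig(epochs=12, seed=0))
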