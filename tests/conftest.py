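import numpy as np
import pytest

from adcqual import phantom


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small rendered cohort shared across tests (8 patients x 2 sites,
    64 px at 2 mm, 6 slices)."""
    cfg = phantom.PhantomConfig(
        n_patients=8, n_sites=2, slices_per_volume=6, image_size=64,
        pixel_spacing=2.0, seed=11,
    )
    visits, metadata = phantom.generate_cohort(cfg)
    return cfg, visits, metadata


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
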