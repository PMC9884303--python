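import numpy as np
import pytest

from epifat.phantom import (
    AbdominalShapeParams,
    CardiacShapeParams,
    generate_abdominal_phantom,
    generate_cardiac_phantom,
)

# small, fast cardiac geometry used by most image tests
SMALL_CARDIAC = CardiacShapeParams(
    shape=(64, 64, 48),
    spacing=(1.5, 1.5, 2.0),
    pericardium_axes_mm=(30.0, 27.0, 24.0),
    chamber_axes_mm=(24.0, 21.0, 18.0),
)

# roomy grid: blobs of 5-20 ml at 50-65 mm offset fit in any direction
BLOB_CARDIAC = CardiacShapeParams(shape=(256, 256, 160))


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless small cardiac phantom: exact recovery is testable."""
    return generate_cardiac_phantom(SMALL_CARDIAC, noise_sd_hu=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_cardiac_phantom(SMALL_CARDIAC, noise_sd_hu=10.0, seed=7)


@pytest.fixture(scope="session")
def abdominal_phantom():
    """Noiseless abdominal annulus phantom."""
    return generate_abdominal_phantom(AbdominalShapeParams(), noise_sd_hu=0.0, seed=3)


@pytest.fixture(scope="session")
def cohort_table():
    from epifat.cohort import generate_cohort

    return generate_cohort(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
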