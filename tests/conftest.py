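import numpy as np
import pytest

from hepaplan import synthetic_data


@pytest.fixture(scope="session")
def phantom2mm():
    """Standard ellipsoid phantom at 2 mm voxels (fast)."""
    return synthetic_data.make_phantom(spacing_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def sphere_phantom():
    """Symmetric sphere phantom: planes through the centre, portal at z=0."""
    return synthetic_data.make_phantom(
        shape="sphere", radii_mm=(50.0, 50.0, 50.0), spacing_mm=(2.0, 2.0, 2.0)
    )


@pytest.fixture(scope="session")
def cohort200():
    return synthetic_data.synthetic_cohort(200, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
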