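import numpy as np
import pytest

from pdacdetect.cascade import phantom_scale_bundle_geometry
from pdacdetect.phantom import PhantomParams, generate_case


@pytest.fixture(scope="session")
def tumor_case():
    return generate_case(
        PhantomParams(shape=(48, 48, 48), has_tumor=True, seed=11), case_id="tumor_case"
    )


@pytest.fixture(scope="session")
def control_case():
    return generate_case(
        PhantomParams(shape=(48, 48, 48), has_tumor=False, seed=12), case_id="control_case"
    )


@pytest.fixture(scope="session")
def phantom_geom():
    return phantom_scale_bundle_geometry((48, 48, 48))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
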