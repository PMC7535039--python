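import numpy as np
import pytest

from hetrad.io import FeatureVector
from hetrad.features.names import FEATURE_NAMES
from hetrad.partition import make_habitats
from hetrad.phantom import PhantomConfig, TextureContrast, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_phantom_config():
    """Desk-scale phantom with the default habitat texture contrast."""
    return PhantomConfig(n_subjects=14, seed=11)


@pytest.fixture(scope="session")
def phantom_subject(small_phantom_config):
    """One generated subject: (volume, gtv, gtvr, isodose95)."""
    return generate_phantom(small_phantom_config, 0)


@pytest.fixture(scope="session")
def phantom_habitats(phantom_subject):
    vol, gtv, gtvr, _ = phantom_subject
    return vol, make_habitats(gtv, gtvr, subject_id=vol.id)


def make_feature_vector(values_by_name=None, subject_id="S1", roi_role="GTVr", fill=0.0):
    """A FeatureVector with all 47 canonical keys, overriding selected names."""
    vals = {name: fill for name in FEATURE_NAMES}
    if values_by_name:
        vals.update(values_by_name)
    return FeatureVector(values=vals, subject_id=subject_id, roi_role=roi_role)


@pytest.fixture
def feature_vector_factory():
    return make_feature_vector


@pytest.fixture
def null_contrast_config():
    """Phantom config with no habitat difference at all (null condition)."""
    return PhantomConfig(
        n_subjects=20,
        seed=5,
        texture_contrast=TextureContrast(
            intensity_shift=0.0,
            correlation_length_rec=1.2,
            correlation_length_nonrec=1.2,
            noise_sd=60.0,
        ),
    )
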