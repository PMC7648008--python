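import numpy as np
import pytest

from mkldecode import synthetic
from mkldecode.synthetic import EffectSpec, StudyDesign


@pytest.fixture(scope="session")
def atlas4():
    """Small 4-region atlas on a 10^3 grid."""
    return synthetic.make_synthetic_atlas((10, 10, 10), 4, seed=7)


@pytest.fixture(scope="session")
def atlas8():
    """Study-shaped 8-region atlas on a 16^3 grid."""
    return synthetic.make_synthetic_atlas((16, 16, 16), 8, seed=1)


@pytest.fixture(scope="session")
def small_design():
    """Reduced-subject version of the block design for fast tests."""
    return StudyDesign(n_subjects=12)


@pytest.fixture(scope="session")
def small_dataset(small_design, atlas4):
    """12-subject contrast dataset with a clear effect in region 2."""
    effect = EffectSpec(informative_region_ids=(2,), delta=1.0, sigma=0.4,
                        subject_offset_sd=0.2)
    images, ratings = synthetic.make_contrast_dataset(small_design, atlas4,
                                                      effect, seed=11)
    return images, ratings


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
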