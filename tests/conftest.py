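import numpy as np
import pytest

from fepfa import make_gaussian_feature_data, make_phantom_image


@pytest.fixture(scope="session")
def recovery_data():
    """The standard planted-signal recovery problem: 4 classes x 50, d=200."""
    return make_gaussian_feature_data(
        n_per_class=50, n_classes=4, d=200, d_informative=20, effect_size=3.0, seed=1
    )


@pytest.fixture()
def phantom():
    return make_phantom_image(16, 16, fg_level=1.0, bg_level=0.0, shape="disc")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
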