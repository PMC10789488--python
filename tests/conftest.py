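import numpy as np
import pandas as pd
import pytest

from neurocoloc.imaging import extract_regional_means
from neurocoloc.simulate import (
    SyntheticConfig,
    generate_atlas,
    generate_gm_probability,
    generate_template_maps,
)


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas((12, 12, 12), 40, seed=7)


@pytest.fixture(scope="session")
def small_templates(small_atlas):
    return generate_template_maps(small_atlas, 5, smoothness=2.0, seed=8)


@pytest.fixture(scope="session")
def gm_regional(small_atlas):
    return extract_regional_means(generate_gm_probability(small_atlas), small_atlas)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        grid_shape=(12, 12, 12),
        n_regions=40,
        n_templates=5,
        n_patients=16,
        n_controls=8,
        planted_template_index=1,
        effect_size_beta=1.0,
        noise_sd=1.0,
        seed=21,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
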