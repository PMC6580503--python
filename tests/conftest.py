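import numpy as np
import pytest

from kascade import pipeline
from kascade.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="session")
def norm_props():
    """The four packaged property tables, standardised."""
    return pipeline.default_normalized_properties()


#: A reduced-size generator configuration for fast unit tests; the full-size
#: defaults are exercised by the acceptance suite.
SMALL_CONFIG = dict(
    n_proteins=60, min_length=80, max_length=160,
    n_positive=30, n_negative=300,
)


@pytest.fixture(scope="session")
def small_config():
    return dict(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(GeneratorConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_feature_matrix(small_bundle):
    return pipeline.encode_bundle(small_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
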