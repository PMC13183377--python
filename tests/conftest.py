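import numpy as np
import pytest

from ovirhythm.simulate import GenParams, generate_population


@pytest.fixture
def times_7d():
    """Standard device grid: 7 days of 4-h bins."""
    return np.arange(42) * 4.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def rhythmic_population():
    """20 rhythmic synthetic flies under default study conditions."""
    return generate_population(GenParams(seed=42), 20, genotype="wt-like")


@pytest.fixture(scope="session")
def null_population():
    """20 arrhythmic flies (no circadian modulation, trend retained)."""
    return generate_population(GenParams(mod_depth=0.0, seed=43), 20,
                               genotype="null")
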