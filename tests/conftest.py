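import numpy as np
import pytest

from ribocell import GenomeDesign, ParameterSet


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def design() -> GenomeDesign:
    return GenomeDesign()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def zero_probability_params(**overrides) -> ParameterSet:
    """A parameter set with every per-step probability set to 0 (null
    dynamics); sizes and factors keep their defaults."""
    p = ParameterSet()
    zeros = {name: 0.0 for name in p.probability_fields()}
    zeros.update(overrides)
    return p.replace(**zeros)
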