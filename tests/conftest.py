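import numpy as np
import pytest

from kirphase.simulator import builtin_patterns, builtin_table1


@pytest.fixture(scope="session")
def table1():
    """Bundled (locus panel, frequency table) of the 17-haplotype study panel."""
    return builtin_table1()


@pytest.fixture(scope="session")
def kir_patterns():
    return builtin_patterns()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240811)
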