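import pytest

from primedit import (
    ECOLI_V4,
    AbundanceTable,
    build_construct_set,
    synthetic_template,
)


@pytest.fixture(scope="session")
def scheme():
    return ECOLI_V4


@pytest.fixture(scope="session")
def template(scheme):
    return synthetic_template(scheme, length=332, seed=20)


@pytest.fixture(scope="session")
def constructs(template, scheme):
    """The canonical 31-member standards pool (10-position window)."""
    return build_construct_set(template, scheme, window=10, flank_len=20, seed=3)


@pytest.fixture(scope="session")
def even_abundance(constructs):
    return AbundanceTable.even(constructs.ids)
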