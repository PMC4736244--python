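import pytest

from phenoprior import (
    PhenotypeQuery,
    catalog_information_content,
    make_fixture_t6,
    topological_weights,
)


@pytest.fixture(scope="session")
def t6():
    """The canonical 6-term worked-example fixture: (dag, catalog)."""
    return make_fixture_t6()


@pytest.fixture(scope="session")
def t6_dag(t6):
    return t6[0]


@pytest.fixture(scope="session")
def t6_catalog(t6):
    return t6[1]


@pytest.fixture(scope="session")
def t6_ic(t6):
    dag, catalog = t6
    return catalog_information_content(catalog, dag)


@pytest.fixture(scope="session")
def t6_tw(t6_dag):
    return topological_weights(t6_dag)


@pytest.fixture()
def q_t3():
    return PhenotypeQuery({"T3"})
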