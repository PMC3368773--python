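import pytest

from mitocomp.fixtures import table_fixture_loader
from mitocomp.gene_order import order_from_annotation


@pytest.fixture(scope="session")
def mirabilis():
    return table_fixture_loader("nmirabilis_table1")


@pytest.fixture(scope="session")
def rubens():
    return table_fixture_loader("zrubens_table1")


@pytest.fixture(scope="session")
def ground_pattern():
    return table_fixture_loader("gene_orders")["bilaterian_ground_pattern"]


@pytest.fixture(scope="session")
def mir_order(mirabilis):
    return order_from_annotation(mirabilis)


@pytest.fixture(scope="session")
def rub_order(rubens):
    return order_from_annotation(rubens)
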