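import pytest

from phedkit.datagen import covid_case_matrix, worked_example_table


@pytest.fixture(scope="session")
def worked_table():
    return worked_example_table()


@pytest.fixture(scope="session")
def covid_case():
    return covid_case_matrix()
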