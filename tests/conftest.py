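import pytest

from tancho import (
    load_kin_pedigree,
    load_kin_table,
    load_marker_panel,
    load_nonkin_table,
    select_dataset,
)


@pytest.fixture(scope="session")
def panel():
    return load_marker_panel()


@pytest.fixture(scope="session")
def nonkin():
    return load_nonkin_table()


@pytest.fixture(scope="session")
def kin():
    return load_kin_table()


@pytest.fixture(scope="session")
def union():
    return select_dataset("union")


@pytest.fixture(scope="session")
def pedigree():
    return load_kin_pedigree()
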