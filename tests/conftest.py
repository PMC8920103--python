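import pytest

from iamdelta import (
    load_reference_deltas,
    load_reference_table,
    recover_both_calibrations,
)


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def printed_deltas():
    return load_reference_deltas()


@pytest.fixture(scope="session")
def calibrations(reference_table, printed_deltas):
    return recover_both_calibrations(reference_table, printed_deltas)
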