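import pytest

from relaxochain import BPPParams, load_table1, load_table2


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def bpp_23mhz():
    """BPP parameters at the 23 MHz benchtop field."""
    return BPPParams(larmor_frequency_mhz=23.0)
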