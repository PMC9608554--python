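import pytest

import chromaqbd as cq


@pytest.fixture(scope="session")
def bbd_table():
    """Packaged Box-Behnken optimization study (16 runs, 4 responses)."""
    return cq.load_fixture("table2_bbd")


@pytest.fixture(scope="session")
def screening_table():
    """Packaged 2^(6-2) screening study (19 runs, 5 responses)."""
    return cq.load_fixture("table1_screening")


@pytest.fixture(scope="session")
def separation_cmas():
    return [
        cq.CMADefinition("s1", "t_b_imp2", "t_e_bup", 0.0),
        cq.CMADefinition("s2", "t_b_imp3", "t_e_imp2", 0.0),
    ]
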