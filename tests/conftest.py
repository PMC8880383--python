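import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, database=None)
settings.load_profile("ci")

import capsid


@pytest.fixture(scope="session")
def t3_cage():
    return capsid.build_icosahedral(3)


@pytest.fixture(scope="session")
def t4_cage():
    return capsid.build_icosahedral(4)


@pytest.fixture(scope="session")
def t1_cage():
    return capsid.build_icosahedral(1)


@pytest.fixture(scope="session")
def prolate_cage():
    return capsid.build_elongated_5fold(3, 4)


@pytest.fixture(scope="session")
def oblate_cage():
    return capsid.build_elongated_5fold(3, 2)


@pytest.fixture(scope="session")
def small_prolate_cage():
    return capsid.build_elongated_3fold(1, 2, 3)
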