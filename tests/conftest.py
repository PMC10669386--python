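import pytest

from glucofuzz import default_sensor, default_system, load_fixture


@pytest.fixture(scope="session")
def fuzzy_system():
    return default_system()


@pytest.fixture(scope="session")
def sensor():
    """(GlucoseOpticsMap, OpticalProperties, CircuitParams) default triple."""
    return default_sensor()


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")
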