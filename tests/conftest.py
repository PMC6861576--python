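import pytest

from benzilkit import io


@pytest.fixture(scope="session")
def benzil_series():
    return io.load_benzil_series()


@pytest.fixture(scope="session")
def by_id(benzil_series):
    return {m.id: m for m in benzil_series}


@pytest.fixture(scope="session")
def reactivity_reference():
    return io.load_reference_table("reactivity")


@pytest.fixture(scope="session")
def photovoltaic_reference():
    return io.load_reference_table("photovoltaic")


@pytest.fixture(scope="session")
def nlo_reference():
    return io.load_reference_table("nlo")


@pytest.fixture(scope="session")
def qsar_reference():
    return io.load_reference_table("qsar")


@pytest.fixture(scope="session")
def docking_tables():
    from benzilkit import docking

    return docking.load_study_tables()
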