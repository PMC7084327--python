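import pytest

from netpharm import datasets


@pytest.fixture(scope="session")
def hr_records():
    return datasets.load_hr_components()


@pytest.fixture(scope="session")
def hr_whitelist():
    return datasets.load_default_whitelist()


@pytest.fixture(scope="session")
def reported_pathways():
    return datasets.load_reported_pathways()


@pytest.fixture(scope="session")
def reported_disease_clusters():
    return datasets.load_reported_disease_clusters()


@pytest.fixture(scope="session")
def reported_overlap_clusters():
    return datasets.load_reported_overlap_clusters()
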