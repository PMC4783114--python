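import csv
from importlib import resources

import pytest

from gastrodia_ms.compound_space import default_candidates
from gastrodia_ms.spectra_io import read_mgf


def _data_path(name):
    return resources.as_file(resources.files("gastrodia_ms.data").joinpath(name))


@pytest.fixture(scope="session")
def candidates():
    return default_candidates()


@pytest.fixture(scope="session")
def by_name(candidates):
    return {c.name: c for c in candidates}


@pytest.fixture(scope="session")
def table5_spectra():
    with _data_path("table5.mgf") as path:
        return read_mgf(path)


@pytest.fixture(scope="session")
def table5_reference():
    with _data_path("table5_reference.csv") as path:
        with open(path, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))


@pytest.fixture(scope="session")
def table5_assignments():
    with _data_path("table5_assignments.csv") as path:
        with open(path, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))


@pytest.fixture(scope="session")
def table3_precision():
    with _data_path("table3_precision.csv") as path:
        with open(path, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))


@pytest.fixture(scope="session")
def table4_recovery():
    with _data_path("table4_recovery.csv") as path:
        with open(path, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))
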