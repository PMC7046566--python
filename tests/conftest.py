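import datetime as dt

import pandas as pd
import pytest

from fracrisk import assemble_table, load_catchment_incidence
from fracrisk.hazards import load_life_table
from fracrisk.synthetic import gen_life_table


@pytest.fixture(scope="session")
def catchment():
    """Events and person-years of the packaged 2015-2017 catchment surveillance."""
    return load_catchment_incidence()


@pytest.fixture(scope="session")
def incidence_table(catchment):
    """Full incidence table (rates + exact Poisson CIs) recomputed from counts."""
    return assemble_table(catchment["events"], catchment)


@pytest.fixture(scope="session")
def death_curves(tmp_path_factory):
    """Gompertz-Makeham death curves loaded through the life-table reader."""
    path = tmp_path_factory.mktemp("lt") / "life_table.csv"
    gen_life_table().to_csv(path, index=False)
    return load_life_table(path)


@pytest.fixture
def write_registry(tmp_path):
    """Write registry rows (list of dicts) to a CSV and return its path."""

    def _write(rows, name="registry.csv", sep=","):
        df = pd.DataFrame(rows)
        path = tmp_path / name
        df.to_csv(path, index=False, sep=sep)
        return path

    return _write


@pytest.fixture
def window():
    return dt.date(2015, 1, 1), dt.date(2017, 12, 31)
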