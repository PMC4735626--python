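import numpy as np
import pandas as pd
import pytest

from teleflux.grid import GridSpec
from teleflux.stacks import MonthlyFieldStack, month_index
from teleflux.synthetic import SyntheticConfig, standin_index_tables


@pytest.fixture(scope="session")
def standin_tables(tmp_path_factory):
    """The synthetic stand-in CPC-dialect NAO/EA tables (paths)."""
    d = tmp_path_factory.mktemp("cpc_standin")
    return standin_index_tables(d)


@pytest.fixture
def small_grid():
    return GridSpec.regular(40.0, 50.0, 0.0, 20.0, 2.5, 5.0)


#: reduced synthetic world for fast pipeline-level tests
FAST_SYN = dict(
    n_years=15,
    n_members=3,
    n_inversions=2,
    flux_grid=(30.0, 75.0, -15.0, 60.0, 4.0),
    z500_grid=(20.0, 80.0, -90.0, 50.0, 4.0),
)


@pytest.fixture
def fast_config():
    return SyntheticConfig(seed=7, **FAST_SYN)


def random_stack(seed: int, n_months: int = 24, variable: str = "T2M",
                 grid: GridSpec | None = None, start: str = "2000-01",
                 units: str = "degC") -> MonthlyFieldStack:
    """A small random monthly stack for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    grid = grid or GridSpec.regular(40.0, 50.0, 0.0, 20.0, 2.5, 5.0)
    values = rng.standard_normal((n_months,) + grid.shape)
    return MonthlyFieldStack(variable=variable, units=units,
                             times=month_index(start, n_months),
                             values=values, grid=grid)
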