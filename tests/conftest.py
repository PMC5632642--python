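import numpy as np
import pandas as pd
import pytest

from dendrogrowth import climate as cm
from dendrogrowth import synthetic_data as sd


@pytest.fixture(scope="session")
def default_climate() -> cm.MonthlyClimate:
    """One deterministic simulated climate (1850-2008, warming break)."""
    return sd.simulate_climate(sd.SimTruth(seed=3))


@pytest.fixture(scope="session")
def default_design(default_climate) -> cm.LagDesign:
    return cm.build_lag_design(default_climate)


@pytest.fixture(scope="session")
def quiet_climate() -> cm.MonthlyClimate:
    """Climate without a warming trend: standardized columns are white."""
    return sd.simulate_climate(sd.SimTruth(seed=3, warming_slope=tuple([0.0] * 12)))


@pytest.fixture(scope="session")
def quiet_design(quiet_climate) -> cm.LagDesign:
    return cm.build_lag_design(quiet_climate)


def make_grouped(df: pd.DataFrame, spec):
    from dendrogrowth.lmm_core import GroupedData

    return GroupedData.from_frame(df, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
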