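import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clvsim import CaseTimeSeries

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_series(
    sap,
    rate=None,
    map_mmhg=None,
    valid=None,
    dt=20.0,
    case_id="case",
):
    """Construct a valid CaseTimeSeries from a SAP trace with sane defaults."""
    sap = np.asarray(sap, dtype=float)
    n = len(sap)
    if rate is None:
        rate = np.zeros(n)
    rate = np.asarray(rate, dtype=float)
    if map_mmhg is None:
        map_mmhg = np.minimum(0.65 * sap + 10.0, 0.95 * sap)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return CaseTimeSeries(
        t=np.arange(n) * dt,
        sap=sap,
        map=map_mmhg,
        rate=rate,
        pump_active=rate > 0,
        valid=valid,
        case_id=case_id,
        dt_record=dt,
    )


@pytest.fixture
def series_factory():
    return build_series
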