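import numpy as np
import pytest

from oxyreg import ArchetypeSpec, NoiseModel, RateProfile, TraceMetadata, UnitContext


@pytest.fixture
def ctx10():
    return UnitContext(temperature_C=10.0, salinity_psu=34.0)


@pytest.fixture
def meta():
    return TraceMetadata(
        trace_id="t1",
        species="Euphausia testis",
        temperature_C=10.0,
        chamber_volume_mL=20.0,
        weight_mg=50.0,
        sampling_interval_s=15.0,
        salinity_psu=34.0,
    )


@pytest.fixture
def conformer_profile():
    do = np.linspace(100.0, 10.0, 20)
    return RateProfile("conf", do, 0.02 * do)


@pytest.fixture
def regulator_profile():
    do = np.linspace(100.0, 10.0, 20)
    return RateProfile("reg", do, np.full(20, 2.0))


def make_powerlaw_profile(gamma, n=200, do_max=100.0, floor=0.0, rmax=1.0, tid="pl"):
    do = np.linspace(do_max, floor, n)
    with np.errstate(divide="ignore"):
        rate = rmax * np.where(do > 0, (do / do_max) ** gamma, 0.0 if gamma > 0 else 1.0)
    return RateProfile(tid, do, rate)
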