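import pytest

from coroperf import (
    DarcyGrid,
    DarcyParams,
    PatientRecord,
    build_aortic_waveform,
    build_effective_waveform,
    default_tree,
    derive_all,
)


@pytest.fixture(scope="session")
def patient() -> PatientRecord:
    """Reference middle-aged male subject used across the suite."""
    return PatientRecord(
        age=60, sex="male", height=175, weight=75, HR=70, P_sys=120, P_dia=80, LV_mass=160
    )


@pytest.fixture(scope="session")
def derived(patient):
    return derive_all(patient)


@pytest.fixture(scope="session")
def par(derived):
    timings, pressures = derived
    return build_aortic_waveform(timings, pressures)


@pytest.fixture(scope="session")
def peff(par, derived):
    timings, _ = derived
    return build_effective_waveform(par, timings)


@pytest.fixture(scope="session")
def small_grid() -> DarcyGrid:
    return DarcyGrid(6, 6, 4, 2e-3)


@pytest.fixture(scope="session")
def params() -> DarcyParams:
    return DarcyParams()


@pytest.fixture(scope="session")
def healthy_tree():
    return default_tree()
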