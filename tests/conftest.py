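import pytest

import pcabsim as ps
from pcabsim.calibration import VONOPRAZAN_2024, apply_calibration


@pytest.fixture(scope="session")
def phys():
    return ps.reference_adult()


@pytest.fixture(scope="session")
def vonoprazan(phys):
    """Uncalibrated parameter table with the Kp scaler solved from Vss."""
    return ps.datasets.vonoprazan_parameters(phys)


@pytest.fixture(scope="session")
def vonoprazan_calibrated(vonoprazan):
    return apply_calibration(vonoprazan, VONOPRAZAN_2024)


@pytest.fixture(scope="session")
def regimen_20mg():
    return ps.DoseRegimen(dose_mg=20.0, duration_h=48.0)


@pytest.fixture(scope="session")
def calibrated_pk(vonoprazan_calibrated, regimen_20mg, phys):
    """The calibrated 20 mg single-dose run shared across tests."""
    return ps.simulate_pk(vonoprazan_calibrated, regimen_20mg, phys)


@pytest.fixture(scope="session")
def potency():
    return ps.datasets.vonoprazan_potency()


@pytest.fixture(scope="session")
def calibrated_pd_config(calibrated_pk, potency):
    """pH ceiling fitted once against the 88.88% holding-time endpoint."""
    return ps.calibrate_ph_max(calibrated_pk, potency, 88.88)
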