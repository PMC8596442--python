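import numpy as np
import pytest

from glucassay.synthetic import TransportSimConfig, simulate_transport
from glucassay.transport import TransportTimeCourse

# Printed bidirectional Papp means (1e-6 cm/s) and derived columns from the
# glucose-transport report table: sample -> (AP-BL, BL-AP, UR, %ctrl AP, %ctrl BL)
TABLE2 = {
    "Control": (34.56, 4.68, 7.39, 100.0, 100.0),
    "RPP-1": (21.79, 5.58, 3.91, 63.05, 119.23),
    "RPP-2": (34.89, 4.57, 7.63, 100.95, 97.65),
    "RPP-3": (12.79, 7.37, 1.74, 37.01, 157.48),
    "RPP-4": (17.21, 6.54, 2.63, 69.8, 139.74),
}


@pytest.fixture
def linear_course():
    """Receiver concentration linear in time, no sampling: Q = C_R * V_R."""
    k = 1e-3  # conc per second
    times = (0.0, 300.0, 600.0, 900.0)
    return TransportTimeCourse(
        area_a=1.12,
        vol_donor_vd=0.5,
        vol_receiver_vr=1.5,
        vol_sample_vs=0.0,
        conc_donor_c0=50.0,
        times=times,
        conc_receiver=tuple(k * t for t in times),
    ), k


@pytest.fixture
def early_time_sim():
    """Noiseless simulated course with < 2% of donor mass transported."""
    cfg = TransportSimConfig(
        papp_true=1e-5, area_a=1.12, vol_donor_vd=0.5, vol_receiver_vr=1.5,
        conc_donor_c0=50.0, vol_sample_vs=0.0, noise_cv=0.0,
        sample_times=(0.0, 150.0, 300.0, 450.0, 600.0),
    )
    return simulate_transport(cfg)


@pytest.fixture
def nonsink_sim():
    """Noiseless course generated by the exact relaxation closed form."""
    cfg = TransportSimConfig(
        papp_true=3e-6, area_a=1.12, vol_donor_vd=0.5, vol_receiver_vr=1.5,
        conc_donor_c0=50.0, vol_sample_vs=0.0, noise_cv=0.0,
        sample_times=tuple(np.linspace(0.0, 7200.0, 8)),
    )
    return simulate_transport(cfg)
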