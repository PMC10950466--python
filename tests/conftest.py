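import numpy as np
import pytest
from hypothesis import settings

import gustwing as gw
from gustwing import segments_stats as ss
from gustwing.core_io import WindRecord

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

WIND_U, WIND_V = 2.0, 1.0


@pytest.fixture(scope="session")
def wind_record():
    return WindRecord(np.array([0.0, 3600.0]), np.array([WIND_U, WIND_U]),
                      np.array([WIND_V, WIND_V]))


@pytest.fixture(scope="session")
def sine_trace():
    """Pure 6 Hz flapping signal, half-amplitude 2 g, 10 s at 200 Hz."""
    t = np.arange(0.0, 10.0, 1.0 / 200.0)
    heave = 1.0 + 2.0 * np.sin(2.0 * np.pi * 6.0 * t)
    z = np.zeros_like(t)
    return gw.AccelTrace(t, z.copy(), z.copy(), heave)


@pytest.fixture(scope="session")
def noiseless_config():
    return gw.SimConfig(
        duration_s=60.0, seed=11, turbulence=0.0,
        sigma_f0_hz=0.0, sigma_a0_g=0.0, gamma_f=0.0, gamma_a=0.0,
        accel_noise_g=0.0, pressure_noise_hpa=0.0, gps_noise_m=0.0,
        gust_alt_sd_per_t=0.0, gust_vel_sd_per_t=0.0,
    )


@pytest.fixture(scope="session")
def flight_set(wind_record):
    """20 flights, 5-level turbulence ladder, kinematic variability on."""
    return gw.make_flight_set(20, seed=2024)


@pytest.fixture(scope="session")
def segment_table(flight_set, wind_record):
    prods = [ss.flight_products(rec, wind=wind_record, terrain=400.0)
             for rec, _ in flight_set]
    return ss.build_segment_table(prods)


@pytest.fixture(scope="session")
def truth_by_segment(flight_set):
    """segment_id -> true turbulence level."""
    out = {}
    for rec, truth in flight_set:
        for i, _ in enumerate(truth.segment_bounds):
            out[f"{rec.flight_id}_s{i:03d}"] = float(truth.segment_turbulence[i])
    return out


@pytest.fixture(scope="session")
def fits(segment_table):
    return ss.fit_all_responses(segment_table)
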