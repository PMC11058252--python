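import numpy as np
import pytest

from colim import MonodParams, default_environment
from colim.synthetic_data import (
    NoiseConfig,
    SeedingConfig,
    SimulationConfig,
    simulate_array,
)

# Best-fit parameter set from the dual-gradient experiment with acetate;
# used throughout as the "true" generating parameters.
FITTED = dict(mu_max=2.4, L0=50.8, K_L=57.2, N0=0.0, K_N=2.8)


@pytest.fixture(scope="session")
def fitted_params():
    return MonodParams(**FITTED)


@pytest.fixture(scope="session")
def env():
    return default_environment()


@pytest.fixture(scope="session")
def noise_free_config(env, fitted_params):
    return SimulationConfig(
        env=env,
        params=fitted_params,
        noise=NoiseConfig(intensity_cv=0.0, background_level=100.0, background_sd=0.0),
        seeding=SeedingConfig(p_empty=0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_series(noise_free_config):
    return simulate_array(noise_free_config)


def brute_force_max_window_slope(times_h, log_ratio, n=9, min_time_days=1.3):
    """Independent oracle: enumerate every window, OLS via polyfit,
    filter on window-center time, pick the max (earliest on ties)."""
    best = None
    for i in range(len(times_h) - n + 1):
        t = np.asarray(times_h[i : i + n], dtype=float)
        y = np.asarray(log_ratio[i : i + n], dtype=float)
        center = t.mean()
        if center < min_time_days * 24.0:
            continue
        if not np.all(np.isfinite(y)):
            continue
        slope = np.polyfit(t, y, 1)[0] * 24.0
        if best is None or slope > best[0] + 0.0:
            if best is None or slope > best[0]:
                best = (slope, center, i)
    return best  # (mu_per_day, center_h, window_index) or None
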