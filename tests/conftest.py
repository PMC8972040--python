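import numpy as np
import pytest

import myoturnover as mt


@pytest.fixture(scope="session")
def geometry():
    return mt.FilamentGeometry()


@pytest.fixture(scope="session")
def clean_render():
    return mt.RenderConfig(noise_sd=0.0, background=0.0,
                           bleach_rate_green=0.0, red_linear_drift=0.0)


@pytest.fixture(scope="session")
def frap_times():
    """10-min sampling grid over 10 h, in hours."""
    return np.arange(0.0, 10.0 + 1e-9, 1 / 6)


@pytest.fixture(scope="session")
def population_30min():
    """One 30-min pulse-chase population shared across classifier tests."""
    return mt.generate_pulse_chase_population(
        "tip_biased_paper", chase_time_min=30.0, n_sarcomeres=150,
        n_myotubes=6, seed=20240 % 2**31,
    )


@pytest.fixture(scope="session")
def classified_30min(population_30min):
    out = []
    for scan in population_30min.scans:
        w = mt.extract_from_scan(scan)
        out.append(mt.classify_pattern(w))
    return out
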