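import numpy as np
import pytest

from bathmort.simulate import SimulationConfig, simulate_panels


@pytest.fixture(scope="session")
def small_sim():
    """3 regions x 6 years with all generator effects on: the demo world."""
    cfg = SimulationConfig(
        n_regions=3, start="2000-01-01", end="2005-12-31", seed=42,
        baseline_rate=2e-6,
    )
    return simulate_panels(cfg)


@pytest.fixture(scope="session")
def cyclic_sim():
    """5 regions x 8 years, pure cyclic seasonality (no temperature effect):
    ground-truth PTR is exactly exp(2A) = 3."""
    cfg = SimulationConfig(
        n_regions=5, start="1998-01-01", end="2005-12-31", seed=7,
        baseline_rate=2e-6, cold_slope_logRR_per_degC=0.0,
        seasonal_amplitude_logRR=np.log(3.0) / 2,
    )
    return simulate_panels(cfg)


@pytest.fixture(scope="session")
def small_panels(small_sim):
    return small_sim.panels
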