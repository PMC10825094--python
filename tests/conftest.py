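import pytest
from hypothesis import HealthCheck, settings

from ventbench import (
    ExperimentConfig,
    LungCircuit,
    VentilatorSettings,
    default_devices,
    run_grid,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_settings():
    """Reference ventilator settings of the bench protocol."""
    return VentilatorSettings(
        tidal_volume_set=400.0,
        inspiratory_flow=60.0,
        pause_time=0.4,
        respiratory_rate=20.0,
        peep_set=5.0,
    )


@pytest.fixture(scope="session")
def lung60():
    return LungCircuit(60.0, 5.0, 5.0, 120.0)


@pytest.fixture(scope="session")
def lung40():
    return LungCircuit(40.0, 5.0, 5.0, 120.0)


@pytest.fixture(scope="session")
def lung20():
    return LungCircuit(20.0, 5.0, 5.0, 120.0)


@pytest.fixture(scope="session")
def devices():
    """Devices calibrated from the printed mean EtCO2 increases."""
    return {d.name: d for d in default_devices()}


@pytest.fixture(scope="session")
def atpd_results():
    """One shared full factorial dry-rig run (deterministic)."""
    return run_grid(ExperimentConfig.atpd_default())
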