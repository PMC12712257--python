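import pytest
from hypothesis import HealthCheck, settings

from bronchosim import (
    RespiratorySystem,
    RohrerModel,
    ScalingLaw,
    SimulationConfig,
    TubeScopeGeometry,
    VentilatorSettings,
    scaling_law_model,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def bench_system() -> RespiratorySystem:
    """Lung-simulator mechanics used throughout the bench study."""
    return RespiratorySystem(compliance=50.0, r_aw=2.0, p_mus=0.0)


@pytest.fixture
def vc_settings() -> VentilatorSettings:
    return VentilatorSettings(mode="vc", vt_set=500.0, peep=0.0, t_in=1.8, t_ex=2.2)


@pytest.fixture
def pc_settings() -> VentilatorSettings:
    return VentilatorSettings(mode="pc", ps=10.0, peep=0.0, t_in=1.8, t_ex=2.2)


@pytest.fixture
def atc_settings() -> VentilatorSettings:
    return VentilatorSettings(mode="atc", atc_target_peak=10.0, peep=0.0)


@pytest.fixture
def reference_tube() -> RohrerModel:
    """Rohrer model at the 10 mm reference diameter: k1 = 0.72, k2 = 2.88."""
    return RohrerModel.symmetric(0.72, 2.88)


def tube_at(d_eff: float, has_scope: bool = True) -> RohrerModel:
    return scaling_law_model(
        TubeScopeGeometry.from_effective_diameter(d_eff, has_scope=has_scope),
        ScalingLaw(),
    )


@pytest.fixture
def fast_config() -> SimulationConfig:
    return SimulationConfig(dt=0.004, max_breaths=100, steady_tol=0.01)
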