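import pytest

from pshpassage.bladestrike import TurbineConfig
from pshpassage.shear import DEFAULT_LIFE_STAGES, LifeStage, LifeStageSpec


@pytest.fixture
def egg_spec() -> LifeStageSpec:
    return DEFAULT_LIFE_STAGES[LifeStage.egg]


@pytest.fixture
def juvenile_spec() -> LifeStageSpec:
    return DEFAULT_LIFE_STAGES[LifeStage.juvenile]


@pytest.fixture
def round_turbine() -> TurbineConfig:
    """Hand-checkable turbine: 13 blades, 300 rpm, D=5 m, B=1.2 m.

    At the mid-table discharge Q=120 m³/s the radial inflow velocity is
    Q/(πDB) = 6.3662 m/s, so a 0.02 m apparent length gives
    P = (13·300/60)·0.02/6.3662 = 0.20420.
    """
    return TurbineConfig(
        n_blades=13,
        rotation_speed_rpm=300.0,
        runner_inlet_diameter=5.0,
        runner_inlet_height=1.2,
        operating_table=((10.0, 100.0), (20.0, 120.0), (30.0, 150.0)),
    )
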