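import pytest

from cachexim import (
    MuscleParams,
    PKParams,
    Scenario,
    TumourParams,
    make_cycle,
    make_daily,
    run,
)
from cachexim.synthetic import default_configs, generate


@pytest.fixture(scope="session")
def pk() -> PKParams:
    return PKParams()


@pytest.fixture(scope="session")
def mp() -> MuscleParams:
    return MuscleParams()


@pytest.fixture(scope="session")
def noise_free_datasets():
    """Both schedule families generated from the model at (tau=8, Rd=6.8), no noise."""
    daily_cfg, ft_cfg = default_configs(noise_sd=0.0)
    return generate(daily_cfg), generate(ft_cfg)


@pytest.fixture(scope="session")
def standard_daily_run():
    """24 mg/kg daily with tumour — the reference regimen trajectory."""
    return run(Scenario(schedule=make_daily(24), tp=TumourParams()))


@pytest.fixture(scope="session")
def five_two_run():
    """35 mg/kg 5-on/2-off with tumour."""
    return run(Scenario(schedule=make_cycle(5, 2, 35), tp=TumourParams()))
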