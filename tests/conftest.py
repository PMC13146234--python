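import pytest

from smokesense.config import ScenarioConfig


def _flat_rates(rate: float, start: int = 10, end: int = 22):
    return tuple(rate if start <= h < end else 0.0 for h in range(24))


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A scaled-down day: enough traffic for distributional checks, fast to run.

    Arrivals stop an hour before closing so that no human device is still
    probing out of hours (which would, correctly, trip the fixed-OUI rule).
    """
    return ScenarioConfig(
        smoker_rate_per_hour=_flat_rates(15.0, 10, 21),
        passerby_rate_per_hour=_flat_rates(80.0, 10, 21),
    )


@pytest.fixture(scope="session")
def sim_day(small_scenario):
    from smokesense.simulate import generate_scenario

    return generate_scenario(small_scenario, seed=7)


def flat_rates(rate: float, start: int = 10, end: int = 22):
    return _flat_rates(rate, start, end)
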