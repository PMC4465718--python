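import pytest

from hpsirna.scenario import ScenarioConfig, build_scenario, map_scenario


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(
        seed=7,
        depths={"S-24-4D": 20_000, "S-24-13": 8_000, "S-24-15": 8_000, "WT": 8_000},
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return build_scenario(small_config)


@pytest.fixture(scope="session")
def small_mapped(small_scenario):
    return map_scenario(small_scenario)
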