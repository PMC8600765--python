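import pytest

from plexdesign import fixtures, pipeline
from plexdesign.params import DesignParameters
from plexdesign.thermo import ThermoConditions

_SCENARIOS: dict = {}
_REPORTS: dict = {}


@pytest.fixture(scope="session")
def conditions() -> ThermoConditions:
    return ThermoConditions()


@pytest.fixture(scope="session")
def params() -> DesignParameters:
    return DesignParameters()


@pytest.fixture(scope="session")
def scenario():
    """Session-cached access to the named synthetic scenarios."""
    def get(name: str, seed: int = 11) -> fixtures.Scenario:
        key = (name, seed)
        if key not in _SCENARIOS:
            _SCENARIOS[key] = fixtures.build_scenario(name, seed)
        return _SCENARIOS[key]
    return get


@pytest.fixture(scope="session")
def run_scenario(scenario):
    """Session-cached full pipeline run of a named scenario."""
    def run(name: str, seed: int = 11) -> tuple:
        key = (name, seed)
        if key not in _REPORTS:
            sc = scenario(name, seed)
            _REPORTS[key] = pipeline.run_design(
                sc.genome, sc.targets, sc.masks, sc.params,
                tag_forward=sc.spec.tag_forward,
                tag_reverse=sc.spec.tag_reverse)
        return scenario(name, seed), _REPORTS[key]
    return run
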