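import pytest

from quitsense import MessageBank, RiskConfig, SimConfig, StudyCalendar, simulate_trial


@pytest.fixture(scope="session")
def calendar():
    return StudyCalendar()


@pytest.fixture(scope="session")
def risk_config():
    return RiskConfig()


@pytest.fixture(scope="session")
def bank():
    return MessageBank.default()


@pytest.fixture(scope="session")
def small_trial():
    """A tiny but complete three-arm dataset (3 per arm, fixed seed)."""
    return simulate_trial(SimConfig(seed=1234, n_per_arm=3))


def make_response(**overrides):
    """A minimal valid prompted random-EMA response, override as needed."""
    data = dict(
        participant_id="P001",
        arm="smart_t2",
        day=10,
        time=600,
        kind="random",
        initiation="prompted",
        urge=1,
        stress=1,
        cigarette_availability=1,
        motivation_to_avoid=1,
        interacting_with_smoker=False,
        alcohol_last_hour=False,
        completed_at=602,
    )
    data.update(overrides)
    return data
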