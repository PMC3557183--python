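import pytest
from hypothesis import HealthCheck, settings

import actipet as ap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Printed fixed-mode amplitudes for the fat VOI (C11, O15, N13) and the
#: bladder VOI (C11, O15) used across round-trip tests.
VOI1_AMPLITUDES = (0.32, 0.65, 0.03)
VOI2_AMPLITUDES = (0.08, 0.92)
PHYSICAL = {"C11": 20.39, "O15": 2.04, "N13": 9.97}


@pytest.fixture(scope="session")
def schedule():
    """The study protocol: 7-min transport delay, 15 x 2-min frames."""
    return ap.default_schedule()


@pytest.fixture(scope="session")
def voi1_model():
    comps = tuple(
        ap.DecayComponent(a, t, label=lbl)
        for a, t, lbl in zip(
            VOI1_AMPLITUDES, (20.39, 2.04, 9.97), ("C11", "O15", "N13")
        )
    )
    return ap.MultiExpModel(comps)


@pytest.fixture(scope="session")
def voi1_tac(voi1_model, schedule):
    return ap.predicted_tac(voi1_model, schedule)


@pytest.fixture(scope="session")
def voi2_model():
    comps = (
        ap.DecayComponent(0.08, 20.39, label="C11"),
        ap.DecayComponent(0.92, 2.04, label="O15"),
    )
    return ap.MultiExpModel(comps)


@pytest.fixture(scope="session")
def voi2_tac(voi2_model, schedule):
    return ap.predicted_tac(voi2_model, schedule)
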