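import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_log():
    """Two players, two rounds: both cooperate, then one defects."""
    from coopeq import Move, RoundRecord

    def rec(t, pid, partner, move):
        return RoundRecord("s1", "before", t, pid, partner, Move(move))

    return [
        rec(1, "a", "b", "C"),
        rec(1, "b", "a", "C"),
        rec(2, "a", "b", "C"),
        rec(2, "b", "a", "D"),
    ]
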