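import pytest

from ergorula import PostureObservation


@pytest.fixture
def make_obs():
    """Factory for observations that deviate from a neutral standing posture
    only in the stated fields."""

    def factory(**overrides) -> PostureObservation:
        base = dict(worker_id="w01", task_id="task", task_hours=1.0)
        base.update(overrides)
        return PostureObservation(**base)

    return factory


@pytest.fixture
def neutral_obs(make_obs):
    return make_obs()
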