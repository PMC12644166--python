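import pytest
from hypothesis import settings

from umbrellas import RatingScale

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def scale06() -> RatingScale:
    """The canonical seven-point scale from 0 to 6 (k = 6)."""
    return RatingScale(0, 6)


@pytest.fixture
def scale17() -> RatingScale:
    """A 1–7 seven-point scale; shift-equivalent to 0–6."""
    return RatingScale(1, 7)
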