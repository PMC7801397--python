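import pytest

from algafame import FameProfile


@pytest.fixture
def mixed_profile() -> FameProfile:
    """Five-species profile spanning all three fatty-acid classes."""
    return FameProfile.from_pairs(
        [("C16:0", 40.0), ("C18:0", 4.0), ("C18:1", 45.0), ("C18:2", 4.0), ("C18:3n3", 2.0)],
        treatment="NS",
        day=12,
        replicate=1,
    )


@pytest.fixture
def saturated_profile() -> FameProfile:
    return FameProfile.from_pairs(
        [("C16:0", 60.0), ("C18:0", 30.0), ("C24:0", 5.0)]
    )
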