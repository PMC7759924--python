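import numpy as np
import pytest

from mirascore.survstats import SurvivalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_records(times, events, prefix="p"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


@pytest.fixture
def km_hand_example():
    """Three patients: events at 1 and 2, censoring at 3."""
    return make_records([1, 2, 3], [1, 1, 0])
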