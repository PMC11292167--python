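import numpy as np
import pytest
from hypothesis import settings

from e4mood.preprocess import Segment

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")

# a small but valid multirate layout for fast model tests
TINY_FS = {"acc_x": 4, "acc_y": 4, "acc_z": 4, "bvp": 8, "eda": 2, "temp": 1}


def make_segment(omega=8, fs=None, rng=None, label=None, subject="subjA",
                 session="subjA_s0", start=0, fill=None):
    """Build a synthetic multirate segment directly (no pipeline)."""
    fs = fs or TINY_FS
    rng = rng or np.random.default_rng(0)
    channels = {}
    for name, f in fs.items():
        n = int(omega * f)
        channels[name] = (
            np.full(n, float(fill)) if fill is not None else rng.normal(size=n)
        )
    return Segment(session_id=session, subject_id=subject, start_offset=start,
                   channels=channels, fs={k: float(v) for k, v in fs.items()},
                   label=label)


@pytest.fixture
def tiny_segment():
    return make_segment()


@pytest.fixture
def tiny_segments():
    rng = np.random.default_rng(1)
    return [
        make_segment(rng=rng, label="acute" if i % 2 else "euthymia",
                     subject=f"s{i % 4}", session=f"s{i % 4}_r0", start=10 * i)
        for i in range(8)
    ]
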