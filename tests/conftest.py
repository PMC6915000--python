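import numpy as np
import pytest

from gaitsf import AngleCycle, Group, Joint, NormalizedCurve, Side


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_cycle(angles, times=None, joint=Joint.HIP, side=Side.RIGHT, **kw):
    angles = np.asarray(angles, dtype=float)
    if times is None:
        times = np.arange(angles.size) / 120.0
    defaults = dict(subject_id="S1", group=Group.NORMAL, cycle_index=0)
    defaults.update(kw)
    return AngleCycle(times=times, angles=angles, joint=joint, side=side, **defaults)


def make_curve(values, joint=Joint.HIP, side=Side.RIGHT, **kw):
    return NormalizedCurve(values=np.asarray(values, dtype=float), joint=joint, side=side, **kw)


@pytest.fixture
def cosine_curve():
    """101-point single-harmonic curve: mean 10, amplitude 2.5, range 5."""
    t = np.arange(101.0)
    return make_curve(10.0 + 2.5 * np.cos(2 * np.pi * t / 100.0))
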