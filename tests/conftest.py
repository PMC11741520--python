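import numpy as np
import pytest

from kisspulse import DffTrace, LHSeries


@pytest.fixture
def flat_trace():
    """Flat zero dF/F trace, 10 Hz, 60 s."""
    t = np.arange(0, 60, 0.1)
    return DffTrace.from_values(t=t, dff=np.zeros_like(t))


def make_trace(dff, dt=0.1):
    dff = np.asarray(dff, dtype=float)
    return DffTrace.from_values(t=np.arange(dff.size) * dt, dff=dff)


def make_lh(conc, interval=6.0):
    conc = np.asarray(conc, dtype=float)
    return LHSeries(t=np.arange(conc.size) * interval, conc=conc)


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def lh_factory():
    return make_lh
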