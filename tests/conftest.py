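import numpy as np
import pytest

from thermolba.lba import LBACellParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def typical_params():
    """Mid-range LBA parameters for a deadline task."""
    return LBACellParams(A=0.5, B=0.7, v_correct=2.5, delta_v=1.0,
                         s_error=0.8, t0=0.2)
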