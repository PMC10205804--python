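import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from corvidsim.motivation import MotivationParameters, MotivationState


@pytest.fixture
def mparams():
    return MotivationParameters(tau_s=5.0, tau_d=10.0, tau_h=100.0,
                                n={"worm": 0.5, "peanut": 0.3}, c0=0.5)


@pytest.fixture
def mstate():
    return MotivationState.initial(["worm", "peanut"], h0=1.0)
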