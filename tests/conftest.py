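import numpy as np
import pytest

from atcfes import make_activation_profile, synthesize_semg


@pytest.fixture
def env3():
    """Three 4 s repetitions separated by 3 s rest, 80 Hz grid."""
    return make_activation_profile(n_reps=3, rep_duration_s=4.0, rest_s=3.0)


@pytest.fixture
def rest_semg():
    """Conditioning-band noise at rest (activation 0), 5 s at 2 kHz."""
    env = make_activation_profile(1, 1.0, 2.0)
    zero = type(env)(t=env.t, a=np.zeros_like(env.a))
    return synthesize_semg(zero, seed=11)


@pytest.fixture
def active_semg(env3):
    return synthesize_semg(env3, seed=7)
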