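import numpy as np
import pytest

from kinkscan.synthetic_data import StepParameterProfile, build_duplex

IDEAL_SEQUENCE = "GCGTATACGCG"  # 11 bp, central TA-rich stretch


@pytest.fixture
def ideal_profile():
    return StepParameterProfile.ideal(IDEAL_SEQUENCE)


@pytest.fixture
def ideal_model(ideal_profile):
    return build_duplex(ideal_profile)


@pytest.fixture
def kinked_profile(ideal_profile):
    """50 deg roll planted at step 5 (the AT step), rest ideal."""
    return ideal_profile.with_roll(5, 50.0)


@pytest.fixture
def kinked_model(kinked_profile):
    return build_duplex(kinked_profile)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_profile(rng, n=None, shift_slide=0.0):
    """Random step-parameter profile within the round-trip domain:
    |roll|, |tilt| <= 60 deg, twist 20-45 deg, rise 2.5-4.5 A."""
    n = n or int(rng.integers(6, 14))
    seq = "".join(rng.choice(list("ACGT"), n))
    m = n - 1
    steps = np.column_stack([
        rng.uniform(-shift_slide, shift_slide, m) if shift_slide else np.zeros(m),
        rng.uniform(-shift_slide, shift_slide, m) if shift_slide else np.zeros(m),
        rng.uniform(2.5, 4.5, m),
        rng.uniform(-60, 60, m),
        rng.uniform(-60, 60, m),
        rng.uniform(20, 45, m),
    ])
    return StepParameterProfile(seq, steps)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
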