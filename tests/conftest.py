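import pytest

import rehabkit as rk


@pytest.fixture(scope="session")
def upper_exercise():
    return rk.get_exercise("bobath_handshake")


@pytest.fixture(scope="session")
def hand_exercise():
    return rk.get_exercise("wrist_flexion_extension")


@pytest.fixture(scope="session")
def lower_exercise():
    return rk.get_exercise("squat")


@pytest.fixture(scope="session")
def clean_stream(upper_exercise):
    """Noise-free 5-repetition bout of a limb exercise, amplitude 2 g."""
    params = rk.SynthParams(n_reps=5, amplitude=2.0, noise_sd=0.0, seed=7)
    return rk.generate_session(upper_exercise, params)


@pytest.fixture(scope="session")
def glove_stream(hand_exercise):
    """Noise-free 5-repetition hand bout, 45-degree wrist pitch amplitude."""
    params = rk.SynthParams(n_reps=5, amplitude=45.0, noise_sd=0.0, seed=11)
    return rk.generate_session(hand_exercise, params)
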