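import numpy as np
import pytest

import dualadapt as da


@pytest.fixture(scope="session")
def exp1_config():
    return da.ExperimentConfig.exp1()


@pytest.fixture(scope="session")
def exp2_config():
    return da.ExperimentConfig.exp2()


@pytest.fixture(scope="session")
def true_model():
    """Default ground-truth model: two-fast-weighted-triple-rate medians."""
    return da.ModelSpec.from_id("2f_3s_wgt"), da.TABLE1_MEDIANS["2f_3s_wgt"]


@pytest.fixture(scope="session")
def exp1_dataset(true_model, exp1_config):
    spec, params = true_model
    return da.generate_participant(spec, params, exp1_config,
                                   da.NOISE_HALFWIDTH["exp1"], seed=11)


@pytest.fixture(scope="session")
def exp2_dataset(true_model, exp2_config):
    spec, params = true_model
    return da.generate_participant(spec, params, exp2_config,
                                   da.NOISE_HALFWIDTH["exp2"], seed=12)


@pytest.fixture(scope="session")
def exp2_noise_free(true_model, exp2_config):
    spec, params = true_model
    return da.generate_participant(spec, params, exp2_config, 0.0, seed=13)


def classic_two_state(A_f, B_f, A_s, B_s, field_sign, is_channel):
    """Independent reference implementation of the classic two-state
    (fast+slow) single-task model; used as an oracle."""
    xf = xs = 0.0
    outputs = []
    for f, ch in zip(field_sign, is_channel):
        x = xf + xs
        outputs.append(x)
        e = 0.0 if ch else f - x
        xf = A_f * xf + B_f * e
        xs = A_s * xs + B_s * e
    return np.array(outputs)
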