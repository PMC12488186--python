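import warnings

import numpy as np
import pandas as pd
import pytest

import tempocontext as tc


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the informational warnings the generators emit on purpose."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def exp2_session():
    """One labeled Experiment-2-style session (biased repeats, 75%)."""
    cfg = tc.SimConfig(n_blocks=4, trials_per_block=100, n_sensors=12,
                       sample_rate=64.0)
    truth = tc.GroundTruth()
    bias = tc.BiasSpec(p_repeat=0.75, second_plane_p_repeat=0.75)
    rng = np.random.default_rng(42)
    trials = tc.synth.make_trial_table(cfg, bias, truth, rng)
    return {"config": cfg, "truth": truth, "bias": bias, "trials": trials}


@pytest.fixture(scope="session")
def signal_epochs():
    """Small sensor-epoch set with a clean planted angle signal."""
    cfg = tc.SimConfig(n_blocks=2, trials_per_block=100, n_sensors=10,
                       sample_rate=64.0)
    truth = tc.GroundTruth(noise_sd=0.5, drift_sd=0.0)
    rng = np.random.default_rng(7)
    angles = rng.uniform(0, 360, cfg.n_trials)
    epochs = tc.synth.gen_epochs(angles, None, truth, cfg, rng)
    return epochs


def wrapped_abs_error(a, b):
    """|a - b| on the circle, degrees."""
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)
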