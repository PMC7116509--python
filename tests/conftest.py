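import copy

import numpy as np
import pytest

from nmrlineshape.binding import ModelParameters, uM
from nmrlineshape.examples import calibration_study, two_state_study
from nmrlineshape.fitting import TitrationLineshapeModel
from nmrlineshape.synthesis import generate_synthetic_titration


def perturbed_spins(spins, d_dI=0.02, d_dS=-0.05, r2=20.0):
    """Truth spins with shifted initial guesses and reset linewidths."""
    out = copy.deepcopy(spins)
    for s in out:
        for state, res in s.states.items():
            if state != "P":
                res.dI -= 2 * d_dI
                res.dS -= 2 * d_dS
            else:
                res.dI += d_dI
                res.dS += d_dS
            res.R2I = r2
            res.R2S = r2
    return out


@pytest.fixture(scope="session")
def noiseless_small():
    """Single-spin 5-point noiseless dataset on the scaled-down grid."""
    truth, design, cfg, proc = calibration_study(snr=None)
    truth.snr = None
    dataset = generate_synthetic_titration(truth, design, cfg, proc)
    return truth, dataset


@pytest.fixture(scope="session")
def noisy_small():
    """Single-spin 5-point dataset at SNR 50 (seed 0)."""
    truth, design, cfg, proc = calibration_study(seed=0, snr=50.0)
    dataset = generate_synthetic_titration(truth, design, cfg, proc)
    return truth, dataset


@pytest.fixture(scope="session")
def noisy_big():
    """Two-spin 9-point titration at SNR 50 on the 64x128 grid."""
    truth, design, cfg, proc = two_state_study(snr=50.0, seed=7)
    dataset = generate_synthetic_titration(truth, design, cfg, proc)
    return truth, dataset


@pytest.fixture()
def small_model(noiseless_small):
    truth, dataset = noiseless_small
    return TitrationLineshapeModel(
        dataset, "two_state",
        ModelParameters({"K_d": 20 * uM, "k_off": 100.0}),
        copy.deepcopy(truth.spins),
    )
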