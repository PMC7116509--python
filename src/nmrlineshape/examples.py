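"""Ready-made synthetic study setups used in the docs and the test suite.

`two_state_study` is the canonical worked example: a 9-point titration of a
100 uM protein with a two-state ligand interaction (K_d = 20 uM,
k_off = 100 s^-1), observed through two amide spin systems that sample
different exchange regimes (one with a large ^1H shift change in
slow-intermediate exchange, one with a small shift change in fast
exchange).  Grids are kept small (64 x 128 complex points) so a full
generate -> fit -> bootstrap cycle runs in seconds to minutes.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

from .binding import ModelParameters, uM, mM
from .processing import ProcessingParams
from .spectrometer import PulseSequenceConfig
from .spins import ROI, SpinSystem, StateResonance
from .synthesis import DEFAULT_SCHEDULE, GroundTruth, TitrationDesign, design_titration

__all__ = ["two_state_study", "calibration_study", "fig_regime_conditions"]


def two_state_study(
    K_d: float = 20 * uM,
    k_off: float = 100.0,
    P0: float = 100 * uM,
    stock_L: float = 10 * mM,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    snr: Optional[float] = None,
    noise_sigma: Optional[float] = None,
    seed: int = 0,
    n_H: int = 128,
    n_S: int = 64,
) -> Tuple[GroundTruth, TitrationDesign, PulseSequenceConfig, ProcessingParams]:
    """Two-spin, two-state titration ground truth plus acquisition setup."""
    design = design_titration(P0=P0, V0=550.0, stock_L=stock_L,
                              schedule=schedule)
    params = ModelParameters({"K_d": K_d, "k_off": k_off})
    spins = [
        SpinSystem(
            "A1",
            {
                "P": StateResonance(8.10, 118.6, 18.0, 15.0),
                "PL": StateResonance(8.40, 119.4, 22.0, 18.0),
            },
            roi=ROI.box((7.95, 8.55), (118.0, 119.8)),
        ),
        SpinSystem(
            "A2",
            {
                "P": StateResonance(8.60, 121.0, 16.0, 14.0),
                "PL": StateResonance(8.55, 120.4, 20.0, 16.0),
            },
            roi=ROI.box((8.40, 8.75), (120.0, 121.6)),
        ),
    ]
    truth = GroundTruth(model="two_state", params=params, spins=spins,
                        snr=snr, noise_sigma=noise_sigma, seed=seed)
    config = PulseSequenceConfig(
        experiment="HSQC", f_spec_H=700.0, offset_H=8.30, offset_S=119.8,
        sw_H=2000.0, sw_S=450.0, n_H=n_H, n_S=n_S, J_HNHA=0.0,
    )
    proc = ProcessingParams(lb_H=4.0, lb_S=8.0)
    return truth, design, config, proc


def calibration_study(
    seed: int = 0,
    snr: float = 50.0,
    K_d: float = 20 * uM,
    k_off: float = 100.0,
) -> Tuple[GroundTruth, TitrationDesign, PulseSequenceConfig, ProcessingParams]:
    """Single-spin, 5-point study for Monte-Carlo/bootstrap calibration.

    Deliberately small (32 x 64 acquired points) and processed at the
    acquired resolution without line broadening, so the frequency-domain
    noise stays uncorrelated and the pooled residual-resampling bootstrap is
    directly comparable with the scatter over independent noise
    realizations.
    """
    design = design_titration(P0=100 * uM, V0=550.0, stock_L=10 * mM,
                              schedule=(0.0, 0.25, 0.6, 1.15, 1.9))
    params = ModelParameters({"K_d": K_d, "k_off": k_off})
    spins = [SpinSystem(
        "A1",
        {
            "P": StateResonance(8.10, 118.6, 18.0, 15.0),
            "PL": StateResonance(8.40, 119.4, 22.0, 18.0),
        },
        roi=ROI.box((7.9, 8.6), (117.9, 120.1)),
    )]
    truth = GroundTruth(model="two_state", params=params, spins=spins,
                        snr=snr, seed=seed)
    config = PulseSequenceConfig(
        experiment="HSQC", f_spec_H=700.0, offset_H=8.25, offset_S=119.0,
        sw_H=1200.0, sw_S=300.0, n_H=64, n_S=32, J_HNHA=0.0,
    )
    proc = ProcessingParams(lb_H=0.0, lb_S=0.0, zf_H=64, zf_S=32)
    return truth, design, config, proc


def fig_regime_conditions(
    n_H: int = 256, n_S: int = 128
) -> Tuple[SpinSystem, PulseSequenceConfig, ProcessingParams]:
    """Single-spin setup matching the classic exchange-regime illustration:
    700 MHz, 1 mM protein, K_d = 2 uM, shift differences of 1 ppm (^1H) and
    0.5 ppm (^15N)."""
    spin = SpinSystem(
        "R1",
        {
            "P": StateResonance(8.20, 119.0, 20.0, 20.0),
            "PL": StateResonance(9.20, 119.5, 20.0, 20.0),
        },
        roi=ROI.box((7.8, 9.6), (118.4, 120.1)),
    )
    config = PulseSequenceConfig(
        experiment="HSQC", f_spec_H=700.0, offset_H=8.70, offset_S=119.25,
        sw_H=2800.0, sw_S=450.0, n_H=n_H, n_S=n_S, J_HNHA=0.0,
    )
    proc = ProcessingParams(lb_H=10.0, lb_S=10.0)
    return spin, config, proc
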