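"""Virtual spectrometer: Bloch-McConnell propagation through 2D pulse sequences.

The magnetization of a spin group is represented on a composite basis of
(spin, model-state) components; chemical exchange mixes the state block of
each spin through the first-order rate matrix ``K`` while chemical shift
evolution and transverse relaxation act on the diagonal.  Propagating an
initial vector proportional to the equilibrium state populations through the
pulse sequence — ideal pulses, exchange-coupled evolution during delays and
acquisition — yields a complex 2D interferogram that is processed exactly
like the experimental data.

Supported experiments are HSQC, HMQC and SOFAST-HMQC.  In the HSQC the
indirect dimension evolves single-quantum ^15N coherence; in the HMQC the
zero- and double-quantum coherences evolve (sensitive to exchange in both
the ^1H and ^15N shifts) with the mid-t1 ^1H refocusing pulse implemented as
a ZQ<->DQ swap, so the net t1 frequency is the ^15N shift while exchange
broadening acts on both coherences.  TROSY-type and sensitivity-enhanced
sequences involve transfer dynamics outside this model and raise
:class:`~nmrlineshape.errors.UnsupportedExperimentError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg

from .binding import BindingModel, ModelParameters, get_model
from .errors import (
    ConfigurationError,
    InvalidArgumentError,
    UnsupportedExperimentError,
)
from .spins import SpinGroup

__all__ = [
    "GAMMA_RATIO_N_H",
    "PulseSequenceConfig",
    "Interferogram",
    "delta_omega",
    "direct_evolution_generator",
    "indirect_evolution_generators",
    "transfer_propagator",
    "simulate_interferogram",
    "simulate_group",
]

#: magnitude of the ^15N/^1H gyromagnetic-ratio (frequency) ratio
GAMMA_RATIO_N_H = 0.10136767

SUPPORTED_EXPERIMENTS = ("HSQC", "HMQC", "SOFAST_HMQC")


def delta_omega(delta_ppm: float, f_spec_MHz: float) -> float:
    """Angular frequency difference (rad/s) for a shift difference in ppm at
    the given spectrometer frequency (MHz): ``2*pi * f_MHz * ppm``."""
    return 2.0 * math.pi * f_spec_MHz * delta_ppm


@dataclass
class PulseSequenceConfig:
    """Experiment type, frequencies, grids, couplings and delays.

    ``f_spec_H``/``f_spec_S`` are the ^1H and ^15N spectrometer frequencies
    in MHz (``f_spec_S`` defaults to the gyromagnetic-ratio value);
    ``offset_*`` are carrier positions in ppm; sweep widths in Hz; ``n_*``
    are acquired complex points.  ``J_IS`` is the one-bond H-N coupling
    (~92 Hz); ``J_HNHA`` the three-bond HN-HA coupling active during
    acquisition (~6.5 Hz, 0 for perdeuterated samples).  The INEPT transfer
    delay defaults to 1/(4 J_IS); optional zz-filter and gradient-selection
    delays propagate exchange through those periods of the HSQC.
    """

    experiment: str = "HSQC"
    f_spec_H: float = 700.0
    f_spec_S: Optional[float] = None
    offset_H: float = 8.2
    offset_S: float = 119.0
    sw_H: float = 2000.0
    sw_S: float = 600.0
    n_H: int = 128
    n_S: int = 64
    J_IS: float = 92.0
    J_HNHA: float = 6.5
    inept_delay: Optional[float] = None
    zz_delay: float = 0.0
    grad_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.experiment not in SUPPORTED_EXPERIMENTS:
            raise UnsupportedExperimentError(
                f"experiment {self.experiment!r} is not implemented; "
                f"supported: {SUPPORTED_EXPERIMENTS} (TROSY and "
                f"sensitivity-enhanced variants are intentionally excluded)"
            )
        if self.f_spec_S is None:
            self.f_spec_S = self.f_spec_H * GAMMA_RATIO_N_H
        if min(self.f_spec_H, self.f_spec_S, self.sw_H, self.sw_S) <= 0:
            raise InvalidArgumentError("frequencies and sweep widths must be > 0")
        if self.n_H < 2 or self.n_S < 2:
            raise InvalidArgumentError("need at least 2 complex points per dim")
        ratio = self.f_spec_S / self.f_spec_H
        if abs(ratio / GAMMA_RATIO_N_H - 1.0) > 0.01:
            raise InvalidArgumentError(
                f"f_spec_S/f_spec_H = {ratio:.5f} is inconsistent with the "
                f"^15N/^1H gyromagnetic ratio ({GAMMA_RATIO_N_H})"
            )
        if self.J_HNHA < 0:
            raise InvalidArgumentError("J_HNHA must be >= 0")
        if self.inept_delay is None:
            self.inept_delay = 1.0 / (4.0 * self.J_IS)
        if self.inept_delay < 0 or self.zz_delay < 0 or self.grad_delay < 0:
            raise InvalidArgumentError("delays must be non-negative")

    @property
    def dwell_H(self) -> float:
        return 1.0 / self.sw_H

    @property
    def dwell_S(self) -> float:
        return 1.0 / self.sw_S


@dataclass
class Interferogram:
    """Hypercomplex 2D time-domain signal (States quadrature in t1).

    ``cos`` and ``sin`` are the two t1-quadrature components, each complex
    in t2, with shape ``(n_S, n_H)``.  t1 is sampled at half-dwell offsets
    ``(n + 1/2)/sw_S``; t2 starts at zero.
    """

    cos: np.ndarray
    sin: np.ndarray
    dwell_t1: float
    dwell_t2: float
    scale: float = 1.0  # P_tot * ns * rg amplitude factor actually applied

    def __post_init__(self) -> None:
        if self.cos.shape != self.sin.shape:
            raise ConfigurationError("quadrature planes must have equal shape")
        if not (np.all(np.isfinite(self.cos)) and np.all(np.isfinite(self.sin))):
            raise ConfigurationError("interferogram contains non-finite values")

    def __add__(self, other: "Interferogram") -> "Interferogram":
        if self.cos.shape != other.cos.shape:
            raise ConfigurationError("cannot add interferograms of unequal shape")
        return Interferogram(self.cos + other.cos, self.sin + other.sin,
                             self.dwell_t1, self.dwell_t2, self.scale)


# ---------------------------------------------------------------------------
# generator construction


def _group_arrays(group: SpinGroup, states: Sequence[str], config: PulseSequenceConfig):
    """Flatten group resonance parameters onto the composite (spin, state)
    basis.  Indirect-dimension shifts are wrapped onto the acquired sweep
    width (modular aliasing of folded peaks); the direct dimension is not
    folded."""
    n_spins, n_states = len(group.members), len(states)
    omega_H = np.empty(n_spins * n_states)
    omega_S = np.empty(n_spins * n_states)
    r2i = np.empty(n_spins * n_states)
    r2s = np.empty(n_spins * n_states)
    for s, spin in enumerate(group.members):
        for k, state in enumerate(states):
            if state not in spin.states:
                raise ConfigurationError(
                    f"spin {spin.label!r} lacks state {state!r} required by "
                    f"the binding model"
                )
            res = spin.states[state]
            i = s * n_states + k
            omega_H[i] = 2 * np.pi * (res.dI - config.offset_H) * config.f_spec_H
            off_hz = (res.dS - config.offset_S) * config.f_spec_S
            wrapped = (off_hz + config.sw_S / 2.0) % config.sw_S - config.sw_S / 2.0
            omega_S[i] = 2 * np.pi * wrapped
            r2i[i] = res.R2I
            r2s[i] = res.R2S
    return omega_H, omega_S, r2i, r2s


def _k_big(K: np.ndarray, n_spins: int) -> np.ndarray:
    if n_spins == 1:
        return K
    return np.kron(np.eye(n_spins), K)


def direct_evolution_generator(
    group: SpinGroup,
    K: np.ndarray,
    config: PulseSequenceConfig,
    states: Sequence[str],
) -> List[np.ndarray]:
    """Acquisition-dimension generators, one per J_HNHA doublet component.

    Each is ``i diag(Omega_H +/- pi J_HNHA) - diag(R2I) + K`` on the
    composite basis (detected with weight 1/2 each)."""
    omega_H, _, r2i, _ = _group_arrays(group, states, config)
    Kb = _k_big(K, len(group.members))
    if Kb.shape[0] != omega_H.size:
        raise ConfigurationError(
            "rate-matrix dimension does not match the number of model states"
        )
    out = []
    for sign in (+1.0, -1.0):
        out.append(
            np.diag(1j * (omega_H + sign * np.pi * config.J_HNHA) - r2i) + Kb
        )
    return out


def indirect_evolution_generators(
    group: SpinGroup,
    K: np.ndarray,
    config: PulseSequenceConfig,
    states: Sequence[str],
) -> List[np.ndarray]:
    """t1 generators: ``[L_SQ]`` for HSQC, ``[L_ZQ, L_DQ]`` for (SOFAST-)HMQC.

    HSQC evolves single-quantum ^15N coherence,
    ``i diag(Omega_N) - diag(R2S) + K``; the HMQC zero/double-quantum
    coherences evolve at ``Omega_N -/+ Omega_H`` and are interchanged by the
    mid-t1 ^1H 180, so the net t1 frequency is Omega_N while exchange acts
    on both coherences."""
    omega_H, omega_S, _, r2s = _group_arrays(group, states, config)
    Kb = _k_big(K, len(group.members))
    if config.experiment == "HSQC":
        return [np.diag(1j * omega_S - r2s) + Kb]
    return [
        np.diag(1j * (omega_S - omega_H) - r2s) + Kb,  # zero quantum
        np.diag(1j * (omega_S + omega_H) - r2s) + Kb,  # double quantum
    ]


def transfer_propagator(
    K: np.ndarray,
    delays: Sequence[Tuple[float, str]],
    r2i: Optional[np.ndarray] = None,
    r2s: Optional[np.ndarray] = None,
    J_IS: Optional[float] = None,
) -> np.ndarray:
    """Product of exchange propagators over a list of (duration, coherence)
    segments.

    Coherence types: ``"zz"`` (longitudinal: exchange only), ``"inept"`` and
    ``"transverse_I"`` (exchange + R2I; ``"inept"`` additionally scales by
    the J transfer amplitude ``sin(pi J_IS * 2 delta)``), ``"transverse_S"``
    (exchange + R2S).  Chemical shift precession is refocused in all
    segments (ideal 180 pulses)."""
    n = K.shape[0]
    P = np.eye(n)
    for duration, kind in delays:
        if duration < 0:
            raise InvalidArgumentError("delay durations must be >= 0")
        if duration == 0.0:
            continue
        if kind == "zz":
            G = K
        elif kind in ("inept", "transverse_I"):
            if r2i is None:
                raise InvalidArgumentError(f"{kind} segment requires R2I rates")
            G = K - np.diag(r2i)
        elif kind == "transverse_S":
            if r2s is None:
                raise InvalidArgumentError("transverse_S segment requires R2S rates")
            G = K - np.diag(r2s)
        else:
            raise InvalidArgumentError(f"unknown coherence type {kind!r}")
        seg = scipy.linalg.expm(G * duration)
        if kind == "inept":
            if J_IS is None:
                raise InvalidArgumentError("inept segment requires J_IS")
            seg = seg * math.sin(math.pi * J_IS * duration)
        P = seg @ P
    return P


# ---------------------------------------------------------------------------
# evolution on time grids


def _eig_or_none(L: np.ndarray):
    """Eigendecomposition if well conditioned, else None (defective)."""
    lam, V = np.linalg.eig(L)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    # cheap 1-norm condition estimate (an upper-bound proxy for cond_2)
    if np.abs(V).sum(axis=0).max() * np.abs(Vinv).sum(axis=0).max() > 1e12:
        return None
    return lam, V, Vinv


def _evolve_vector_on_grid(L: np.ndarray, times: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Columns ``expm(L t) v`` for each t; eigendecomposition with a
    scaling-and-squaring (stepwise expm) fallback for defective generators
    on uniform grids."""
    dec = _eig_or_none(L)
    if dec is not None:
        lam, V, Vinv = dec
        B = Vinv @ v.astype(complex)
        return V @ (np.exp(np.outer(lam, times)) * B[:, None])
    # uniform-grid fallback
    dt = times[1] - times[0] if len(times) > 1 else times[0]
    E0 = scipy.linalg.expm(L * times[0])
    E = scipy.linalg.expm(L * dt)
    out = np.empty((L.shape[0], len(times)), dtype=complex)
    w = E0 @ v.astype(complex)
    for i in range(len(times)):
        out[:, i] = w
        w = E @ w
    return out


def _detect_t2(L2: np.ndarray, M: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Signal matrix s[t1, t2] = 1^T expm(L2 t2) M[:, t1]."""
    dec = _eig_or_none(L2)
    n = L2.shape[0]
    ones = np.ones(n)
    if dec is not None:
        lam, V, Vinv = dec
        w = ones @ V
        G = Vinv @ M.astype(complex)
        return (G * w[:, None]).T @ np.exp(np.outer(lam, t2))
    dt = t2[1] - t2[0] if len(t2) > 1 else 1.0
    E = scipy.linalg.expm(L2 * dt)
    E0 = scipy.linalg.expm(L2 * t2[0])
    out = np.empty((M.shape[1], len(t2)), dtype=complex)
    W = E0 @ M.astype(complex)
    for j in range(len(t2)):
        out[:, j] = ones @ W
        W = E @ W
    return out


def _hmqc_t1_matrix(L_zq: np.ndarray, L_dq: np.ndarray,
                    t1: np.ndarray, v: np.ndarray) -> np.ndarray:
    """ZQ/DQ evolution with the mid-t1 swap:
    A(t1) v = 1/2 [E_zq(t1/2) E_dq(t1/2) + E_dq(t1/2) E_zq(t1/2)] v."""
    dec_z = _eig_or_none(L_zq)
    dec_d = _eig_or_none(L_dq)
    n = L_zq.shape[0]
    out = np.empty((n, len(t1)), dtype=complex)
    if dec_z is not None and dec_d is not None:
        lam_z, Vz, Vzi = dec_z
        lam_d, Vd, Vdi = dec_d
        vz = Vzi @ v.astype(complex)
        vd = Vdi @ v.astype(complex)
        for i, t in enumerate(t1):
            Ez = Vz @ (np.exp(lam_z * t / 2)[:, None] * Vzi)
            Ed = Vd @ (np.exp(lam_d * t / 2)[:, None] * Vdi)
            out[:, i] = 0.5 * (Ez @ (Ed @ v) + Ed @ (Ez @ v))
        return out
    for i, t in enumerate(t1):
        Ez = scipy.linalg.expm(L_zq * t / 2)
        Ed = scipy.linalg.expm(L_dq * t / 2)
        out[:, i] = 0.5 * (Ez @ (Ed @ v) + Ed @ (Ez @ v))
    return out


# ---------------------------------------------------------------------------
# full sequence


def simulate_group(
    group: SpinGroup,
    K: np.ndarray,
    populations: np.ndarray,
    amplitude: float,
    config: PulseSequenceConfig,
    states: Sequence[str],
) -> Interferogram:
    """Propagate one spin group through the pulse sequence.

    ``populations`` are the equilibrium state fractions (one set, shared by
    every spin of the group); ``amplitude`` is the P_tot * ns * rg scale.
    """
    n_spins = len(group.members)
    n_states = len(states)
    if K.shape != (n_states, n_states):
        raise ConfigurationError(
            f"rate matrix is {K.shape}, expected ({n_states}, {n_states})"
        )
    omega_H, omega_S, r2i, r2s = _group_arrays(group, states, config)
    Kb = _k_big(K, n_spins)
    n = n_spins * n_states

    p0 = amplitude * np.tile(np.asarray(populations, dtype=float), n_spins)

    delta = config.inept_delay
    if config.experiment == "HSQC":
        pre = [(2 * delta, "inept")]
        if config.zz_delay > 0:
            pre.append((config.zz_delay, "zz"))
        post: List[Tuple[float, str]] = []
        if config.grad_delay > 0:
            post.append((config.grad_delay, "transverse_S"))
        post.append((2 * delta, "inept"))
    else:  # HMQC / SOFAST_HMQC: J_IS defocus/refocus periods on transverse 1H
        pre = [(2 * delta, "inept")]
        post = [(2 * delta, "inept")]
    T_pre = transfer_propagator(Kb, pre, r2i=r2i, r2s=r2s, J_IS=config.J_IS)
    T_post = transfer_propagator(Kb, post, r2i=r2i, r2s=r2s, J_IS=config.J_IS)

    t1 = (np.arange(config.n_S) + 0.5) * config.dwell_S
    t2 = np.arange(config.n_H) * config.dwell_H

    v1 = T_pre @ p0
    gens1 = indirect_evolution_generators(group, K, config, states)
    if len(gens1) == 1:
        M = _evolve_vector_on_grid(gens1[0], t1, v1)
    else:
        M = _hmqc_t1_matrix(gens1[0], gens1[1], t1, v1)

    M_cos = T_post @ np.real(M)
    M_sin = T_post @ np.imag(M)

    gens2 = direct_evolution_generator(group, K, config, states)
    if config.J_HNHA == 0.0:
        gens2 = gens2[:1]  # degenerate doublet: one component, full weight
    weight = 1.0 / len(gens2)
    s_cos = np.zeros((config.n_S, config.n_H), dtype=complex)
    s_sin = np.zeros_like(s_cos)
    for L2 in gens2:
        s_cos += weight * _detect_t2(L2, M_cos, t2)
        s_sin += weight * _detect_t2(L2, M_sin, t2)

    return Interferogram(s_cos, s_sin, config.dwell_S, config.dwell_H,
                         scale=amplitude)


def simulate_interferogram(
    group: SpinGroup,
    model: BindingModel | str,
    params: ModelParameters,
    P_tot: float,
    L_tot: float,
    config: PulseSequenceConfig,
    ns: int = 1,
    rg: float = 1.0,
) -> Interferogram:
    """Solve the equilibrium at one titration point and simulate the group.

    The initial amplitudes are proportional to the equilibrium state
    fractions times ``P_tot * ns * rg``, so spectra across a titration share
    a single absolute scale and no per-spectrum normalization is needed.
    """
    if isinstance(model, str):
        model = get_model(model)
    eq = model.solve(params, P_tot, L_tot)
    K = model.rate_matrix(params, eq.free_ligand)
    amplitude = P_tot * ns * rg
    return simulate_group(group, K, eq.fractions, amplitude, config, model.states)
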