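"""Binding/exchange models: equilibrium populations and first-order rate matrices.

Each model describes a kinetic scheme connecting a small number of protein
states (free, bound, open, closed, ...).  At every titration point the model
is solved for the equilibrium state populations and the free-ligand
concentration, and a first-order exchange rate matrix ``K`` is assembled in
which association steps enter with pseudo-first-order rates ``k_on * [L]``.

Concentrations are molar throughout the package; the convenience constants
``uM`` and ``mM`` are provided for interface code.  Equilibrium constants are
concentrations (K_d) or dimensionless ratios (K_AB); all rates are s^-1.
Association rate constants are always derived as ``k_on = k_off / K_d`` and
never stored independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidArgumentError, SolverError

__all__ = [
    "uM",
    "mM",
    "ModelParameters",
    "EquilibriumPopulations",
    "BindingModel",
    "get_model",
    "available_models",
    "free_ligand_concentration",
    "exchange_rate",
    "closed_cycle_kd4",
    "build_rate_matrix",
    "solve_equilibrium",
]

uM = 1e-6
mM = 1e-3

#: default box bounds used when the user does not specify any
_DEFAULT_BOUNDS = {
    "K_d": (1e-12, 1.0),
    "K_d_app": (1e-12, 1.0),
    "K_d1": (1e-12, 1.0),
    "K_d2": (1e-12, 1.0),
    "K_d3": (1e-12, 1.0),
    "k_off": (1e-4, 1e8),
    "k_off_A": (1e-4, 1e8),
    "k_off_B": (1e-4, 1e8),
    "k_off1": (1e-4, 1e8),
    "k_off2": (1e-4, 1e8),
    "k_off3": (1e-4, 1e8),
    "k_off4": (1e-4, 1e8),
    "k_open": (1e-4, 1e8),
    "k_close": (1e-4, 1e8),
    "k_ex": (1e-4, 1e8),
    "k_ex2": (1e-4, 1e8),
    "K_AB": (1e-8, 1e8),
    "K_AB2": (1e-8, 1e8),
    "n": (0.1, 10.0),
}


@dataclass
class ModelParameters:
    """Thermodynamic and kinetic constants with bounds and fit flags.

    ``values`` maps parameter names (``K_d``, ``k_off``, ...) to numbers;
    ``bounds`` and ``vary`` are optional per-parameter overrides.  All rates
    and equilibrium constants must be strictly positive.
    """

    values: Dict[str, float]
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    vary: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise InvalidArgumentError(
                    f"model parameter {name!r} must be strictly positive, got {v}"
                )
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise InvalidArgumentError(
                    f"bounds for {name!r} must satisfy min < max, got ({lo}, {hi})"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get_bounds(self, name: str) -> Tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        return _DEFAULT_BOUNDS.get(name, (1e-12, 1e12))

    def get_vary(self, name: str, default: bool = True) -> bool:
        return self.vary.get(name, default)

    def copy(self) -> "ModelParameters":
        return ModelParameters(dict(self.values), dict(self.bounds), dict(self.vary))


@dataclass
class EquilibriumPopulations:
    """State fractions (per observed protein molecule) and free-ligand level."""

    states: Tuple[str, ...]
    fractions: np.ndarray
    free_ligand: float

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise SolverError(
                f"state fractions sum to {self.fractions.sum()!r}, expected 1"
            )

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.states, self.fractions))


def free_ligand_concentration(P_tot: float, L_tot: float, K_d: float) -> float:
    """Free-ligand concentration for two-state 1:1 binding (closed form).

    Solves the mass-balance quadratic
    ``K_d * (L_tot - L) = L * (P_tot - L_tot + L)`` for the physical root::

        [L] = 1/2 * { L_tot - P_tot - K_d
                      + sqrt((L_tot + P_tot + K_d)^2 - 4 P_tot L_tot) }
    """
    if P_tot < 0 or L_tot < 0:
        raise InvalidArgumentError("total concentrations must be non-negative")
    if K_d <= 0:
        raise InvalidArgumentError("K_d must be strictly positive")
    # quadratic L^2 + b L - K_d L_tot = 0 with b = P_tot - L_tot + K_d;
    # pick the cancellation-free expression of the physical root
    b = P_tot - L_tot + K_d
    disc = math.sqrt(b * b + 4.0 * K_d * L_tot)
    if b > 0:
        L = 2.0 * K_d * L_tot / (b + disc)
    else:
        L = 0.5 * (disc - b)
    return min(max(L, 0.0), L_tot)


def exchange_rate(k_off: float, K_d: float, L_free: float) -> float:
    """Two-state exchange rate ``k_ex = k_on [L] + k_off`` with k_on = k_off/K_d."""
    if k_off <= 0 or K_d <= 0:
        raise InvalidArgumentError("k_off and K_d must be strictly positive")
    if L_free < 0:
        raise InvalidArgumentError("L_free must be non-negative")
    return (k_off / K_d) * L_free + k_off


def closed_cycle_kd4(K_d1: float, K_d2: float, K_d3: float) -> float:
    """Fourth dissociation constant from thermodynamic-cycle closure.

    For the two-binding-site scheme the cycle P -> B1 -> B12 / P -> B2 -> B12
    fixes ``K_d4 = K_d1 * K_d3 / K_d2``.
    """
    if K_d1 <= 0 or K_d2 <= 0 or K_d3 <= 0:
        raise InvalidArgumentError("all dissociation constants must be positive")
    return K_d1 * K_d3 / K_d2


class BindingModel:
    """Base class for exchange/binding schemes.

    Subclasses declare the ordered state labels (free states first) and
    implement the per-[L] relative state populations, the ligand consumed by
    the bound states, and the first-order transition rates.
    """

    name: str = ""
    states: Tuple[str, ...] = ()
    param_names: Tuple[str, ...] = ()
    #: states carrying population in the absence of ligand (stage-1 fitting)
    free_states: Tuple[str, ...] = ()
    uses_ligand: bool = True

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _check_params(self, params: ModelParameters) -> None:
        missing = [p for p in self.param_names if p not in params.values]
        if missing:
            raise InvalidArgumentError(
                f"model {self.name!r} missing parameter(s): {missing}"
            )

    # -- scheme definition -------------------------------------------------
    def relative_populations(self, params: ModelParameters, L: float) -> np.ndarray:
        """Unnormalized state populations at free-ligand concentration L."""
        raise NotImplementedError

    def ligand_stoichiometry(self, params: ModelParameters) -> np.ndarray:
        """Ligand molecules bound in each state (for ligand mass balance)."""
        raise NotImplementedError

    def transition_rates(
        self, params: ModelParameters, L_free: float
    ) -> List[Tuple[int, int, float]]:
        """List of (from-state, to-state, first-order rate in s^-1)."""
        raise NotImplementedError

    # -- solving -----------------------------------------------------------
    def state_fractions(self, params: ModelParameters, L: float) -> np.ndarray:
        w = self.relative_populations(params, L)
        return w / w.sum()

    def solve(
        self, params: ModelParameters, P_tot: float, L_tot: float
    ) -> EquilibriumPopulations:
        """Equilibrium populations; subclasses with a closed form override
        this, and the generic numeric route stays available as
        :meth:`solve_numeric`."""
        return self.solve_numeric(params, P_tot, L_tot)

    def solve_numeric(
        self, params: ModelParameters, P_tot: float, L_tot: float
    ) -> EquilibriumPopulations:
        self._check_params(params)
        if P_tot < 0 or L_tot < 0:
            raise InvalidArgumentError("total concentrations must be non-negative")
        if not self.uses_ligand or L_tot == 0.0 or P_tot == 0.0:
            L = L_tot if P_tot == 0.0 else 0.0
            return EquilibriumPopulations(
                self.states, self.state_fractions(params, L), L
            )
        stoich = self.ligand_stoichiometry(params)

        def mass_balance(L: float) -> float:
            f = self.state_fractions(params, L)
            return L + P_tot * float(stoich @ f) - L_tot

        lo, hi = 0.0, L_tot
        if mass_balance(lo) > 0:  # no ligand consumed even at L=0
            L = 0.0
        else:
            try:
                L = brentq(mass_balance, lo, hi, xtol=1e-30, rtol=8.9e-16,
                           maxiter=200)
            except Exception as exc:  # pragma: no cover - diagnostics path
                raise SolverError(
                    f"free-ligand root finding failed for model {self.name!r} "
                    f"(P_tot={P_tot}, L_tot={L_tot}): {exc}"
                ) from exc
        return EquilibriumPopulations(self.states, self.state_fractions(params, L), L)

    def rate_matrix(self, params: ModelParameters, L_free: float) -> np.ndarray:
        """First-order exchange matrix K; K[i, j] is the rate from j into i."""
        self._check_params(params)
        if L_free < 0:
            raise InvalidArgumentError("L_free must be non-negative")
        n = self.n_states
        K = np.zeros((n, n))
        for i, j, rate in self.transition_rates(params, L_free):
            if rate < 0 or not np.isfinite(rate):
                raise InvalidArgumentError(
                    f"transition rate {self.states[i]}->{self.states[j]} "
                    f"is not a finite non-negative number: {rate}"
                )
            K[j, i] += rate
        K -= np.diag(K.sum(axis=0))
        return K


class NoExchangeModel(BindingModel):
    """Single static state; fits linewidths/positions in isolated spectra."""

    name = "no_exchange"
    states = ("A",)
    param_names = ()
    free_states = ("A",)
    uses_ligand = False

    def relative_populations(self, params, L):
        return np.ones(1)

    def ligand_stoichiometry(self, params):
        return np.zeros(1)

    def transition_rates(self, params, L_free):
        return []


class TwoStateModel(BindingModel):
    """P + L <-> PL with K_d = k_off/k_on."""

    name = "two_state"
    states = ("P", "PL")
    param_names = ("K_d", "k_off")
    free_states = ("P",)

    def relative_populations(self, params, L):
        return np.array([1.0, L / params["K_d"]])

    def ligand_stoichiometry(self, params):
        return np.array([0.0, 1.0])

    def solve(self, params, P_tot, L_tot):
        self._check_params(params)
        L = free_ligand_concentration(P_tot, L_tot, params["K_d"])
        return EquilibriumPopulations(
            self.states, self.state_fractions(params, L), L
        )

    def transition_rates(self, params, L_free):
        k_off = params["k_off"]
        k_on = k_off / params["K_d"]
        return [(0, 1, k_on * L_free), (1, 0, k_off)]


class TwoStateFlexStoichModel(BindingModel):
    """P + nL <-> PL; n is a continuous stoichiometry scaling the ligand
    consumption (mass balance uses n*[PL]) and a Hill-type association term
    [L]^n.  Intended to absorb uncertainty in the ligand stock concentration.
    """

    name = "two_state_flex_stoich"
    states = ("P", "PL")
    param_names = ("K_d", "k_off", "n")
    free_states = ("P",)

    def relative_populations(self, params, L):
        return np.array([1.0, (L / params["K_d"]) ** params["n"]])

    def ligand_stoichiometry(self, params):
        return np.array([0.0, params["n"]])

    def transition_rates(self, params, L_free):
        k_off = params["k_off"]
        n = params["n"]
        k_on = k_off / params["K_d"] ** n
        return [(0, 1, k_on * L_free ** n), (1, 0, k_off)]


class InducedFitModel(BindingModel):
    """P + L <-> PL_open <-> PL_closed.

    k_close is the closing rate (PL_open -> PL_closed) and k_open the
    opening rate, so the closed:open ratio at equilibrium is k_close/k_open.
    """

    name = "induced_fit"
    states = ("P", "PL_open", "PL_closed")
    param_names = ("K_d", "k_off", "k_open", "k_close")
    free_states = ("P",)

    def relative_populations(self, params, L):
        f_open = L / params["K_d"]
        return np.array([1.0, f_open, f_open * params["k_close"] / params["k_open"]])

    def ligand_stoichiometry(self, params):
        return np.array([0.0, 1.0, 1.0])

    def transition_rates(self, params, L_free):
        k_off = params["k_off"]
        k_on = k_off / params["K_d"]
        return [
            (0, 1, k_on * L_free),
            (1, 0, k_off),
            (1, 2, params["k_close"]),
            (2, 1, params["k_open"]),
        ]


class ConformationalSelectionModel(BindingModel):
    """P_closed <-> P_open; P_open + L <-> PL.

    k_open is the opening rate (P_closed -> P_open); only the open state
    binds ligand, with K_d referring to the binding step.
    """

    name = "conformational_selection"
    states = ("P_closed", "P_open", "PL")
    param_names = ("K_d", "k_off", "k_open", "k_close")
    free_states = ("P_closed", "P_open")

    def relative_populations(self, params, L):
        f_open = params["k_open"] / params["k_close"]
        return np.array([1.0, f_open, f_open * L / params["K_d"]])

    def ligand_stoichiometry(self, params):
        return np.array([0.0, 0.0, 1.0])

    def transition_rates(self, params, L_free):
        k_off = params["k_off"]
        k_on = k_off / params["K_d"]
        return [
            (0, 1, params["k_open"]),
            (1, 0, params["k_close"]),
            (1, 2, k_on * L_free),
            (2, 1, k_off),
        ]


class FourStateModel(BindingModel):
    """A <-> B free-state exchange, each binding ligand: A+L<->AL, B+L<->BL,
    AL <-> BL.  Ligand affinity is specified as the apparent constant for
    (A+B) + L <-> (AL+BL); site constants follow from detailed balance:

        K_d,A = K_d,app (1 + K_AB2) / (1 + K_AB)
        K_d,B = K_d,A K_AB / K_AB2

    A<->B rates split from (K_AB, k_ex) as k_AB = k_ex K_AB/(1+K_AB),
    k_BA = k_ex/(1+K_AB); likewise AL<->BL from (K_AB2, k_ex2).
    """

    name = "four_state"
    states = ("A", "B", "AL", "BL")
    param_names = ("K_d_app", "k_off_A", "k_off_B", "K_AB", "K_AB2", "k_ex", "k_ex2")
    free_states = ("A", "B")

    @staticmethod
    def site_kds(params: ModelParameters) -> Tuple[float, float]:
        K_AB, K_AB2 = params["K_AB"], params["K_AB2"]
        K_dA = params["K_d_app"] * (1.0 + K_AB2) / (1.0 + K_AB)
        K_dB = K_dA * K_AB / K_AB2
        return K_dA, K_dB

    def relative_populations(self, params, L):
        K_AB, K_AB2 = params["K_AB"], params["K_AB2"]
        K_dA, _ = self.site_kds(params)
        f_AL = L / K_dA
        return np.array([1.0, K_AB, f_AL, f_AL * K_AB2])

    def ligand_stoichiometry(self, params):
        return np.array([0.0, 0.0, 1.0, 1.0])

    def transition_rates(self, params, L_free):
        K_AB, K_AB2 = params["K_AB"], params["K_AB2"]
        k_AB = params["k_ex"] * K_AB / (1.0 + K_AB)
        k_BA = params["k_ex"] / (1.0 + K_AB)
        k_AB2 = params["k_ex2"] * K_AB2 / (1.0 + K_AB2)
        k_BA2 = params["k_ex2"] / (1.0 + K_AB2)
        K_dA, K_dB = self.site_kds(params)
        kon_A = params["k_off_A"] / K_dA
        kon_B = params["k_off_B"] / K_dB
        return [
            (0, 1, k_AB), (1, 0, k_BA),
            (2, 3, k_AB2), (3, 2, k_BA2),
            (0, 2, kon_A * L_free), (2, 0, params["k_off_A"]),
            (1, 3, kon_B * L_free), (3, 1, params["k_off_B"]),
        ]


class DimerizationModel(BindingModel):
    """2M <-> D, represented with two dimer spin states (2M <-> D1 + D2) so
    that asymmetric dimers can be modelled; link D1/D2 resonance parameters
    for a symmetric dimer.  K_d = [M]^2/[D] = k_off/k_on; the titration
    variable is the (diluting) total protein concentration, not a ligand.
    """

    name = "dimerization"
    states = ("M", "D1", "D2")
    param_names = ("K_d", "k_off")
    free_states = ("M", "D1", "D2")
    uses_ligand = False

    def free_monomer(self, params: ModelParameters, M_tot: float) -> float:
        K_d = params["K_d"]
        # [M] + 2 [M]^2 / K_d = M_tot
        return 0.25 * (-K_d + math.sqrt(K_d * K_d + 8.0 * K_d * M_tot))

    def solve(self, params, P_tot, L_tot=0.0):
        self._check_params(params)
        if P_tot < 0:
            raise InvalidArgumentError("total concentration must be non-negative")
        if P_tot == 0.0:
            return EquilibriumPopulations(self.states, np.array([1.0, 0.0, 0.0]), 0.0)
        M = self.free_monomer(params, P_tot)
        D = M * M / params["K_d"]
        f = np.array([M, D, D]) / P_tot
        f /= f.sum()  # guard rounding; exact up to float error
        return EquilibriumPopulations(self.states, f, M)

    def relative_populations(self, params, M):
        D = M * M / params["K_d"]
        return np.array([M, D, D])

    def ligand_stoichiometry(self, params):
        return np.zeros(3)

    def transition_rates(self, params, M_free):
        # tagged monomer enters either dimer subunit; each association event
        # proceeds at pseudo-first-order rate k_on [M] per target subunit
        k_off = params["k_off"]
        k_on = k_off / params["K_d"]
        return [
            (0, 1, k_on * M_free), (1, 0, k_off),
            (0, 2, k_on * M_free), (2, 0, k_off),
        ]


class TwoBindingSitesModel(BindingModel):
    """Two ligand sites: P <-> B1 (K_d1), P <-> B2 (K_d2), B1 <-> B12 (K_d3),
    B2 <-> B12 (K_d4 = K_d1 K_d3 / K_d2 by cycle closure).

    ``kd2_pairing`` selects the association rate constant of the P <-> B2
    step: ``"kon2"`` (default) derives it from K_d2 and k_off2; ``"kon3"``
    shares the B1 -> B12 association rate constant, with the dissociation
    rate of the P <-> B2 step then derived from K_d2 to preserve the stated
    equilibrium (k_off2 is ignored for that step).
    """

    name = "two_binding_sites"
    states = ("P", "B1", "B2", "B12")
    param_names = ("K_d1", "K_d2", "K_d3", "k_off1", "k_off2", "k_off3", "k_off4")
    free_states = ("P",)

    def __init__(self, kd2_pairing: str = "kon2") -> None:
        if kd2_pairing not in ("kon2", "kon3"):
            raise InvalidArgumentError("kd2_pairing must be 'kon2' or 'kon3'")
        self.kd2_pairing = kd2_pairing

    def relative_populations(self, params, L):
        K1, K2, K3 = params["K_d1"], params["K_d2"], params["K_d3"]
        return np.array([1.0, L / K1, L / K2, L * L / (K1 * K3)])

    def ligand_stoichiometry(self, params):
        return np.array([0.0, 1.0, 1.0, 2.0])

    def transition_rates(self, params, L_free):
        K1, K2, K3 = params["K_d1"], params["K_d2"], params["K_d3"]
        K4 = closed_cycle_kd4(K1, K2, K3)
        kon1 = params["k_off1"] / K1
        kon3 = params["k_off3"] / K3
        kon4 = params["k_off4"] / K4
        if self.kd2_pairing == "kon2":
            kon2 = params["k_off2"] / K2
            koff2 = params["k_off2"]
        else:  # K_d2 = k_off2 / k_on3 pairing as printed
            kon2 = kon3
            koff2 = kon3 * K2
        return [
            (0, 1, kon1 * L_free), (1, 0, params["k_off1"]),
            (0, 2, kon2 * L_free), (2, 0, koff2),
            (1, 3, kon3 * L_free), (3, 1, params["k_off3"]),
            (2, 3, kon4 * L_free), (3, 2, params["k_off4"]),
        ]


_MODELS: Dict[str, Callable[[], BindingModel]] = {
    "no_exchange": NoExchangeModel,
    "two_state": TwoStateModel,
    "two_state_flex_stoich": TwoStateFlexStoichModel,
    "induced_fit": InducedFitModel,
    "conformational_selection": ConformationalSelectionModel,
    "four_state": FourStateModel,
    "dimerization": DimerizationModel,
    "two_binding_sites": TwoBindingSitesModel,
}


def available_models() -> Tuple[str, ...]:
    return tuple(_MODELS)


def get_model(name: str, **kwargs) -> BindingModel:
    """Instantiate a binding model by name."""
    try:
        cls = _MODELS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown binding model {name!r}; available: {sorted(_MODELS)}"
        ) from None
    return cls(**kwargs)


def solve_equilibrium(
    model: BindingModel | str,
    params: ModelParameters,
    P_tot: float,
    L_tot: float,
) -> EquilibriumPopulations:
    """Solve state populations and free-ligand concentration at one point."""
    if isinstance(model, str):
        model = get_model(model)
    return model.solve(params, P_tot, L_tot)


def build_rate_matrix(
    model: BindingModel | str,
    params: ModelParameters,
    L_free: float,
) -> np.ndarray:
    """First-order exchange rate matrix at the given free-ligand level.

    Columns sum to zero; ``K @ p_eq = 0`` on the matching equilibrium
    fractions (detailed balance holds for every scheme in the library).
    """
    if isinstance(model, str):
        model = get_model(model)
    return model.rate_matrix(params, L_free)
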