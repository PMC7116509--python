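"""Spin systems, regions of interest, spin groups and shared-parameter links.

A *spin system* represents one residue: for every state of the binding model
it carries a direct (^1H) and indirect (^15N) chemical shift (``dI``, ``dS``,
ppm) and effective linewidths (``R2I``, ``R2S``, s^-1).  Each spin system is
associated with a polygonal *region of interest* (ROI) per spectrum whose
grid points enter the fit.  Overlapping spin systems are collected into a
*spin group*; their ROIs are merged and their resonances simulated jointly.

Resonance parameters can be tied together across spins/states through named
shared variables (e.g. to enforce a symmetric dimer); linked targets always
carry identical values.

Fit parameters are labelled ``ASSIGNMENT_QUANTITY_STATE`` (e.g.
``G12_dI_PL``); shared variables appear once in the packed vector under
their own name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .binding import ModelParameters
from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "StateResonance",
    "SpinSystem",
    "ROI",
    "SpinGroup",
    "rasterize_roi",
    "merge_group_rois",
    "build_groups",
    "ParameterPacker",
    "QUANTITIES",
    "DEFAULT_R2",
]

QUANTITIES = ("dI", "dS", "R2I", "R2S")
DEFAULT_R2 = 20.0  # s^-1 starting linewidth for newly created spins


@dataclass
class StateResonance:
    """Resonance parameters of one spin in one model state."""

    dI: float  # ppm, direct (^1H)
    dS: float  # ppm, indirect (^15N)
    R2I: float = DEFAULT_R2  # s^-1
    R2S: float = DEFAULT_R2  # s^-1

    def __post_init__(self) -> None:
        if self.R2I <= 0 or self.R2S <= 0:
            raise InvalidArgumentError("linewidths R2I, R2S must be positive")


class ROI:
    """Polygonal fit region, possibly different for each spectrum.

    ``polygons`` maps spectrum index -> vertex list of (ppm_H, ppm_N).  A
    polygon defined only for spectrum 0 is reused for every later spectrum
    (the usual "copy previous ROI" workflow).
    """

    def __init__(self, polygons: Mapping[int, Sequence[Tuple[float, float]]]):
        self.polygons: Dict[int, np.ndarray] = {}
        for idx, verts in polygons.items():
            arr = np.asarray(verts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(np.unique(arr, axis=0)) < 3:
                raise InvalidArgumentError(
                    f"ROI polygon for spectrum {idx} needs >=3 distinct vertices"
                )
            self.polygons[int(idx)] = arr

    @classmethod
    def box(cls, h_range: Tuple[float, float], n_range: Tuple[float, float]) -> "ROI":
        """Rectangular ROI from ppm ranges, applied to all spectra."""
        h0, h1 = sorted(h_range)
        n0, n1 = sorted(n_range)
        return cls({0: [(h0, n0), (h1, n0), (h1, n1), (h0, n1)]})

    def polygon_for(self, spectrum_index: int) -> np.ndarray:
        if spectrum_index in self.polygons:
            return self.polygons[spectrum_index]
        if 0 in self.polygons:
            return self.polygons[0]
        raise ConfigurationError(
            f"no ROI polygon defined for spectrum {spectrum_index}"
        )


@dataclass
class SpinSystem:
    """One residue across all model states.

    ``states`` maps state label -> :class:`StateResonance`; ``shared`` maps
    ``(state, quantity)`` -> shared-variable name.
    """

    label: str
    states: Dict[str, StateResonance]
    roi: Optional[ROI] = None
    group: Optional[str] = None
    shared: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def get(self, state: str, quantity: str) -> float:
        return getattr(self.states[state], quantity)

    def set(self, state: str, quantity: str, value: float) -> None:
        setattr(self.states[state], quantity, value)


@dataclass
class SpinGroup:
    """Spin systems fitted jointly over merged ROIs."""

    label: str
    members: List[SpinSystem]

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidArgumentError("a spin group needs at least one member")


def build_groups(spins: Sequence[SpinSystem]) -> List[SpinGroup]:
    """Partition spins into groups by their ``group`` label (singletons for
    unlabelled spins); each spin belongs to exactly one group."""
    groups: Dict[str, List[SpinSystem]] = {}
    order: List[str] = []
    for spin in spins:
        key = spin.group if spin.group is not None else f"__solo_{spin.label}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(spin)
    return [SpinGroup(key, groups[key]) for key in order]


def _points_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing number) point-in-polygon test, boundary
    inclusive.  Vertex traversal order and starting vertex do not matter."""
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        # points exactly on the (closed) segment
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        within = (
            (np.minimum(x1, x2) - 1e-300 <= px) & (px <= np.maximum(x1, x2) + 1e-300)
            & (np.minimum(y1, y2) - 1e-300 <= py) & (py <= np.maximum(y1, y2) + 1e-300)
        )
        scale = max(abs(x2 - x1), abs(y2 - y1), 1e-300)
        on_edge |= within & (np.abs(cross) <= 1e-12 * scale * scale)
        # even-odd ray crossing (ray towards +x), half-open in y to avoid
        # double counting at vertices
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < np.where(cond, x_int, np.inf))
    return inside | on_edge


def rasterize_roi(
    polygon: Sequence[Tuple[float, float]],
    ppm_h: np.ndarray,
    ppm_n: np.ndarray,
) -> np.ndarray:
    """Boolean mask of grid points whose (ppm_H, ppm_N) centre lies inside
    the polygon (even-odd rule, boundary points included).

    Returns an array of shape ``(len(ppm_n), len(ppm_h))`` matching the
    spectrum layout (rows = indirect dimension).
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(np.unique(verts, axis=0)) < 3:
        raise InvalidArgumentError("polygon needs at least 3 distinct vertices")
    H, N = np.meshgrid(np.asarray(ppm_h, float), np.asarray(ppm_n, float))
    return _points_in_polygon(H, N, verts)


def merge_group_rois(
    group: SpinGroup,
    spectrum_index: int,
    ppm_h: np.ndarray,
    ppm_n: np.ndarray,
) -> np.ndarray:
    """Union of the member ROI masks of a spin group for one spectrum."""
    mask = np.zeros((len(ppm_n), len(ppm_h)), dtype=bool)
    for spin in group.members:
        if spin.roi is None:
            raise ConfigurationError(
                f"spin {spin.label!r} has no ROI (needed for spectrum "
                f"{spectrum_index})"
            )
        poly = spin.roi.polygon_for(spectrum_index)
        mask |= rasterize_roi(poly, ppm_h, ppm_n)
    return mask


@dataclass
class _Slot:
    """One element of the packed fit vector."""

    label: str
    targets: List[Tuple[object, str]]  # (owner, attr) pairs sharing the value
    value: float
    bounds: Tuple[float, float]
    scale: float = 1.0  # characteristic step over which the fit responds


class ParameterPacker:
    """Maps between the spin/model parameter tree and a flat fit vector.

    The *stage* controls which parameters are free:

    - ``"free_state_only"``: resonance parameters of the ligand-free states
      only; all binding-model parameters fixed.
    - ``"global"``: every spin/state resonance parameter plus the model
      parameters flagged to vary; free-state chemical shifts are fixed
      (the usual second-stage protocol) unless ``fix_free_shifts=False``.

    Shared variables collapse all their targets onto one vector element;
    unpacking writes the common value back to every target.
    """

    SHIFT_BOUND = 1e4  # ppm; effectively unbounded chemical shifts
    R2_BOUNDS = (1e-2, 1e5)  # s^-1

    def __init__(
        self,
        spins: Sequence[SpinSystem],
        model_params: ModelParameters,
        states: Sequence[str],
        free_states: Sequence[str] = (),
        stage: str = "global",
        fix_free_shifts: bool = True,
        fit_model_params: Optional[bool] = None,
    ) -> None:
        if stage not in ("free_state_only", "global"):
            raise InvalidArgumentError(f"unknown fit stage {stage!r}")
        self.spins = list(spins)
        self.model_params = model_params
        self.states = tuple(states)
        self.free_states = tuple(free_states)
        self.stage = stage

        slots: List[_Slot] = []
        shared_slots: Dict[str, _Slot] = {}
        claimed: Dict[Tuple[int, str, str], str] = {}

        for i, spin in enumerate(self.spins):
            for state in self.states:
                if state not in spin.states:
                    raise ConfigurationError(
                        f"spin {spin.label!r} lacks parameters for state {state!r}"
                    )
                for quantity in QUANTITIES:
                    if not self._is_free(state, quantity, fix_free_shifts):
                        continue
                    if quantity.startswith("R2"):
                        bounds, scale = self.R2_BOUNDS, 10.0
                    else:
                        bounds = (-self.SHIFT_BOUND, self.SHIFT_BOUND)
                        # trust-region scale ~ a linewidth in ppm
                        scale = 0.03 if quantity == "dI" else 0.2
                    target = (spin.states[state], quantity)
                    shared_name = spin.shared.get((state, quantity))
                    if shared_name is not None:
                        key = (i, state, quantity)
                        if key in claimed and claimed[key] != shared_name:
                            raise ConfigurationError(
                                f"{spin.label}_{quantity}_{state} linked to two "
                                f"shared variables"
                            )
                        claimed[key] = shared_name
                        if shared_name in shared_slots:
                            shared_slots[shared_name].targets.append(target)
                        else:
                            slot = _Slot(shared_name, [target],
                                         spin.get(state, quantity), bounds,
                                         scale)
                            shared_slots[shared_name] = slot
                            slots.append(slot)
                    else:
                        slots.append(_Slot(
                            f"{spin.label}_{quantity}_{state}",
                            [target], spin.get(state, quantity), bounds, scale,
                        ))

        if fit_model_params is None:
            fit_model_params = stage == "global"
        if fit_model_params:
            for name in model_params.values:
                if not model_params.get_vary(name):
                    continue
                slots.append(_Slot(
                    name, [(model_params.values, name)],
                    model_params[name], model_params.get_bounds(name),
                    abs(model_params[name]),
                ))

        self._slots = slots
        self.labels = [s.label for s in slots]

    def _is_free(self, state: str, quantity: str, fix_free_shifts: bool) -> bool:
        is_free_state = state in self.free_states
        if self.stage == "free_state_only":
            return is_free_state
        # global stage: free-state chemical shifts stay pinned from stage 1;
        # free-state linewidths may still refine
        if fix_free_shifts and is_free_state and quantity in ("dI", "dS"):
            return False
        return True

    def __len__(self) -> int:
        return len(self._slots)

    def pack(self) -> np.ndarray:
        """Current parameter values as a flat vector."""
        return np.array([s.value for s in self._slots], dtype=float)

    @property
    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([s.bounds[0] for s in self._slots])
        hi = np.array([s.bounds[1] for s in self._slots])
        return lo, hi

    @property
    def x_scales(self) -> np.ndarray:
        """Per-parameter trust-region scales (shift ~ linewidth, R2 ~ 10/s,
        model constants ~ their magnitude)."""
        return np.array([s.scale if s.scale > 0 else 1.0 for s in self._slots])

    def unpack(self, x: np.ndarray) -> None:
        """Write a fit vector back onto spins and model parameters; all
        targets of a shared variable receive the identical value."""
        if len(x) != len(self._slots):
            raise InvalidArgumentError(
                f"vector length {len(x)} != number of free parameters "
                f"{len(self._slots)}"
            )
        for slot, v in zip(self._slots, x):
            slot.value = float(v)
            for owner, attr in slot.targets:
                if isinstance(owner, dict):
                    owner[attr] = float(v)
                else:
                    setattr(owner, attr, float(v))

    def index_map(self) -> Dict[str, int]:
        return {label: i for i, label in enumerate(self.labels)}
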