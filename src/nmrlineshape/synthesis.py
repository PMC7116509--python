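"""Titration design (dilution accounting) and synthetic dataset generation.

`design_titration` converts a ligand-equivalents schedule into per-point
added volumes and dilution-corrected total concentrations, exactly the
bookkeeping needed when aliquots of a concentrated ligand stock are added
to a protein sample of fixed initial volume.

`generate_synthetic_titration` builds a complete processed titration series
from known ground-truth parameters: equilibrium solve, virtual-spectrometer
simulation, complex Gaussian noise added in the time domain (so processing
shapes the noise exactly as for real data), processing to .ft2 spectra and,
optionally, files on disk plus a manifest consumable by the fit CLI.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import BindingModel, ModelParameters, get_model, uM
from .errors import DesignError, InvalidArgumentError
from .fitting import TitrationDataset, TitrationPoint
from .nmrpipe import write_ft2
from .processing import ProcessingParams, process_interferogram
from .spectrometer import Interferogram, PulseSequenceConfig, simulate_group
from .spins import SpinSystem, build_groups

__all__ = [
    "DEFAULT_SCHEDULE",
    "TitrationDesign",
    "design_titration",
    "GroundTruth",
    "generate_synthetic_titration",
]

#: ligand-equivalents schedule with denser early sampling (quadratic-like
#: increments), the usual default for a 9-point titration
DEFAULT_SCHEDULE = (0.0, 0.1, 0.25, 0.4, 0.6, 0.85, 1.15, 1.5, 1.9)


@dataclass
class TitrationDesign:
    """Computed titration table.

    ``table`` columns: equivalents, added_volume, cum_volume, volume,
    P_tot, L_tot (concentrations molar, volumes in the unit of ``V0``).
    """

    P0: float
    V0: float
    stock_L: float
    protein_in_stock: bool
    table: pd.DataFrame

    @property
    def P_tot(self) -> np.ndarray:
        return self.table["P_tot"].to_numpy()

    @property
    def L_tot(self) -> np.ndarray:
        return self.table["L_tot"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def is_saturating(self, K_d: float) -> bool:
        """Final point reaches the greater of 3 K_d or two equivalents."""
        final_L = float(self.table["L_tot"].iloc[-1])
        final_P = float(self.table["P_tot"].iloc[-1])
        return final_L >= max(3.0 * K_d, 2.0 * final_P)


def design_titration(
    P0: float,
    V0: float,
    stock_L: float,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    protein_in_stock: bool = False,
) -> TitrationDesign:
    """Per-point volumes and dilution-corrected totals for a titration.

    At point *i* the added (cumulative) volume ``v_i`` is chosen so that the
    total ligand equals ``equivalents_i`` times the current total protein.
    Without protein in the stock, protein dilutes as ``P0 V0 / (V0 + v_i)``;
    with protein in the stock (at P0), P_tot stays constant.

    Raises :class:`DesignError` when the stock is too dilute to reach a
    requested equivalents target, reporting the required concentration.
    """
    if P0 <= 0 or V0 <= 0 or stock_L <= 0:
        raise InvalidArgumentError("P0, V0 and stock_L must be positive")
    eqs = np.asarray(schedule, dtype=float)
    if np.any(np.diff(eqs) < 0):
        raise InvalidArgumentError("equivalents schedule must be nondecreasing")
    if np.any(eqs < 0):
        raise InvalidArgumentError("equivalents must be non-negative")
    rows = []
    prev_v = 0.0
    for e in eqs:
        if protein_in_stock:
            # stock_L * v = e * P0 * (V0 + v)  ->  v = e P0 V0 / (stock_L - e P0)
            denom = stock_L - e * P0
            if denom <= 0:
                raise DesignError(
                    f"stock {stock_L:g} M cannot reach {e} equivalents with "
                    f"protein in the stock; need > {e * P0:g} M"
                )
            v = e * P0 * V0 / denom
        else:
            # stock_L * v = e * P0 * V0  (protein moles fixed)
            v = e * P0 * V0 / stock_L
        V = V0 + v
        P_tot = P0 if protein_in_stock else P0 * V0 / V
        L_tot = stock_L * v / V
        if v + 1e-12 < prev_v:
            raise DesignError("added volume must be nondecreasing")
        rows.append({
            "equivalents": e,
            "added_volume": v - prev_v,
            "cum_volume": v,
            "volume": V,
            "P_tot": P_tot,
            "L_tot": L_tot,
        })
        prev_v = v
    return TitrationDesign(P0, V0, stock_L, protein_in_stock,
                           pd.DataFrame(rows))


@dataclass
class GroundTruth:
    """Known-truth specification for a synthetic titration.

    ``noise_sigma`` is given in final-spectrum intensity units (calibrated
    through a processing pass); alternatively ``snr`` sets sigma to the
    noiseless first-spectrum maximum divided by snr.  Same seed, same
    dataset, byte for byte.
    """

    model: str
    params: ModelParameters
    spins: List[SpinSystem]
    noise_sigma: Optional[float] = None
    snr: Optional[float] = None
    seed: int = 0
    ns: int = 1
    rg: float = 1.0


def _simulate_noiseless(
    model: BindingModel,
    params: ModelParameters,
    spins: Sequence[SpinSystem],
    P_tot: float,
    L_tot: float,
    amplitude: float,
    config: PulseSequenceConfig,
) -> Interferogram:
    eq = model.solve(params, P_tot, L_tot)
    K = model.rate_matrix(params, eq.free_ligand)
    total: Optional[Interferogram] = None
    for group in build_groups(spins):
        ifg = simulate_group(group, K, eq.fractions, amplitude, config,
                             model.states)
        total = ifg if total is None else total + ifg
    return total


def _noise_gain(config: PulseSequenceConfig, proc: ProcessingParams,
                rng: np.random.Generator) -> float:
    """Std of the processed spectrum per unit time-domain complex sigma,
    measured with a calibration noise pass through the processing chain."""
    shape = (config.n_S, config.n_H)
    cos = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    sin = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    ifg = Interferogram(cos, sin, config.dwell_S, config.dwell_H)
    spec = process_interferogram(ifg, proc, config)
    return float(spec.data.std())


def generate_synthetic_titration(
    truth: GroundTruth,
    design: TitrationDesign,
    config: PulseSequenceConfig,
    proc: ProcessingParams,
    outdir: Optional[str] = None,
) -> TitrationDataset:
    """Simulate, noise and process a full titration series.

    Returns a ready-to-fit :class:`TitrationDataset`; when ``outdir`` is
    given, also writes ``spectrum-<i>.ft2`` files and a ``manifest.csv``
    with per-point path, P_tot, L_tot (in uM), ns, rg and noise sigma.
    """
    model = get_model(truth.model)
    rng = np.random.default_rng(truth.seed)
    cal_rng = np.random.default_rng((truth.seed, 0xC0FFEE))

    ifgs = []
    for P_tot, L_tot in zip(design.P_tot, design.L_tot):
        amplitude = P_tot * truth.ns * truth.rg
        ifgs.append(_simulate_noiseless(
            model, truth.params, truth.spins, P_tot, L_tot, amplitude, config,
        ))

    sigma = truth.noise_sigma
    if sigma is None and truth.snr is not None:
        first = process_interferogram(ifgs[0], proc, config)
        sigma = float(np.max(np.abs(first.data))) / truth.snr
    sigma_t = 0.0
    if sigma is not None and sigma > 0:
        sigma_t = sigma / _noise_gain(config, proc, cal_rng)

    points = []
    rows = []
    for i, ifg in enumerate(ifgs):
        if sigma_t > 0:
            shape = ifg.cos.shape
            noisy = Interferogram(
                ifg.cos + sigma_t * (rng.standard_normal(shape)
                                     + 1j * rng.standard_normal(shape)),
                ifg.sin + sigma_t * (rng.standard_normal(shape)
                                     + 1j * rng.standard_normal(shape)),
                ifg.dwell_t1, ifg.dwell_t2, ifg.scale,
            )
        else:
            noisy = ifg
        spec = process_interferogram(noisy, proc, config)
        # unit weights for noiseless data keep chi-square well defined
        spec.noise_sigma = sigma if (sigma and sigma > 0) else 1.0
        point = TitrationPoint(
            P_tot=float(design.P_tot[i]), L_tot=float(design.L_tot[i]),
            spectrum=spec, ns=truth.ns, rg=truth.rg,
            noise_sigma=spec.noise_sigma,
        )
        points.append(point)
        if outdir is not None:
            os.makedirs(outdir, exist_ok=True)
            fname = f"spectrum-{i + 1}.ft2"
            write_ft2(spec, os.path.join(outdir, fname))
            rows.append({
                "path": fname,
                "P_tot_uM": point.P_tot / uM,
                "L_tot_uM": point.L_tot / uM,
                "ns": point.ns,
                "rg": point.rg,
                "noise_sigma": spec.noise_sigma,
            })
    if outdir is not None:
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "manifest.csv"),
                                  index=False)
    return TitrationDataset(points, config, proc, estimate_missing_noise=False)
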