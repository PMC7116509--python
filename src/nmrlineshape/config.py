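"""Declarative YAML configuration: binding model, pulse sequence,
processing, spin systems/ROIs, and the titration manifest.

Concentrations in config files and manifests are micromolar (the natural
bench unit); they are converted to molar at load time.  A minimal fit
configuration looks like::

    model:
      name: two_state
      parameters:
        K_d:   {value: 20.0, min: 0.01, max: 1000.0, vary: true}   # uM
        k_off: {value: 100.0, vary: true}                          # s^-1
    pulse:
      experiment: HSQC
      f_spec_H: 700.0
      offset_H: 8.2
      offset_S: 119.0
      sw_H: 2000.0
      sw_S: 600.0
      n_H: 128
      n_S: 64
    processing:
      lb_H: 4.0
      lb_S: 8.0
    spins:
      - label: A1
        group: g1            # optional overlap group
        states:
          P:  {dI: 8.10, dS: 118.6, R2I: 20.0, R2S: 20.0}
          PL: {dI: 8.35, dS: 119.3, R2I: 20.0, R2S: 20.0}
        roi:
          0: [[7.9, 117.5], [8.6, 117.5], [8.6, 120.5], [7.9, 120.5]]
        shared:              # optional shared-variable links
          PL.dI: shared1
"""

from __future__ import annotations

import os
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .binding import BindingModel, ModelParameters, get_model, uM
from .errors import ConfigurationError
from .fitting import TitrationDataset, TitrationPoint
from .nmrpipe import read_ft2
from .processing import ProcessingParams
from .spectrometer import PulseSequenceConfig
from .spins import ROI, SpinSystem, StateResonance

__all__ = [
    "CONCENTRATION_PARAMS",
    "load_config",
    "load_model",
    "load_spins",
    "load_manifest",
]

#: binding-model parameters carrying concentration units (converted from uM)
CONCENTRATION_PARAMS = {"K_d", "K_d_app", "K_d1", "K_d2", "K_d3"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return cfg


def load_model(cfg: dict) -> Tuple[BindingModel, ModelParameters]:
    section = cfg.get("model")
    if not section or "name" not in section:
        raise ConfigurationError("config needs a model section with a name")
    kwargs = {}
    if "kd2_pairing" in section:
        kwargs["kd2_pairing"] = section["kd2_pairing"]
    model = get_model(section["name"], **kwargs)
    values: Dict[str, float] = {}
    bounds: Dict[str, Tuple[float, float]] = {}
    vary: Dict[str, bool] = {}
    for name, spec in (section.get("parameters") or {}).items():
        if isinstance(spec, (int, float)):
            spec = {"value": spec}
        scale = uM if name in CONCENTRATION_PARAMS else 1.0
        values[name] = float(spec["value"]) * scale
        if "min" in spec or "max" in spec:
            bounds[name] = (
                float(spec.get("min", 0.0)) * scale or 1e-300,
                float(spec.get("max", np.inf)) * scale,
            )
        if "vary" in spec:
            vary[name] = bool(spec["vary"])
    return model, ModelParameters(values, bounds, vary)


def load_pulse(cfg: dict) -> PulseSequenceConfig:
    return PulseSequenceConfig(**(cfg.get("pulse") or {}))


def load_processing(cfg: dict) -> ProcessingParams:
    section = dict(cfg.get("processing") or {})
    if "ext_H" in section and section["ext_H"] is not None:
        section["ext_H"] = tuple(section["ext_H"])
    return ProcessingParams(**section)


def load_spins(cfg: dict) -> List[SpinSystem]:
    spins = []
    for entry in cfg.get("spins") or []:
        states = {
            state: StateResonance(**vals)
            for state, vals in (entry.get("states") or {}).items()
        }
        roi = None
        if entry.get("roi"):
            roi = ROI({int(k): v for k, v in entry["roi"].items()})
        shared = {}
        for key, name in (entry.get("shared") or {}).items():
            state, quantity = key.split(".")
            shared[(state, quantity)] = name
        spins.append(SpinSystem(
            label=str(entry.get("label", f"S{len(spins) + 1}")),
            states=states, roi=roi, group=entry.get("group"), shared=shared,
        ))
    if not spins:
        raise ConfigurationError("config defines no spin systems")
    return spins


def load_manifest(
    manifest_path,
    config: PulseSequenceConfig,
    proc: ProcessingParams,
) -> TitrationDataset:
    """Titration dataset from a manifest table.

    One row per point with columns ``path`` (relative to the manifest),
    ``P_tot_uM``, ``L_tot_uM``, ``ns``, ``rg`` and optionally
    ``noise_sigma`` (blank = automatic estimation).
    """
    base = os.path.dirname(os.path.abspath(manifest_path))
    table = pd.read_csv(manifest_path)
    points = []
    for _, row in table.iterrows():
        spec = read_ft2(os.path.join(base, str(row["path"])))
        sigma = row.get("noise_sigma", np.nan)
        sigma = float(sigma) if pd.notna(sigma) and sigma != "" else None
        points.append(TitrationPoint(
            P_tot=float(row["P_tot_uM"]) * uM,
            L_tot=float(row["L_tot_uM"]) * uM,
            spectrum=spec,
            ns=int(row.get("ns", 1)),
            rg=float(row.get("rg", 1.0)),
            noise_sigma=sigma,
        ))
    return TitrationDataset(points, config, proc)
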