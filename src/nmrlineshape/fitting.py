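"""Global lineshape fitting of titration series.

`TitrationLineshapeModel` bundles the observed spectra, the binding model,
the spin systems/ROIs and the pulse-sequence/processing configuration; its
:meth:`~TitrationLineshapeModel.fit` minimizes the noise-weighted chi-square

    chi^2 = sum_s sum_{p in ROI(s)} (I_obs - I_sim)^2 / sigma_s^2

over the packed parameter vector and returns a
:class:`LineshapeFitResults` carrying the estimates, covariance-derived
standard errors, diagnostics and a ``summary()`` table.  Simulation
amplitudes are fixed by ``P_tot * ns * rg``, so no per-peak or per-spectrum
normalization enters the fit.  Uncertainties beyond the local covariance
come from :meth:`LineshapeFitResults.bootstrap`, which resamples residuals
within each spectrum's ROI set, rebuilds synthetic observations around the
best-fit surface and refits from the original starting values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .binding import BindingModel, ModelParameters, get_model
from .errors import ConfigurationError, InvalidArgumentError
from .nmrpipe import Spectrum2D, write_ft2
from .processing import ProcessingParams, estimate_noise, process_interferogram
from .spectrometer import PulseSequenceConfig, simulate_group
from .spins import ParameterPacker, SpinGroup, SpinSystem, build_groups, merge_group_rois

__all__ = [
    "TitrationPoint",
    "TitrationDataset",
    "TitrationLineshapeModel",
    "LineshapeFitResults",
    "BootstrapResult",
]


@dataclass
class TitrationPoint:
    """One titration point: dilution-corrected totals (molar), acquisition
    scale factors and the processed spectrum."""

    P_tot: float
    L_tot: float
    spectrum: Spectrum2D
    ns: int = 1
    rg: float = 1.0
    noise_sigma: Optional[float] = None

    def sigma(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        if self.spectrum.noise_sigma is not None:
            return self.spectrum.noise_sigma
        raise ConfigurationError(
            "no noise sigma available; run estimate_noise or set one manually"
        )

    @property
    def amplitude(self) -> float:
        return self.P_tot * self.ns * self.rg


class TitrationDataset:
    """Ordered titration points sharing one pulse-sequence and processing
    configuration.  All spectra must share axes (sweep widths, offsets and
    sizes must not change within a titration); ns and rg may vary."""

    def __init__(
        self,
        points: Sequence[TitrationPoint],
        config: PulseSequenceConfig,
        proc: ProcessingParams,
        estimate_missing_noise: bool = True,
    ) -> None:
        if not points:
            raise InvalidArgumentError("dataset needs at least one titration point")
        self.points = list(points)
        self.config = config
        self.proc = proc
        ref = self.points[0].spectrum
        for p in self.points[1:]:
            for a, b in ((p.spectrum.axis_direct, ref.axis_direct),
                         (p.spectrum.axis_indirect, ref.axis_indirect)):
                if a.size != b.size or not (
                    np.isclose(a.sw, b.sw) and np.isclose(a.obs, b.obs)
                    and np.isclose(a.orig, b.orig)
                ):
                    raise ConfigurationError(
                        "titration spectra do not share frequency axes; "
                        "acquisition parameters must not change between points"
                    )
        if estimate_missing_noise:
            for p in self.points:
                if p.noise_sigma is None and p.spectrum.noise_sigma is None:
                    p.spectrum.noise_sigma = estimate_noise(p.spectrum)

    def __len__(self) -> int:
        return len(self.points)


class TitrationLineshapeModel:
    """Two-dimensional lineshape model for a titration series.

    Parameters
    ----------
    dataset : TitrationDataset
    binding_model : BindingModel or str
        Exchange scheme (e.g. ``"two_state"``).
    params : ModelParameters
        Initial values, bounds and fit flags for the scheme's constants.
    spins : sequence of SpinSystem
        Per-residue resonance parameters with ROIs; spins sharing a
        ``group`` label are simulated jointly over merged ROIs.
    """

    def __init__(
        self,
        dataset: TitrationDataset,
        binding_model: BindingModel | str,
        params: ModelParameters,
        spins: Sequence[SpinSystem],
    ) -> None:
        self.dataset = dataset
        self.binding_model = (
            get_model(binding_model) if isinstance(binding_model, str)
            else binding_model
        )
        self.params = params
        self.spins = list(spins)
        self.groups = build_groups(self.spins)
        self._check_axes()
        self._masks: Dict[Tuple[int, int], np.ndarray] = {}
        for ip, point in enumerate(dataset.points):
            hp = point.spectrum.ppm_direct
            np_ = point.spectrum.ppm_indirect
            for ig, group in enumerate(self.groups):
                mask = merge_group_rois(group, ip, hp, np_)
                if not mask.any():
                    raise ConfigurationError(
                        f"ROI mask empty for group {group.label!r}, "
                        f"spectrum {ip}"
                    )
                self._masks[(ip, ig)] = mask
        self._obs = {
            key: self.dataset.points[key[0]].spectrum.data[mask].astype(float)
            for key, mask in self._masks.items()
        }

    # -- infrastructure ----------------------------------------------------
    def _check_axes(self) -> None:
        """Simulated spectra must land on the observed grid."""
        from .nmrpipe import AxisInfo

        cfg, proc = self.dataset.config, self.dataset.proc
        zf_H, zf_S = proc.zf_sizes(cfg.n_H, cfg.n_S)
        ax2 = AxisInfo.from_carrier(zf_H, cfg.sw_H, cfg.f_spec_H, cfg.offset_H)
        if proc.ext_H is not None:
            lo, hi = sorted(proc.ext_H)
            ppm = ax2.ppm()
            n_keep = int(np.sum((ppm >= lo) & (ppm <= hi)))
        else:
            n_keep = zf_H
        ref = self.dataset.points[0].spectrum
        if ref.axis_direct.size != n_keep or ref.axis_indirect.size != zf_S:
            raise ConfigurationError(
                f"processing parameters produce a "
                f"{zf_S}x{n_keep} grid but the data are "
                f"{ref.axis_indirect.size}x{ref.axis_direct.size}"
            )

    def make_packer(
        self,
        stage: str = "global",
        fix_free_shifts: bool = True,
        fit_model_params: Optional[bool] = None,
    ) -> ParameterPacker:
        return ParameterPacker(
            self.spins, self.params, self.binding_model.states,
            self.binding_model.free_states, stage=stage,
            fix_free_shifts=fix_free_shifts, fit_model_params=fit_model_params,
        )

    def simulate_point(
        self, point: TitrationPoint, group: SpinGroup
    ) -> Spectrum2D:
        """Best-current-parameter simulation of one group at one point."""
        model = self.binding_model
        eq = model.solve(self.params, point.P_tot, point.L_tot)
        K = model.rate_matrix(self.params, eq.free_ligand)
        ifg = simulate_group(group, K, eq.fractions, point.amplitude,
                             self.dataset.config, model.states)
        return process_interferogram(ifg, self.dataset.proc, self.dataset.config)

    def simulate_full(self, point: TitrationPoint) -> Spectrum2D:
        """All groups summed on the full grid (for export and plotting)."""
        spec = None
        for group in self.groups:
            s = self.simulate_point(point, group)
            spec = s if spec is None else Spectrum2D(
                spec.data + s.data, s.axis_direct, s.axis_indirect
            )
        return spec

    def _sim_masked(self, spectra: Sequence[int]) -> Dict[Tuple[int, int], np.ndarray]:
        """Simulated intensities on the masked points, at current params."""
        model = self.binding_model
        out: Dict[Tuple[int, int], np.ndarray] = {}
        for ip in spectra:
            point = self.dataset.points[ip]
            eq = model.solve(self.params, point.P_tot, point.L_tot)
            K = model.rate_matrix(self.params, eq.free_ligand)
            for ig, group in enumerate(self.groups):
                ifg = simulate_group(group, K, eq.fractions, point.amplitude,
                                     self.dataset.config, model.states)
                spec = process_interferogram(ifg, self.dataset.proc,
                                             self.dataset.config)
                out[(ip, ig)] = spec.data[self._masks[(ip, ig)]]
        return out

    def _residuals(
        self,
        x: np.ndarray,
        packer: ParameterPacker,
        spectra: Sequence[int],
        obs_override: Optional[Mapping[Tuple[int, int], np.ndarray]] = None,
    ) -> np.ndarray:
        packer.unpack(x)
        sims = self._sim_masked(spectra)
        parts = []
        for ip in spectra:
            sigma = self.dataset.points[ip].sigma()
            for ig in range(len(self.groups)):
                obs = (obs_override or self._obs)[(ip, ig)]
                parts.append((obs - sims[(ip, ig)]) / sigma)
        return np.concatenate(parts)

    def chi_square(
        self,
        x: Optional[np.ndarray] = None,
        packer: Optional[ParameterPacker] = None,
        spectra: Optional[Sequence[int]] = None,
    ) -> float:
        """Noise-weighted chi-square at the given (or current) parameters."""
        spectra = list(range(len(self.dataset))) if spectra is None else spectra
        if x is None or packer is None:
            packer = self.make_packer("global", fix_free_shifts=False)
            x = packer.pack()
        r = self._residuals(np.asarray(x, float), packer, spectra)
        return float(r @ r)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        stage: str = "global",
        spectra: Optional[Sequence[int]] = None,
        fix_free_shifts: bool = True,
        fit_model_params: Optional[bool] = None,
        ftol: float = 1e-8,
        xtol: float = 1e-10,
        max_iter: int = 300,
        verbose: int = 0,
    ) -> "LineshapeFitResults":
        """Bounded trust-region least-squares fit of the selected stage.

        ``stage="free_state_only"`` refines the ligand-free resonance
        parameters against the first spectrum only; ``stage="global"``
        fits everything else (bound-state resonances, free-state
        linewidths, binding-model constants) against all selected spectra
        with the free-state chemical shifts pinned.
        """
        if spectra is None:
            spectra = [0] if stage == "free_state_only" else list(
                range(len(self.dataset))
            )
        packer = self.make_packer(stage, fix_free_shifts, fit_model_params)
        if len(packer) == 0:
            raise ConfigurationError("no free parameters in this stage")
        x0 = packer.pack()
        lo, hi = packer.bounds
        x_scale = packer.x_scales
        res = least_squares(
            self._residuals, x0, args=(packer, spectra),
            bounds=(lo, hi), method="trf", ftol=ftol, xtol=xtol, gtol=1e-14,
            x_scale=x_scale, max_nfev=max_iter * (len(x0) + 1), verbose=verbose,
        )
        packer.unpack(res.x)  # leave the model at the optimum
        return LineshapeFitResults(self, packer, spectra, res, x0)

    def fit_two_stage(self, **kwargs) -> "LineshapeFitResults":
        """Stage 1 (free-state resonances on the first spectrum) followed by
        the global stage; returns the global-stage results."""
        self.fit(stage="free_state_only", **kwargs)
        return self.fit(stage="global", **kwargs)


class LineshapeFitResults:
    """Best-fit parameters, covariance errors and diagnostics.

    Attributes
    ----------
    params : dict
        Label -> best-fit value (labels ``ASSIGNMENT_QUANTITY_STATE`` for
        resonance parameters, bare names for binding-model constants).
    bse : dict
        Covariance-derived standard errors.
    chisqr, redchi, ndata, nfree : float/int
        Goodness-of-fit bookkeeping.
    at_bounds : list of str
        Parameters pinned at a box bound (poorly constrained; treat with
        caution).
    """

    def __init__(self, model, packer, spectra, optres, x0):
        self.model = model
        self.packer = packer
        self.spectra = list(spectra)
        self.labels = list(packer.labels)
        self.x = np.asarray(optres.x, float)
        self.x0 = np.asarray(x0, float)
        self.success = bool(optres.success)
        self.message = optres.message
        self.nfev = optres.nfev
        self.chisqr = float(2.0 * optres.cost)
        self.ndata = optres.fun.size
        self.nfree = len(self.x)
        self.redchi = self.chisqr / max(self.ndata - self.nfree, 1)

        # covariance from the Jacobian at the optimum, with diagonal
        # preconditioning so disparate parameter scales do not poison pinv
        J = optres.jac
        JTJ = J.T @ J
        d = np.sqrt(np.diag(JTJ))
        d[d == 0] = 1.0
        JTJ_scaled = JTJ / np.outer(d, d)
        self.cov = np.linalg.pinv(JTJ_scaled, rcond=1e-12) / np.outer(d, d)
        bse = np.sqrt(np.clip(np.diag(self.cov), 0.0, np.inf))
        self.params = dict(zip(self.labels, self.x))
        self.bse = dict(zip(self.labels, bse))

        lo, hi = packer.bounds
        width = np.where(np.isfinite(hi - lo), hi - lo, np.abs(self.x) + 1.0)
        tol = 1e-8 * width
        self.at_bounds = [
            lab for lab, v, l, h, t in zip(self.labels, self.x, lo, hi, tol)
            if (v - l) < t or (h - v) < t
        ]

    # -- reporting ---------------------------------------------------------
    def cov_params(self) -> np.ndarray:
        """Parameter covariance matrix from the Jacobian at the optimum."""
        return self.cov

    def summary(self) -> str:
        model = self.model
        lines = [
            "Two-dimensional lineshape fit",
            "=" * 64,
            f"binding model:     {model.binding_model.name}",
            f"spectra fitted:    {self.spectra}",
            f"chi-square:        {self.chisqr:.6g}",
            f"reduced chi-sq:    {self.redchi:.6g}  "
            f"({self.ndata} points, {self.nfree} free parameters)",
            f"converged:         {self.success} ({self.message})",
        ]
        if self.at_bounds:
            lines.append(f"AT BOUNDS:         {', '.join(self.at_bounds)}")
        lines.append("-" * 64)
        lines.append(f"{'parameter':<28}{'value':>16}{'std err':>16}")
        for lab in self.labels:
            lines.append(
                f"{lab:<28}{self.params[lab]:>16.8g}{self.bse[lab]:>16.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model.binding_model.name,
            "chisqr": self.chisqr,
            "redchi": self.redchi,
            "ndata": self.ndata,
            "success": self.success,
            "parameters": [
                {"label": lab, "value": self.params[lab], "stderr": self.bse[lab]}
                for lab in self.labels
            ],
            "at_bounds": self.at_bounds,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @property
    def fittedvalues(self) -> List[Spectrum2D]:
        """Full-grid best-fit spectra (all groups summed), one per point."""
        self.packer.unpack(self.x)
        return [self.model.simulate_full(p) for p in self.model.dataset.points]

    def export_fitted(self, outdir, prefix: str = "fitted") -> List[str]:
        """Write the simulated best-fit spectra as NMRPipe .ft2 files."""
        import os

        paths = []
        for i, spec in enumerate(self.fittedvalues):
            path = os.path.join(str(outdir), f"{prefix}-{i + 1}.ft2")
            write_ft2(spec, path)
            paths.append(path)
        return paths

    def plot_overlay(self, point: int = 0, ax=None, levels: int = 8):
        from .plotting import plot_overlay

        return plot_overlay(self, point, ax=ax, levels=levels)

    def plot_waterfall(self, point: int = 0, ax=None):
        from .plotting import plot_waterfall

        return plot_waterfall(self, point, ax=ax)

    # -- bootstrap ---------------------------------------------------------
    def bootstrap(self, n_replicas: int = 50, seed: Optional[int] = None,
                  verbose: bool = False) -> "BootstrapResult":
        """Residual-resampling bootstrap.

        For each replica the best-fit surface is perturbed by residuals
        resampled with replacement from the pooled ROI points of the same
        spectrum, and the fit is repeated from the original starting
        parameters.  At least 50 replicas are recommended for reliable
        uncertainty estimates.
        """
        if n_replicas < 2:
            raise InvalidArgumentError("need at least 2 bootstrap replicas")
        model = self.model
        rng = np.random.default_rng(seed)

        self.packer.unpack(self.x)
        fit_masked = model._sim_masked(self.spectra)
        resid = {
            key: model._obs[key] - fit_masked[key] for key in fit_masked
        }
        lo, hi = self.packer.bounds
        x_scale = self.packer.x_scales

        replicas = np.empty((n_replicas, self.nfree))
        for r in range(n_replicas):
            obs_override = {}
            for ip in self.spectra:
                keys = [(ip, ig) for ig in range(len(model.groups))]
                pool = np.concatenate([resid[k] for k in keys])
                draw = rng.choice(pool, size=pool.size, replace=True)
                ofs = 0
                for k in keys:
                    n = fit_masked[k].size
                    obs_override[k] = fit_masked[k] + draw[ofs:ofs + n]
                    ofs += n
            res = least_squares(
                model._residuals, self.x0,
                args=(self.packer, self.spectra, obs_override),
                bounds=(lo, hi), method="trf", ftol=1e-8, xtol=1e-10,
                gtol=1e-14, x_scale=x_scale,
                max_nfev=300 * (self.nfree + 1),
            )
            replicas[r] = res.x
            if verbose:
                print(f"bootstrap replica {r + 1}/{n_replicas}: "
                      f"chi2={2 * res.cost:.4g}")
        self.packer.unpack(self.x)  # restore the best fit
        return BootstrapResult(self.labels, replicas)


class BootstrapResult:
    """Per-replica parameter vectors with summary statistics."""

    def __init__(self, labels: Sequence[str], replicas: np.ndarray):
        self.labels = list(labels)
        self.replicas = np.asarray(replicas, float)
        self.mean = self.replicas.mean(axis=0)
        self.se = self.replicas.std(axis=0, ddof=1)
        if self.replicas.shape[0] > 1:
            self.cov = np.cov(self.replicas, rowvar=False).reshape(
                len(self.labels), len(self.labels)
            )
        else:
            self.cov = np.zeros((len(self.labels),) * 2)
        sd = np.sqrt(np.diag(self.cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            self.corr = self.cov / np.outer(sd, sd)
        self.corr[~np.isfinite(self.corr)] = 0.0

    def stderr(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    def correlation(self, label_a: str, label_b: str) -> float:
        ia, ib = self.labels.index(label_a), self.labels.index(label_b)
        return float(self.corr[ia, ib])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.replicas, columns=self.labels)

    def covariance_frame(self):
        import pandas as pd

        return pd.DataFrame(self.cov, index=self.labels, columns=self.labels)

    def summary(self) -> str:
        lines = [
            "Bootstrap error analysis",
            "=" * 64,
            f"replicas: {self.replicas.shape[0]}",
            f"{'parameter':<28}{'mean':>16}{'std err':>16}",
        ]
        for i, lab in enumerate(self.labels):
            lines.append(f"{lab:<28}{self.mean[i]:>16.8g}{self.se[i]:>16.3g}")
        return "\n".join(lines)
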