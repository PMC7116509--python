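"""Static plots: observed/fitted contour overlays and 3D waterfalls."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_spectrum", "plot_overlay", "plot_waterfall"]


def _levels(data: np.ndarray, n: int) -> np.ndarray:
    top = float(np.max(np.abs(data)))
    base = top * 0.08
    return base * (top / base) ** (np.arange(n) / max(n - 1, 1))


def plot_spectrum(spectrum, ax=None, levels: int = 8, color: str = "C0"):
    """Contour plot of a single 2D spectrum (ppm axes, inverted)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lv = _levels(spectrum.data, levels)
    ax.contour(spectrum.ppm_direct, spectrum.ppm_indirect, spectrum.data,
               levels=lv, colors=color, linewidths=0.7)
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel(r"$^1$H (ppm)")
    ax.set_ylabel(r"$^{15}$N (ppm)")
    return ax


def plot_overlay(results, point: int = 0, ax=None, levels: int = 8):
    """Observed (blue) and fitted (red) contours for one titration point."""
    obs = results.model.dataset.points[point].spectrum
    fit = results.fittedvalues[point]
    ax = plot_spectrum(obs, ax=ax, levels=levels, color="C0")
    plot_spectrum(fit, ax=ax, levels=levels, color="C3")
    ax.set_title(f"titration point {point}: observed (blue) vs fitted (red)")
    return ax


def plot_waterfall(results, point: int = 0, ax=None):
    """3D surface view of observed and fitted intensities."""
    import matplotlib.pyplot as plt

    obs = results.model.dataset.points[point].spectrum
    fit = results.fittedvalues[point]
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    H, N = np.meshgrid(obs.ppm_direct, obs.ppm_indirect)
    ax.plot_wireframe(H, N, obs.data, color="gray", linewidth=0.4,
                      rstride=2, cstride=2)
    ax.plot_wireframe(H, N, fit.data, color="m", linewidth=0.4,
                      rstride=2, cstride=2)
    ax.set_xlabel(r"$^1$H (ppm)")
    ax.set_ylabel(r"$^{15}$N (ppm)")
    return ax
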