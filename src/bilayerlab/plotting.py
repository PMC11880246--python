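"""Quick-look figures: trace segments, all-point histograms with fits, I-V.

Each function draws on a provided or fresh matplotlib Axes and returns it.
"""

from __future__ import annotations

import numpy as np

from .amplitude_hist import AllPointHistogram, GaussianPairFit, _two_gaussians
from .channel_sim import Trace
from .iv_fit import IVDataset, IVFitResult

__all__ = ["plot_trace", "plot_histogram", "plot_iv"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trace(trace: Trace, start_s: float = 0.0, duration_s: float = 2.0, ax=None):
    ax = _axes(ax)
    fs = trace.sampling_rate_Hz
    i0 = int(start_s * fs)
    i1 = min(trace.n_samples, i0 + int(duration_s * fs))
    ax.plot(trace.time_s[i0:i1], trace.current_pA[i0:i1], lw=0.4, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("current (pA)")
    ax.set_title(f"{trace.holding_potential_mV:+.0f} mV")
    return ax


def plot_histogram(
    hist: AllPointHistogram, fit: GaussianPairFit | None = None, ax=None
):
    ax = _axes(ax)
    ax.stairs(hist.counts, hist.bin_edges_pA, fill=True, alpha=0.5, color="gray")
    if fit is not None:
        x = np.linspace(hist.bin_edges_pA[0], hist.bin_edges_pA[-1], 500)
        n, w = hist.n_samples, hist.bin_width_pA
        params = []
        for comp in (fit.closed, fit.open):
            amp = comp.weight * n * w / (comp.sd_pA * np.sqrt(2 * np.pi))
            params += [amp, comp.mean_pA, comp.sd_pA]
        ax.plot(x, _two_gaussians(x, *params), color="C3")
    ax.set_xlabel("current (pA)")
    ax.set_ylabel("samples")
    return ax


def plot_iv(data: IVDataset, fit: IVFitResult | None = None, ax=None):
    ax = _axes(ax)
    pts = data.points
    yerr = pts["se_pA"] if "se_pA" in pts.columns else None
    ax.errorbar(
        pts["holding_mV"], pts["current_pA"], yerr=yerr, fmt="o", color="k"
    )
    if fit is not None:
        v = np.linspace(pts["holding_mV"].min(), pts["holding_mV"].max(), 50)
        ax.plot(v, fit.slope_pA_per_mV * v + fit.intercept_pA, color="C0")
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("holding potential (mV)")
    ax.set_ylabel("unitary current (pA)")
    return ax
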