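"""All-point amplitude histograms and two-Gaussian unitary-amplitude fits.

The all-point histogram of a single-channel record shows one peak per
conductance level; for a two-level (closed/open) channel the distance
between the two Gaussian means is the unitary current.  Following common
practice in commercial analysis software, the fit is a deterministic
nonlinear least-squares fit of a two-Gaussian sum to the binned counts
(not an EM fit to raw samples), initialized at the two highest
well-separated local maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .channel_sim import Trace
from .exceptions import DegenerateFitError, FitError, InputError

__all__ = [
    "AllPointHistogram",
    "GaussianComponent",
    "GaussianPairFit",
    "all_point_histogram",
    "fit_amplitude_gaussians",
]

#: Minimum separation (pA) between the two initializing histogram peaks.
MIN_PEAK_SEPARATION_PA = 0.5


@dataclass(frozen=True)
class AllPointHistogram:
    """Histogram of every current sample in a trace, uniform bins."""

    bin_edges_pA: np.ndarray
    counts: np.ndarray
    bin_width_pA: float

    def __post_init__(self):
        edges = np.asarray(self.bin_edges_pA, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges_pA", edges)
        object.__setattr__(self, "counts", counts)
        if len(edges) != len(counts) + 1:
            raise InputError("need len(edges) == len(counts) + 1")
        if np.any(np.diff(edges) <= 0):
            raise InputError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise InputError("counts must be >= 0")

    @property
    def centers_pA(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_pA[:-1] + self.bin_edges_pA[1:])

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GaussianComponent:
    mean_pA: float
    sd_pA: float
    weight: float  # fraction of all samples in this component


@dataclass(frozen=True)
class GaussianPairFit:
    """Two-component Gaussian fit of an all-point histogram.

    The component nearer the baseline is labeled closed; the unitary
    amplitude is the signed difference mean_open - mean_closed.
    """

    closed: GaussianComponent
    open: GaussianComponent
    rss: float  # residual sum of squares on bin counts
    baseline_pA: float

    def __post_init__(self):
        for c in (self.closed, self.open):
            if c.sd_pA <= 0:
                raise FitError("fitted SDs must be positive")
            if c.weight <= 0:
                raise FitError("fitted weights must be positive")
        if self.closed.weight + self.open.weight > 1 + 1e-9:
            raise FitError("component weights exceed 1")
        if self.unitary_amplitude_pA == 0:
            raise FitError("zero unitary amplitude")

    @property
    def unitary_amplitude_pA(self) -> float:
        return self.open.mean_pA - self.closed.mean_pA

    def summary(self) -> str:
        lines = [
            "Two-Gaussian amplitude fit",
            f"  closed: mean {self.closed.mean_pA:+.3f} pA, "
            f"sd {self.closed.sd_pA:.3f} pA, weight {self.closed.weight:.3f}",
            f"  open:   mean {self.open.mean_pA:+.3f} pA, "
            f"sd {self.open.sd_pA:.3f} pA, weight {self.open.weight:.3f}",
            f"  unitary amplitude: {self.unitary_amplitude_pA:+.3f} pA",
            f"  RSS: {self.rss:.4g}",
        ]
        return "\n".join(lines)


def all_point_histogram(
    trace: Trace | np.ndarray, bin_width_pA: float = 0.05
) -> AllPointHistogram:
    """Uniform-bin histogram of all samples, spanning [min, max].

    The bin grid is anchored at the sample minimum with the requested
    width; the last bin is extended to include the maximum, so the total
    count always equals the number of samples.
    """
    samples = trace.current_pA if isinstance(trace, Trace) else np.asarray(trace, float)
    if samples.size == 0:
        raise InputError("cannot histogram an empty trace")
    if bin_width_pA <= 0:
        raise InputError("bin_width_pA must be positive")
    lo, hi = float(samples.min()), float(samples.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_pA)))
    edges = lo + bin_width_pA * np.arange(n_bins + 1)
    if edges[-1] < hi:  # guard against rounding in the ceil
        edges = np.append(edges, edges[-1] + bin_width_pA)
    counts, _ = np.histogram(samples, bins=edges)
    return AllPointHistogram(
        bin_edges_pA=edges, counts=counts, bin_width_pA=bin_width_pA
    )


def _two_gaussians(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - m2) / s2) ** 2
    )


def _single_gaussian_fit(hist: AllPointHistogram) -> GaussianComponent:
    """Moment-based single-Gaussian description (for degenerate histograms)."""
    x, c = hist.centers_pA, hist.counts.astype(float)
    total = c.sum()
    mean = float((x * c).sum() / total)
    var = float(((x - mean) ** 2 * c).sum() / total)
    return GaussianComponent(
        mean_pA=mean, sd_pA=float(np.sqrt(max(var, 1e-12))), weight=1.0
    )


def fit_amplitude_gaussians(
    hist: AllPointHistogram,
    baseline_pA: float | None = None,
    min_separation_pA: float = MIN_PEAK_SEPARATION_PA,
) -> GaussianPairFit:
    """Fit a sum of two Gaussians to the binned counts.

    Initialization takes the histogram's tallest local maximum and the
    tallest other maximum at least ``min_separation_pA`` away.  If no such
    pair exists the histogram is considered unimodal and a
    :class:`~bilayerlab.exceptions.DegenerateFitError` is raised carrying a
    single-component fit.

    ``baseline_pA`` decides which fitted component is labeled closed (the
    nearer one); by default the taller initial peak's position is used,
    which is correct whenever the channel spends the majority of the record
    at the closed level.
    """
    x = hist.centers_pA
    c = hist.counts.astype(float)
    if len(x) < 4 or np.count_nonzero(c) < 2:
        raise DegenerateFitError(
            "histogram too narrow for a two-component fit",
            single_fit=_single_gaussian_fit(hist),
        )
    prominence = 0.02 * c.max()
    peaks, _ = signal.find_peaks(
        np.concatenate(([0.0], c, [0.0])), prominence=prominence
    )
    peaks -= 1  # undo the padding used to allow edge peaks
    if len(peaks) == 0:
        raise DegenerateFitError(
            "no histogram peaks found", single_fit=_single_gaussian_fit(hist)
        )
    peaks = peaks[np.argsort(c[peaks])[::-1]]  # tallest first
    p1 = peaks[0]
    p2 = None
    for cand in peaks[1:]:
        if abs(x[cand] - x[p1]) >= min_separation_pA:
            p2 = cand
            break
    if p2 is None:
        raise DegenerateFitError(
            "histogram is unimodal (no second peak at >= "
            f"{min_separation_pA} pA separation)",
            single_fit=_single_gaussian_fit(hist),
        )
    def _local_sd(peak: int) -> float:
        # second moment in a window around the peak; floors at 1/4 bin so a
        # delta-like level (noiseless trace) still yields a finite width
        half = max(3, int(round(0.25 * abs(x[p2] - x[p1]) / hist.bin_width_pA)))
        sl = slice(max(0, peak - half), peak + half + 1)
        mass = c[sl].sum()
        if mass <= 0:
            return hist.bin_width_pA
        mu = (x[sl] * c[sl]).sum() / mass
        var = (((x[sl] - mu) ** 2) * c[sl]).sum() / mass
        return float(max(np.sqrt(var), 0.25 * hist.bin_width_pA))

    p0 = [c[p1], x[p1], _local_sd(p1), c[p2], x[p2], _local_sd(p2)]
    bounds = (
        [0.0, x[0], 1e-6, 0.0, x[0], 1e-6],
        [np.inf, x[-1], x[-1] - x[0] + 1e-6] * 2,
    )
    try:
        popt, _ = optimize.curve_fit(
            _two_gaussians, x, c, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"two-Gaussian fit did not converge: {exc}") from exc
    a1, m1, s1, a2, m2, s2 = popt
    rss = float(np.sum((_two_gaussians(x, *popt) - c) ** 2))
    n_total = hist.n_samples
    w1 = a1 * s1 * np.sqrt(2 * np.pi) / (n_total * hist.bin_width_pA)
    w2 = a2 * s2 * np.sqrt(2 * np.pi) / (n_total * hist.bin_width_pA)
    wsum = w1 + w2
    if wsum > 1.0:  # least squares does not constrain total mass
        w1, w2 = w1 / wsum, w2 / wsum
    if baseline_pA is None:
        baseline_pA = float(x[p1])
    comps = [
        GaussianComponent(float(m1), float(s1), float(w1)),
        GaussianComponent(float(m2), float(s2), float(w2)),
    ]
    comps.sort(key=lambda comp: abs(comp.mean_pA - baseline_pA))
    closed, open_ = comps
    return GaussianPairFit(
        closed=closed, open=open_, rss=rss, baseline_pA=float(baseline_pA)
    )
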