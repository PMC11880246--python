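"""Synthetic single-channel trace generator.

Emulates a planar-lipid-bilayer recording of one or more identical,
independent ion channels, each gating between a single closed and a single
open conformation as a continuous-time two-state Markov process:

    closed --k_open-->  open
    open  --k_close--> closed

Dwell times are therefore exponential with means 1/k_open (closed) and
1/k_close (open), and the stationary open probability is
k_open / (k_open + k_close).  The open-channel current is ohmic,
i = g (V - E_rev), with slope conductance g and reversal potential E_rev
(supplied directly or computed from a bath via :mod:`~bilayerlab.electrochem`).

Rendering mimics acquisition: the ideal piecewise-constant current is
sampled on the ADC clock (default 10 kHz), white Gaussian noise is added,
and the sum is passed through a causal low-pass Butterworth filter
(default 4 poles at 1 kHz) standing in for the recording amplifier's
hardware filter.  Gating events are realized on the continuous time axis
first, so openings briefer than a sample period can vanish at rendering —
exactly as they would in a real digitized record.

All randomness is driven by explicit integer seeds; identical inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as _signal

from .exceptions import DomainError, InputError
from . import electrochem

__all__ = [
    "ChannelModel",
    "GatingPath",
    "Trace",
    "unitary_current",
    "simulate_gating",
    "render_trace",
    "simulate_trace",
]


def unitary_current(
    conductance_pS: float, holding_mV: float, e_rev_mV: float
) -> float:
    """Open-channel current in pA: g (V - E_rev) with g in pS and V in mV."""
    if conductance_pS <= 0:
        raise DomainError("conductance must be positive")
    return conductance_pS * (holding_mV - e_rev_mV) / 1000.0


@dataclass(frozen=True)
class ChannelModel:
    """Ground-truth parameters of the simulated channel and rig.

    Parameters
    ----------
    conductance_pS : float
        Unitary slope conductance, pS.
    e_rev_mV : float
        Reversal potential, mV.  Use :meth:`from_bath` to derive it from
        solution compositions.
    k_open_per_s, k_close_per_s : float
        Closed->open and open->closed transition rates, 1/s.
    n_channels : int
        Number of identical independent channels in the bilayer.
    noise_sd_pA : float
        SD of the additive white Gaussian noise, before filtering.
    filter_cutoff_Hz : float or None
        Low-pass corner frequency; ``None`` disables filtering.
    filter_order : int
        Butterworth pole count of the acquisition-filter stand-in.
    sampling_rate_Hz : float
        ADC sampling rate; must exceed twice the filter cutoff.
    """

    conductance_pS: float
    e_rev_mV: float
    k_open_per_s: float
    k_close_per_s: float
    n_channels: int = 1
    noise_sd_pA: float = 0.8
    filter_cutoff_Hz: float | None = 1000.0
    filter_order: int = 4
    sampling_rate_Hz: float = 10000.0

    def __post_init__(self):
        if self.conductance_pS <= 0:
            raise DomainError("conductance_pS must be positive")
        if self.k_open_per_s <= 0 or self.k_close_per_s <= 0:
            raise DomainError("gating rates must be positive")
        if self.n_channels < 1:
            raise DomainError("n_channels must be >= 1")
        if self.noise_sd_pA < 0:
            raise DomainError("noise_sd_pA must be >= 0")
        if self.sampling_rate_Hz <= 0:
            raise DomainError("sampling_rate_Hz must be positive")
        if (
            self.filter_cutoff_Hz is not None
            and self.sampling_rate_Hz <= 2.0 * self.filter_cutoff_Hz
        ):
            raise DomainError(
                "sampling_rate_Hz must exceed 2 x filter_cutoff_Hz "
                f"({self.sampling_rate_Hz} <= 2 x {self.filter_cutoff_Hz})"
            )

    @classmethod
    def from_bath(
        cls, conductance_pS: float, bath: "electrochem.BathPair", **kwargs: Any
    ) -> "ChannelModel":
        """Build a model whose reversal potential follows from a bath.

        Uses the extended GHK solver when a permeant divalent cation is
        present, the monovalent closed form otherwise.
        """
        if any(s.valence == +2 and s.permeability > 0 for s in bath.species):
            e_rev = electrochem.ghk_reversal_extended(bath)
        else:
            e_rev = electrochem.ghk_reversal_monovalent(bath)
        return cls(
            conductance_pS=conductance_pS, e_rev_mV=e_rev, **kwargs
        )

    @property
    def open_probability_stationary(self) -> float:
        """Stationary per-channel open probability k_open/(k_open+k_close)."""
        return self.k_open_per_s / (self.k_open_per_s + self.k_close_per_s)

    def unitary_current(self, holding_mV: float) -> float:
        return unitary_current(self.conductance_pS, holding_mV, self.e_rev_mV)


@dataclass(frozen=True)
class GatingPath:
    """Piecewise-constant open-channel count over time.

    ``open_counts[k]`` channels are open for ``dwells_ms[k]`` milliseconds;
    dwells tile ``[0, total_duration_ms]`` and consecutive counts differ.
    """

    open_counts: np.ndarray  # int, number of open channels per segment
    dwells_ms: np.ndarray  # float, segment durations
    total_duration_ms: float

    def __post_init__(self):
        counts = np.asarray(self.open_counts, dtype=int)
        dwells = np.asarray(self.dwells_ms, dtype=float)
        object.__setattr__(self, "open_counts", counts)
        object.__setattr__(self, "dwells_ms", dwells)
        if counts.shape != dwells.shape or counts.ndim != 1 or counts.size == 0:
            raise InputError("open_counts and dwells_ms must be equal-length 1-D")
        if np.any(dwells <= 0):
            raise InputError("all dwell times must be positive")
        if not np.isclose(dwells.sum(), self.total_duration_ms, rtol=1e-9):
            raise InputError("dwells must sum to total_duration_ms")
        if np.any(counts[1:] == counts[:-1]):
            raise InputError("consecutive segments must have different counts")

    @property
    def boundaries_ms(self) -> np.ndarray:
        """Segment end times, length len(dwells)."""
        return np.cumsum(self.dwells_ms)

    @property
    def open_fraction(self) -> float:
        """Fraction of time with at least one channel open."""
        return float(
            self.dwells_ms[self.open_counts > 0].sum() / self.total_duration_ms
        )

    @property
    def mean_open_count(self) -> float:
        """Time-averaged open-channel count (the NPo of the ground truth)."""
        return float(
            (self.open_counts * self.dwells_ms).sum() / self.total_duration_ms
        )

    def dwell_times_ms(self, state: str) -> np.ndarray:
        """Dwell durations of fully 'closed' (count 0) or 'open' (count > 0)
        segments; for n_channels == 1 these are the per-state sojourn times."""
        mask = self.open_counts > 0 if state == "open" else self.open_counts == 0
        return self.dwells_ms[mask]


def _single_channel_transitions(
    k_open: float, k_close: float, duration_ms: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Transition times (ms, strictly inside (0, duration)) and initial state
    (0 closed / 1 open) for one channel, initialized at stationarity."""
    p_open = k_open / (k_open + k_close)
    state = int(rng.random() < p_open)
    times = []
    t = 0.0
    s = state
    while True:
        rate = k_close if s else k_open  # exit rate of the current state, 1/s
        t += rng.exponential(1000.0 / rate)
        if t >= duration_ms:
            break
        times.append(t)
        s = 1 - s
    return np.asarray(times), state


def simulate_gating(
    model: ChannelModel, duration_ms: float, seed: int | None = None
) -> GatingPath:
    """Simulate the aggregate open-count path of ``model.n_channels``
    independent two-state channels for ``duration_ms``.

    Each channel starts in its stationary distribution and draws exponential
    dwell times at the exit rate of its current state.  An explicit ``seed``
    is required; identical seeds give identical paths.
    """
    if duration_ms <= 0:
        raise DomainError("duration_ms must be positive")
    if seed is None:
        raise InputError("an explicit seed is required for simulation")
    rng = np.random.default_rng(seed)
    per_channel = [
        _single_channel_transitions(
            model.k_open_per_s, model.k_close_per_s, duration_ms, rng
        )
        for _ in range(model.n_channels)
    ]
    initial_open = sum(s0 for _, s0 in per_channel)
    # Each transition flips exactly one channel by +/-1; a channel starting
    # closed contributes +1, -1, +1, ... and one starting open the opposite.
    times = np.concatenate([t for t, _ in per_channel])
    signs = np.concatenate(
        [
            (1 if s0 == 0 else -1) * (1 - 2 * (np.arange(len(t)) % 2))
            for t, s0 in per_channel
        ]
    ) if times.size else np.empty(0, dtype=int)
    order = np.argsort(times, kind="stable")
    times, signs = times[order], signs[order]
    counts_at = initial_open + np.cumsum(signs)
    edges = np.concatenate(([0.0], times, [duration_ms]))
    seg_counts = np.concatenate(([initial_open], counts_at)).astype(int)
    dwells = np.diff(edges)
    # Drop zero-length segments (coincident transition times; measure zero)
    keep = dwells > 0
    seg_counts, dwells = seg_counts[keep], dwells[keep]
    # Merge consecutive equal counts (possible for n_channels > 1)
    if seg_counts.size > 1:
        change = np.concatenate(([True], seg_counts[1:] != seg_counts[:-1]))
        idx = np.flatnonzero(change)
        merged_dwells = np.add.reduceat(dwells, idx)
        seg_counts = seg_counts[idx]
        dwells = merged_dwells
    return GatingPath(
        open_counts=seg_counts,
        dwells_ms=dwells,
        total_duration_ms=float(duration_ms),
    )


@dataclass(frozen=True)
class Trace:
    """A sampled current record with its acquisition metadata."""

    sampling_rate_Hz: float
    holding_potential_mV: float
    current_pA: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        cur = np.asarray(self.current_pA, dtype=float)
        object.__setattr__(self, "current_pA", cur)
        if cur.ndim != 1:
            raise InputError("current_pA must be 1-D")
        if cur.size and not np.all(np.isfinite(cur)):
            raise InputError("current samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.current_pA.size)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sampling_rate_Hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_Hz


def render_trace(
    path: GatingPath,
    model: ChannelModel,
    holding_mV: float,
    seed: int | None = None,
) -> Trace:
    """Render a gating path into a noisy, filtered, sampled current trace.

    Samples the ideal current (open count x unitary current) at
    ``model.sampling_rate_Hz``, adds white Gaussian noise of SD
    ``model.noise_sd_pA``, then applies a causal ``model.filter_order``-pole
    Butterworth low-pass at ``model.filter_cutoff_Hz`` (skipped when the
    cutoff is ``None``).  Noise generation requires a seed unless
    ``noise_sd_pA`` is zero.
    """
    if model.noise_sd_pA > 0 and seed is None:
        raise InputError("an explicit seed is required when noise_sd_pA > 0")
    fs = model.sampling_rate_Hz
    n = int(round(path.total_duration_ms / 1000.0 * fs))
    t_ms = (np.arange(n) / fs) * 1000.0
    # open count at each sample time: segment k covers [edge_{k-1}, edge_k)
    idx = np.searchsorted(path.boundaries_ms, t_ms, side="right")
    idx = np.minimum(idx, len(path.open_counts) - 1)
    i_unit = model.unitary_current(holding_mV)
    ideal = path.open_counts[idx] * i_unit
    if model.noise_sd_pA > 0:
        rng = np.random.default_rng(seed)
        samples = ideal + rng.normal(0.0, model.noise_sd_pA, size=n)
    else:
        samples = ideal.astype(float)
    if model.filter_cutoff_Hz is not None:
        sos = _signal.butter(
            model.filter_order, model.filter_cutoff_Hz, btype="low", fs=fs,
            output="sos",
        )
        # Initialize the filter at the first sample's value to avoid a
        # start-up transient from zero.
        zi = _signal.sosfilt_zi(sos) * samples[0]
        samples, _ = _signal.sosfilt(sos, samples, zi=zi)
    return Trace(
        sampling_rate_Hz=fs,
        holding_potential_mV=holding_mV,
        current_pA=samples,
        metadata={
            "synthetic": True,
            "seed": seed,
            "model": {
                "conductance_pS": model.conductance_pS,
                "e_rev_mV": model.e_rev_mV,
                "k_open_per_s": model.k_open_per_s,
                "k_close_per_s": model.k_close_per_s,
                "n_channels": model.n_channels,
                "noise_sd_pA": model.noise_sd_pA,
                "filter_cutoff_Hz": model.filter_cutoff_Hz,
                "filter_order": model.filter_order,
            },
        },
    )


def simulate_trace(
    model: ChannelModel,
    duration_ms: float,
    holding_mV: float,
    seed: int,
) -> Trace:
    """Convenience wrapper: gating + rendering with independent sub-seeds
    derived from ``seed`` via :class:`numpy.random.SeedSequence`."""
    gating_seed, noise_seed = np.random.SeedSequence(seed).spawn(2)
    path = simulate_gating(
        model, duration_ms, seed=int(gating_seed.generate_state(1)[0] % 2**31)
    )
    trace = render_trace(
        path, model, holding_mV,
        seed=int(noise_seed.generate_state(1)[0] % 2**31),
    )
    trace.metadata["master_seed"] = seed
    return trace
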