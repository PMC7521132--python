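"""Tap extraction and circular synchronization scoring.

Synchronization with the 600-ms beat grid is scored with vector strength,

    VS = |sum_j exp(i*phi_j)| / N,

the modulus of the mean resultant of unit phasors at the tap phases phi_j
relative to the nominal isochronous grid.  VS is 1 for perfectly
phase-consistent tapping and near 0 for random tapping.  Circular standard
deviation sqrt(-2 ln VS) is the equivalent dispersion measure.

Phases are computed against the *nominal* grid (omitted beats included):
the task instructs participants to keep tapping where the beat "should be",
so the grid, not the audible beats, drives the phase reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TapSeries",
    "TapPhaseSet",
    "SyncScore",
    "detect_tap_onsets",
    "tap_phases",
    "vector_strength",
    "circular_sd",
    "score_taps",
]


class UndefinedScoreError(ValueError):
    """A circular score is requested on an empty or degenerate phase set."""


@dataclass(frozen=True)
class TapSeries:
    """Tap onset times in seconds, strictly increasing."""

    onsets: np.ndarray
    source: str = "detected"  # {"detected", "simulated"}

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.ndim != 1:
            raise ValueError("onsets must be 1-D")
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("tap onsets must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass(frozen=True)
class TapPhaseSet:
    """Tap phases in radians, wrapped to [-pi, pi)."""

    phases: np.ndarray
    ioi: float  # s

    @property
    def n(self) -> int:
        return len(self.phases)


@dataclass(frozen=True)
class SyncScore:
    vs: float
    circ_sd: float  # radians
    n_taps: int


def detect_tap_onsets(
    signal: np.ndarray,
    rate: float,
    threshold: float = 0.3,
    refractory: float = 0.200,
) -> TapSeries:
    """Extract tap onsets from a piezo-like waveform.

    Onsets are upward crossings of ``threshold * max(|signal|)``; crossings
    within ``refractory`` seconds of an accepted onset are suppressed (piezo
    hits ring).  An all-zero signal yields an empty series.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    peak = np.max(np.abs(signal))
    if peak == 0:
        return TapSeries(np.empty(0), source="detected")
    level = threshold * peak
    above = signal >= level
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    kept: list[int] = []
    n_refr = refractory * rate
    for c in crossings:
        if not kept or c - kept[-1] >= n_refr:
            kept.append(int(c))
    return TapSeries(np.asarray(kept, dtype=float) / rate, source="detected")


def tap_phases(taps: TapSeries, grid_start: float = 0.0, ioi: float = 0.6) -> TapPhaseSet:
    """Phase of each tap relative to the nominal isochronous grid.

    phi = wrap(2*pi*frac((t - grid_start)/ioi)) into [-pi, pi).  Taps before
    the first grid line are dropped (no defined phase context).
    """
    if ioi <= 0:
        raise ValueError("ioi must be positive")
    t = taps.onsets[taps.onsets >= grid_start]
    frac = np.mod((t - grid_start) / ioi, 1.0)
    phases = np.mod(2 * np.pi * frac + np.pi, 2 * np.pi) - np.pi
    return TapPhaseSet(phases=phases, ioi=ioi)


def vector_strength(phases: TapPhaseSet | np.ndarray) -> float:
    """Mean resultant length of the unit phasors at the tap phases."""
    phi = phases.phases if isinstance(phases, TapPhaseSet) else np.asarray(phases)
    if len(phi) == 0:
        raise UndefinedScoreError("vector strength undefined for zero taps")
    vs = float(np.abs(np.exp(1j * phi).mean()))
    return min(vs, 1.0)


def circular_sd(phases: TapPhaseSet | np.ndarray | float) -> float:
    """Circular standard deviation sqrt(-2 ln VS), in radians.

    Accepts a phase set or a precomputed vector strength.  VS of 0 gives
    +inf (uniform phases carry no preferred direction).
    """
    vs = phases if isinstance(phases, (int, float)) else vector_strength(phases)
    if vs < 0 or vs > 1:
        raise ValueError("vector strength outside [0, 1]")
    if vs == 0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(vs)))


def score_taps(taps: TapSeries, grid_start: float = 0.0, ioi: float = 0.6) -> SyncScore:
    """Convenience wrapper: phases -> (VS, circular SD, N)."""
    ph = tap_phases(taps, grid_start=grid_start, ioi=ioi)
    vs = vector_strength(ph)
    return SyncScore(vs=vs, circ_sd=circular_sd(vs), n_taps=ph.n)
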