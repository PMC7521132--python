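"""N1-P2 evoked-potential pipeline and the timing response index (TRI).

Stages, in the order they run on a session recording:

1. :func:`decode_triggers` — recover event onsets and labels from the
   amplitude-coded square-wave trigger channel.
2. :func:`preprocess` — downsample the EEG to 500 Hz, low-pass at 30 Hz
   with a zero-net-delay Hamming-windowed-sinc FIR, re-index markers.
3. :func:`extract_epochs` / :func:`baseline_correct` /
   :func:`reject_artifacts` — epoch the key events (deviant /
   standard_key) with a 50-ms pre-stimulus baseline and a +/-100 uV
   extreme-value rejection; a subject with fewer than 80 kept trials is
   flagged for exclusion.
4. :func:`average_evoked` — per-subject and grand-average evoked
   potentials per condition.
5. :func:`find_component_windows` — locate the grand-average N1 (minimum)
   and P2 (maximum) per condition and open mean-amplitude windows of
   +/-halfwidth around them.
6. :func:`compute_tri` — per-condition N1-P2 magnitude (P2 mean amplitude
   minus N1 mean amplitude) and the TRI, the deviant-minus-standard
   difference of those magnitudes.  Variants vary the window halfwidth
   (50/30/20 ms) or use per-subject peak voltages (optionally averaged
   over 20 ms around each peak).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .paradigm import DEFAULT_CODE_MAP

__all__ = [
    "ContinuousRecording",
    "EventMarkers",
    "EpochSet",
    "ComponentWindows",
    "TRIResult",
    "decode_triggers",
    "design_lowpass_fir",
    "preprocess",
    "extract_epochs",
    "baseline_correct",
    "reject_artifacts",
    "average_evoked",
    "grand_average",
    "find_component_windows",
    "mean_amplitude",
    "compute_tri",
    "TRI_VARIANTS",
]

TARGET_RATE = 500.0  # Hz, analysis rate
KEY_LABELS = ("deviant", "standard_key")
#: Map pipeline condition names onto the event labels that feed them.
CONDITION_OF_LABEL = {"deviant": "deviant", "standard_key": "standard"}
TRI_VARIANTS = ("mean50", "mean30", "mean20", "peak", "peak_mean20")


class UnknownCodeError(ValueError):
    """A trigger plateau matches no amplitude in the code map."""


class PipelineError(RuntimeError):
    pass


@dataclass
class ContinuousRecording:
    """Multichannel continuous signal; EEG channels in microvolts."""

    data: np.ndarray  # channels x samples
    rate: float  # Hz
    ch_names: list[str]
    units: str = "uV"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel-name count mismatch")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EventMarkers:
    """Decoded events: 0-based sample indices (native rate) and labels."""

    samples: np.ndarray  # int sample indices, strictly increasing
    labels: np.ndarray  # object array of label strings
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.samples) > 1 and np.any(np.diff(self.samples) <= 0):
            raise ValueError("marker samples must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def onsets(self) -> np.ndarray:
        return self.samples / self.rate


@dataclass
class EpochSet:
    """Stimulus-locked voltage segments (epochs x samples, uV)."""

    data: np.ndarray
    labels: np.ndarray  # per-epoch label in KEY_LABELS
    rate: float
    window: tuple[float, float]  # s relative to onset, half-open [t0, t1)
    kept: np.ndarray = field(default=None)  # bool per epoch
    n_dropped_bounds: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.kept is None:
            self.kept = np.ones(len(self.labels), dtype=bool)
        if self.window[0] > -0.05 + 1e-9:
            raise ValueError("epoch window must include the [-50, 0) ms baseline")

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.window[0] + np.arange(n) / self.rate

    def n_kept(self, label: str | None = None) -> int:
        mask = self.kept if label is None else self.kept & (self.labels == label)
        return int(mask.sum())


@dataclass(frozen=True)
class ComponentWindows:
    """Per-condition N1/P2 latencies and mean-amplitude windows (seconds)."""

    n1_lat: dict  # condition -> s
    p2_lat: dict
    n1_window: dict  # condition -> (t0, t1) closed interval, s
    p2_window: dict
    halfwidth: float  # s

    def with_halfwidth(self, halfwidth: float, epoch_window: tuple[float, float]) -> "ComponentWindows":
        """Same peak latencies, different window halfwidth."""
        clip = lambda lat: (
            max(lat - halfwidth, epoch_window[0]),
            min(lat + halfwidth, epoch_window[1]),
        )
        return ComponentWindows(
            n1_lat=dict(self.n1_lat),
            p2_lat=dict(self.p2_lat),
            n1_window={c: clip(l) for c, l in self.n1_lat.items()},
            p2_window={c: clip(l) for c, l in self.p2_lat.items()},
            halfwidth=halfwidth,
        )


@dataclass
class TRIResult:
    """Per-subject N1-P2 magnitudes and their deviant-standard difference."""

    n1_mean: dict  # condition -> uV
    p2_mean: dict
    magnitude: dict  # condition -> p2_mean - n1_mean, uV
    tri: float  # deviant magnitude - standard magnitude, uV
    variant: str
    n_kept: dict = field(default_factory=dict)  # condition -> kept epochs


# ---------------------------------------------------------------------------
# trigger decoding

def decode_triggers(
    trigger: np.ndarray,
    rate: float,
    code_map: dict | None = None,
    *,
    plateau_samples: int | None = None,
) -> EventMarkers:
    """Locate trigger pulses and classify their amplitudes to event codes.

    Rising edges are the first samples exceeding half the smallest code
    amplitude; the plateau amplitude (median over the pulse top) is
    assigned to the nearest code.  A plateau farther from every code than
    half the smallest gap between codes raises :class:`UnknownCodeError`.
    The ``base_short`` code decodes back to label ``base``.
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    trigger = np.asarray(trigger, dtype=float)
    amplitudes = np.array(sorted(code_map.values()))
    labels_by_amp = {v: k for k, v in code_map.items()}
    thresh = 0.5 * amplitudes.min()
    gaps = np.diff(amplitudes)
    tol = 0.5 * (gaps.min() if len(gaps) else amplitudes.min())

    above = trigger > thresh
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    if len(edges) == 0:
        return EventMarkers(np.empty(0, int), np.empty(0, object), rate)

    if plateau_samples is None:
        plateau_samples = max(int(round(0.005 * rate)), 1)
    # plateau amplitude: masked median over the pulse top, vectorised
    idx = np.minimum(edges[:, None] + np.arange(plateau_samples), len(trigger) - 1)
    top = trigger[idx]
    top = np.where(top > thresh, top, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        amps = np.nanmedian(top, axis=1)
    amps = np.where(np.isnan(amps), trigger[edges], amps)
    nearest_i = np.argmin(np.abs(amplitudes[None, :] - amps[:, None]), axis=1)
    err = np.abs(amps - amplitudes[nearest_i])
    if np.any(err > tol):
        bad = int(edges[np.argmax(err > tol)])
        raise UnknownCodeError(f"plateau at sample {bad} matches no code")
    names = {v: ("base" if k == "base_short" else k) for k, v in code_map.items()}
    labels = np.array([names[float(amplitudes[i])] for i in nearest_i], dtype=object)
    return EventMarkers(edges.astype(int), labels, rate)


# ---------------------------------------------------------------------------
# filtering / resampling

def design_lowpass_fir(
    rate: float = TARGET_RATE,
    passband_hz: float = 30.0,
    transition_hz: float = 10.0,
) -> np.ndarray:
    """Hamming-windowed-sinc low-pass FIR taps.

    Passband edge at ``passband_hz``, transition band up to
    ``passband_hz + transition_hz``; -6 dB point at the band centre.  Order
    from the standard Hamming design rule (3.3 / normalized transition
    width), forced odd so the delay is an integer number of samples.
    """
    numtaps = int(math.ceil(3.3 / (transition_hz / rate)))
    if numtaps % 2 == 0:
        numtaps += 1
    cutoff = passband_hz + transition_hz / 2.0
    return sps.firwin(numtaps, cutoff, window="hamming", fs=rate)


def preprocess(
    rec: ContinuousRecording,
    markers: EventMarkers | None = None,
    *,
    target_rate: float = TARGET_RATE,
    eeg_channels: list[str] | None = None,
) -> tuple[ContinuousRecording, EventMarkers | None]:
    """Downsample EEG channels to 500 Hz, then low-pass at 30 Hz.

    Resampling uses a polyphase filter (anti-alias protection built in);
    the low-pass FIR is linear-phase and applied delay-compensated so
    component latencies are preserved.  The trigger channel (any channel
    named ``TRIG``) is carried through by sample picking, unfiltered.
    Markers are re-indexed to the target rate by round-half-up.
    """
    if rec.rate < target_rate:
        raise ValueError("native rate below the analysis rate")
    if eeg_channels is None:
        eeg_channels = [c for c in rec.ch_names if c.upper() != "TRIG"]

    up, down = (np.array([rec.rate, target_rate]) / math.gcd(int(rec.rate), int(target_rate))).astype(int)[::-1]
    taps = design_lowpass_fir(target_rate)
    out_rows = []
    n_out = None
    for name in rec.ch_names:
        x = rec.channel(name)
        if name in eeg_channels:
            y = x if rec.rate == target_rate else sps.resample_poly(x, up, down)
            y = sps.fftconvolve(y, taps, mode="same")  # odd symmetric taps: zero net delay
        else:
            step = rec.rate / target_rate
            idx = np.floor(np.arange(0, len(x), step) + 0.5).astype(int)
            y = x[np.minimum(idx, len(x) - 1)]
        n_out = len(y) if n_out is None else min(n_out, len(y))
        out_rows.append(y)
    data = np.vstack([r[:n_out] for r in out_rows])
    out = ContinuousRecording(data, target_rate, list(rec.ch_names), units=rec.units)

    new_markers = None
    if markers is not None:
        scale = target_rate / markers.rate
        resampled = np.floor(markers.samples * scale + 0.5).astype(int)
        new_markers = EventMarkers(resampled, markers.labels.copy(), target_rate)
    return out, new_markers


# ---------------------------------------------------------------------------
# epoching

def extract_epochs(
    rec: ContinuousRecording,
    markers: EventMarkers,
    window: tuple[float, float] = (-0.05, 0.45),
    channel: str = "Cz",
) -> EpochSet:
    """Epoch the key events (deviant / standard_key) on one channel.

    The epoch window is half-open [t0, t1) relative to the event onset.
    Events whose window exceeds the recording bounds are dropped and
    counted in ``n_dropped_bounds``.
    """
    if abs(markers.rate - rec.rate) > 1e-9:
        raise ValueError("markers and recording rates differ")
    x = rec.channel(channel)
    i0 = int(round(window[0] * rec.rate))
    n = int(round((window[1] - window[0]) * rec.rate))
    rows, labels, dropped = [], [], 0
    for s, lab in zip(markers.samples, markers.labels):
        if lab not in KEY_LABELS:
            continue
        start = s + i0
        if start < 0 or start + n > len(x):
            dropped += 1
            continue
        rows.append(x[start : start + n])
        labels.append(lab)
    if not rows:
        raise PipelineError("no key events inside the recording")
    return EpochSet(
        data=np.vstack(rows),
        labels=np.asarray(labels, object),
        rate=rec.rate,
        window=window,
        n_dropped_bounds=dropped,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's own mean over the 50 ms preceding the beat."""
    t = epochs.times
    base = (t >= -0.05 - 1e-9) & (t < -1e-12)
    if not base.any():
        raise ValueError("no baseline samples in epoch window")
    data = epochs.data - epochs.data[:, base].mean(axis=1, keepdims=True)
    return EpochSet(data, epochs.labels.copy(), epochs.rate, epochs.window,
                    kept=epochs.kept.copy(), n_dropped_bounds=epochs.n_dropped_bounds)


def reject_artifacts(
    epochs: EpochSet, limit: float = 100.0, min_total: int = 80
) -> tuple[EpochSet, dict]:
    """Reject epochs with any sample beyond +/-limit uV.

    Returns the epoch set with updated ``kept`` flags and a report dict
    with kept/rejected counts per label and an ``excluded`` flag set when
    fewer than ``min_total`` epochs survive.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    ok = np.all(np.abs(epochs.data) <= limit, axis=1)
    kept = epochs.kept & ok
    out = EpochSet(epochs.data.copy(), epochs.labels.copy(), epochs.rate,
                   epochs.window, kept=kept, n_dropped_bounds=epochs.n_dropped_bounds)
    report = {
        "kept": {lab: int((kept & (epochs.labels == lab)).sum()) for lab in KEY_LABELS},
        "rejected": {lab: int((~kept & (epochs.labels == lab)).sum()) for lab in KEY_LABELS},
        "excluded": bool(kept.sum() < min_total),
        "n_total": int(len(kept)),
    }
    return out, report


# ---------------------------------------------------------------------------
# averaging and the TRI

def average_evoked(epochs: EpochSet) -> dict:
    """Per-condition evoked potential: mean over kept epochs.

    Returns ``{"deviant": waveform, "standard": waveform}``; raises if a
    condition has no kept epochs.
    """
    out = {}
    for lab in KEY_LABELS:
        mask = epochs.kept & (epochs.labels == lab)
        if not mask.any():
            raise PipelineError(f"no kept epochs for condition {lab!r}")
        out[CONDITION_OF_LABEL[lab]] = epochs.data[mask].mean(axis=0)
    return out


def grand_average(subject_evokeds: list[dict]) -> dict:
    """Unweighted mean over subjects' evoked potentials, per condition."""
    conditions = subject_evokeds[0].keys()
    return {c: np.mean([ev[c] for ev in subject_evokeds], axis=0) for c in conditions}


def find_component_windows(
    grand: dict,
    times: np.ndarray,
    *,
    n1_search: tuple[float, float] = (0.050, 0.200),
    p2_max: float = 0.320,
    halfwidth: float = 0.050,
) -> ComponentWindows:
    """Locate grand-average N1/P2 peaks per condition and open windows.

    N1 is the voltage minimum inside ``n1_search``; P2 the maximum between
    the found N1 latency and ``p2_max``.  Ties break to the earliest
    latency; windows are latency +/- halfwidth clipped to the epoch.
    """
    n1_lat, p2_lat, n1_win, p2_win = {}, {}, {}, {}
    t0, t1 = float(times[0]), float(times[-1])
    for cond, wave in grand.items():
        m = (times >= n1_search[0] - 1e-9) & (times <= n1_search[1] + 1e-9)
        seg_t, seg_v = times[m], wave[m]
        ln1 = float(seg_t[int(np.argmin(seg_v))])  # argmin takes first on ties
        m2 = (times > ln1 + 1e-9) & (times <= p2_max + 1e-9)
        if not m2.any():
            raise PipelineError(f"empty P2 search range for {cond!r}")
        seg_t, seg_v = times[m2], wave[m2]
        lp2 = float(seg_t[int(np.argmax(seg_v))])
        n1_lat[cond], p2_lat[cond] = ln1, lp2
        n1_win[cond] = (max(ln1 - halfwidth, t0), min(ln1 + halfwidth, t1))
        p2_win[cond] = (max(lp2 - halfwidth, t0), min(lp2 + halfwidth, t1))
    return ComponentWindows(n1_lat, p2_lat, n1_win, p2_win, halfwidth)


def mean_amplitude(wave: np.ndarray, times: np.ndarray, window: tuple[float, float]) -> float:
    """Arithmetic mean voltage over a closed time window."""
    m = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not m.any():
        raise ValueError("window outside epoch")
    return float(wave[m].mean())


def compute_tri(
    evoked: dict,
    times: np.ndarray,
    windows: ComponentWindows,
    variant: str = "mean50",
    n_kept: dict | None = None,
) -> TRIResult:
    """N1-P2 magnitudes per condition and the timing response index.

    ``mean50``/``mean30``/``mean20`` take the mean amplitude over windows
    of the named halfwidth around the grand-average peaks.  ``peak`` takes
    each subject's own minimum (N1) and maximum (P2) voltage inside the
    50-ms-halfwidth mean-amplitude windows; ``peak_mean20`` averages 20 ms
    (+/-10 ms) around those per-subject peaks.
    """
    if variant not in TRI_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    epoch_win = (float(times[0]), float(times[-1]))
    if variant.startswith("mean"):
        hw = int(variant[4:]) / 1000.0
        w = windows if abs(windows.halfwidth - hw) < 1e-12 else windows.with_halfwidth(hw, epoch_win)
        n1_mean = {c: mean_amplitude(v, times, w.n1_window[c]) for c, v in evoked.items()}
        p2_mean = {c: mean_amplitude(v, times, w.p2_window[c]) for c, v in evoked.items()}
    else:
        w = windows if abs(windows.halfwidth - 0.050) < 1e-12 else windows.with_halfwidth(0.050, epoch_win)
        n1_mean, p2_mean = {}, {}
        for c, v in evoked.items():
            mn1 = (times >= w.n1_window[c][0] - 1e-9) & (times <= w.n1_window[c][1] + 1e-9)
            mp2 = (times >= w.p2_window[c][0] - 1e-9) & (times <= w.p2_window[c][1] + 1e-9)
            tn1 = float(times[mn1][int(np.argmin(v[mn1]))])
            tp2 = float(times[mp2][int(np.argmax(v[mp2]))])
            if variant == "peak":
                n1_mean[c] = float(v[mn1].min())
                p2_mean[c] = float(v[mp2].max())
            else:  # peak_mean20
                n1_mean[c] = mean_amplitude(v, times, (max(tn1 - 0.010, epoch_win[0]), min(tn1 + 0.010, epoch_win[1])))
                p2_mean[c] = mean_amplitude(v, times, (max(tp2 - 0.010, epoch_win[0]), min(tp2 + 0.010, epoch_win[1])))
    magnitude = {c: p2_mean[c] - n1_mean[c] for c in evoked}
    tri = magnitude["deviant"] - magnitude["standard"]
    return TRIResult(n1_mean=n1_mean, p2_mean=p2_mean, magnitude=magnitude,
                     tri=tri, variant=variant, n_kept=dict(n_kept or {}))
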