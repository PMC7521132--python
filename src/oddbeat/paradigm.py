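"""Temporal-oddball paradigm generation.

Two passive-listening conditions are built around the same physical beat:

* **long** — an isochronous 800-ms stream into which an extra beat
  ("deviant") is occasionally inserted halfway between two beats, so the
  deviant is preceded by audible inter-onset intervals of 800 then 400 ms.
* **short** — an isochronous 400-ms stream with occasional omissions.  A
  beat that closes a single-omission gap is preceded by the *same* audible
  800-then-400-ms context but is fully expected; those beats are the
  adaptation-matched "standards" (label ``standard_key``).

A third ``tapping`` condition is the 600-ms-IOI stimulus used for the
sensorimotor-synchronization task (occasional omissions, participants tap
through them).

Event timelines are plain :class:`pandas.DataFrame` objects with columns
``onset`` (s, trial-relative), ``label`` (``base`` / ``deviant`` /
``omitted`` / ``standard_key``), ``condition`` and ``trial_index``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StimulusParams",
    "TrialSpec",
    "SessionPlan",
    "DEFAULT_CODE_MAP",
    "generate_trial",
    "label_key_events",
    "build_session",
    "render_tracks",
    "tone_burst",
]

#: Default inter-onset intervals per condition, in seconds.
CONDITION_IOI = {"long": 0.8, "short": 0.4, "tapping": 0.6}

#: Trigger-amplitude event codes (label -> pulse amplitude).  Any injective
#: map works; ``base_short`` is the code used for plain base beats in the
#: short and tapping conditions so every (condition, label) pair is
#: distinguishable from the trigger channel alone.
DEFAULT_CODE_MAP = {
    "base": 0.2,
    "base_short": 0.4,
    "deviant": 0.6,
    "standard_key": 0.8,
}

EVENT_COLUMNS = ["onset", "label", "condition", "trial_index"]


class InvalidSpecError(ValueError):
    """A paradigm specification violates its invariants."""


class IntegrityError(ValueError):
    """An event table violates a structural invariant (e.g. onset order)."""


class RenderError(ValueError):
    """Audio/trigger rendering is impossible for the given events."""


@dataclass(frozen=True)
class StimulusParams:
    """Tone-burst parameters: an 800-Hz sine pulse, 50 ms long, with 10-ms
    raised-cosine ramps at onset and offset."""

    carrier_freq: float = 800.0  # Hz
    burst_duration: float = 0.050  # s
    ramp: float = 0.010  # s, raised-cosine up and down
    level: float = 0.5  # linear amplitude in [0, 1]
    audio_rate: float = 44100.0  # Hz

    def __post_init__(self) -> None:
        if 2 * self.ramp > self.burst_duration:
            raise InvalidSpecError("ramps longer than the burst")
        if self.carrier_freq >= self.audio_rate / 2:
            raise InvalidSpecError("carrier above Nyquist")
        if not 0 <= self.level <= 1:
            raise InvalidSpecError("level outside [0, 1]")


@dataclass(frozen=True)
class TrialSpec:
    """One passive-listening (or tapping) trial."""

    condition: str  # {"long", "short", "tapping"}
    duration: float  # s
    ioi: float | None = None  # s; default from condition
    anomaly_prob: float = 0.15  # deviant-insertion / omission probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_IOI:
            raise InvalidSpecError(f"unknown condition {self.condition!r}")
        if self.duration <= 0:
            raise InvalidSpecError("duration must be positive")
        if not 0 <= self.anomaly_prob <= 1:
            raise InvalidSpecError("anomaly_prob must be in [0, 1]")
        if self.ioi is None:
            object.__setattr__(self, "ioi", CONDITION_IOI[self.condition])
        if self.ioi <= 0:
            raise InvalidSpecError("ioi must be positive")
        if self.duration < self.ioi:
            raise InvalidSpecError("duration shorter than one IOI")


@dataclass
class SessionPlan:
    """An ordered list of trials with their session-time offsets."""

    trials: list[TrialSpec]
    events: list[pd.DataFrame]  # trial-relative onsets
    trial_starts: np.ndarray  # s, session time
    total_duration: float  # s
    master_seed: int
    intertrial_gap_s: float = 0.0

    def session_events(self) -> pd.DataFrame:
        """All trials concatenated, onsets shifted to session time."""
        frames = []
        for start, ev in zip(self.trial_starts, self.events):
            shifted = ev.copy()
            shifted["onset"] = shifted["onset"] + start
            frames.append(shifted)
        out = pd.concat(frames, ignore_index=True)
        if not np.all(np.diff(out["onset"].to_numpy()) > 0):
            raise IntegrityError("session onsets not strictly increasing")
        return out


def _n_slots(duration: float, ioi: float) -> int:
    # floor(duration / ioi) slots at 0, ioi, ..., (n-1)*ioi; a tiny epsilon
    # guards against 112.5/0.4 style float-quotient undershoot.
    return int(math.floor(duration / ioi + 1e-9))


def generate_trial(spec: TrialSpec) -> pd.DataFrame:
    """Generate the event timeline of one trial.

    Long condition: base beats on the exact IOI grid, with deviants
    inserted halfway into base-beat gaps at an overall rate of
    ``anomaly_prob`` per gap.  A deviant only has the (IOI, IOI/2)
    preceding audible-interval context the paradigm requires when the
    previous gap is empty, so two deviants never occupy adjacent gaps (nor
    the first gap): insertion runs sequentially with compensated
    probability ``p/(1-p)`` (capped at 1) whenever the previous gap is
    empty, which keeps the marginal insertion rate at exactly ``p`` while
    guaranteeing every deviant the 800-then-400-ms context.
    Short/tapping: beats on the exact grid, each independently replaced by
    an ``omitted`` (silent) row with probability ``anomaly_prob``.
    """
    rng = np.random.default_rng(spec.seed)
    n = _n_slots(spec.duration, spec.ioi)
    grid = np.arange(n) * spec.ioi

    if spec.condition == "long":
        onsets = list(grid)
        labels = ["base"] * n
        p = spec.anomaly_prob
        p_seq = min(p / (1.0 - p), 1.0) if p < 1.0 else 1.0
        prev_filled = False  # refers to gap 0, which is always empty
        for k in range(1, n - 1):  # gap k lies between base beats k and k+1
            if not prev_filled and rng.random() < p_seq:
                onsets.append(grid[k] + spec.ioi / 2)
                labels.append("deviant")
                prev_filled = True
            else:
                prev_filled = False
        order = np.argsort(onsets, kind="stable")
        onsets = np.asarray(onsets)[order]
        labels = np.asarray(labels, dtype=object)[order]
    else:
        omitted = rng.random(n) < spec.anomaly_prob
        onsets = grid
        labels = np.where(omitted, "omitted", "base").astype(object)

    return pd.DataFrame(
        {
            "onset": np.asarray(onsets, dtype=float),
            "label": labels,
            "condition": spec.condition,
            "trial_index": 0,
        }
    )


def label_key_events(table: pd.DataFrame, *, tol: float = 1e-6) -> pd.DataFrame:
    """Mark the adaptation-matched key events of a trial.

    In long trials every deviant is already a key event (its preceding
    audible IOIs are 800 then 400 ms by construction).  In short trials a
    base beat is relabelled ``standard_key`` iff its two preceding *audible*
    inter-onset intervals are exactly (2*IOI, IOI) — it closes a
    single-omission gap.  The first two audible beats of a trial are never
    key events.
    """
    onsets = table["onset"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        raise IntegrityError("onsets not strictly increasing")
    out = table.copy()
    condition = table["condition"].iloc[0] if len(table) else None
    if condition != "short":
        return out

    ioi = CONDITION_IOI["short"]
    audible = np.flatnonzero(table["label"].to_numpy() != "omitted")
    t = onsets[audible]
    labels = out["label"].to_numpy(dtype=object)
    for j in range(2, len(t)):
        prev1 = t[j] - t[j - 1]
        prev2 = t[j - 1] - t[j - 2]
        if abs(prev1 - ioi) < tol and abs(prev2 - 2 * ioi) < tol:
            labels[audible[j]] = "standard_key"
    out["label"] = labels
    return out


def build_session(
    n_pairs: int = 8,
    total_min: float = 30.0,
    p: float = 0.15,
    seed: int = 0,
    *,
    intertrial_gap_s: float = 0.0,
) -> SessionPlan:
    """Build the passive-listening session: ``2*n_pairs`` equal-duration
    trials alternating long/short (long first), totalling ``total_min``
    minutes of stimulation, with key events labelled.

    Each trial draws from an independent child seed derived from ``seed``,
    so the plan is reproducible and trials are statistically independent.
    """
    if n_pairs < 1:
        raise InvalidSpecError("need at least one long/short pair")
    n_trials = 2 * n_pairs
    trial_dur = total_min * 60.0 / n_trials
    if trial_dur < max(CONDITION_IOI["long"], CONDITION_IOI["short"]):
        raise InvalidSpecError("total_min too small to fit one IOI per trial")

    children = np.random.SeedSequence(seed).spawn(n_trials)
    trials: list[TrialSpec] = []
    events: list[pd.DataFrame] = []
    starts = np.zeros(n_trials)
    t0 = 0.0
    for i in range(n_trials):
        cond = "long" if i % 2 == 0 else "short"
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        spec = TrialSpec(condition=cond, duration=trial_dur, anomaly_prob=p, seed=child_seed)
        ev = label_key_events(generate_trial(spec))
        ev["trial_index"] = i
        trials.append(spec)
        events.append(ev)
        starts[i] = t0
        t0 += trial_dur + intertrial_gap_s
    total = n_trials * trial_dur + (n_trials - 1) * intertrial_gap_s
    return SessionPlan(
        trials=trials,
        events=events,
        trial_starts=starts,
        total_duration=total,
        master_seed=seed,
        intertrial_gap_s=intertrial_gap_s,
    )


def tone_burst(stim: StimulusParams, rate: float | None = None) -> np.ndarray:
    """One ramped sine burst sampled at ``rate`` (default the audio rate)."""
    rate = stim.audio_rate if rate is None else rate
    n = int(round(stim.burst_duration * rate))
    t = np.arange(n) / rate
    burst = stim.level * np.sin(2 * np.pi * stim.carrier_freq * t)
    n_ramp = int(round(stim.ramp * rate))
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        burst[:n_ramp] *= ramp
        burst[-n_ramp:] *= ramp[::-1]
    return burst


def _effective_code_label(label: str, condition: str, code_map: dict) -> str:
    if label == "base" and condition in ("short", "tapping") and "base_short" in code_map:
        return "base_short"
    return label


def render_tracks(
    plan_or_events: SessionPlan | pd.DataFrame,
    stim: StimulusParams | None = None,
    code_map: dict | None = None,
    *,
    rate: float | None = None,
    trigger_pulse_s: float = 0.010,
    total_duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (audio, trigger) tracks for a session or single event table.

    The audio track holds one ramped sine burst per audible beat, onset
    sample-aligned with the event onset; the trigger track holds one
    rectangular pulse per audible beat whose amplitude encodes the label
    and whose rising edge shares the burst's onset sample.  Omitted slots
    render nothing on either track.
    """
    stim = stim or StimulusParams()
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    if min(code_map.values()) <= 0 or len(set(code_map.values())) != len(code_map):
        raise InvalidSpecError("trigger codes must be distinct positive amplitudes")
    rate = stim.audio_rate if rate is None else rate

    if isinstance(plan_or_events, SessionPlan):
        events = plan_or_events.session_events()
        duration = plan_or_events.total_duration
    else:
        events = plan_or_events
        duration = float(events["onset"].max()) + stim.burst_duration if len(events) else 1.0
    if total_duration is not None:
        duration = total_duration

    audible = events[events["label"] != "omitted"]
    gaps = np.diff(audible["onset"].to_numpy())
    if len(gaps) and gaps.min() < stim.burst_duration - 1e-12:
        raise RenderError("overlapping bursts: an IOI is shorter than the burst")

    n_samples = int(round(duration * rate))
    audio = np.zeros(n_samples)
    trigger = np.zeros(n_samples)
    burst = tone_burst(stim, rate)
    n_pulse = max(int(round(trigger_pulse_s * rate)), 1)
    for onset, label, condition in zip(
        audible["onset"], audible["label"], audible["condition"]
    ):
        key = _effective_code_label(label, condition, code_map)
        if key not in code_map:
            raise InvalidSpecError(f"no trigger code for label {label!r}")
        i0 = int(round(onset * rate))
        end = min(i0 + len(burst), n_samples)
        audio[i0:end] += burst[: end - i0]
        trigger[i0 : min(i0 + n_pulse, n_samples)] = code_map[key]
    return audio, trigger
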