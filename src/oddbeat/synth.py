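"""Synthetic subjects: EEG with expectancy-modulated N1-P2 responses, and
tapping with von Mises phase jitter.

The generative model per subject:

* Every audible beat evokes an N1-P2 kernel at Cz — a negative Gaussian
  bump (N1) followed by a positive one (P2).  Deviant beats evoke the same
  kernel with amplitudes scaled by ``(1 + g)`` and latencies shifted later
  by ``deviant_lat_shift`` — ``g`` is the subject's *expectancy gain*, the
  quantity the timing response index should recover.
* Background noise is a 1/f + white mixture (default 80/20 power split)
  with a subject-specific total SD in microvolts.
* Taps fall at nominal 600-ms grid times plus ``(ioi/2pi) * theta`` with
  ``theta ~ von Mises(0, kappa)``; ``kappa`` is the subject's tapping
  concentration, which vector strength should recover (VS -> I1(k)/I0(k)).

A population couples ``g`` and ``kappa`` through a Gaussian copula with a
target Spearman correlation, so the whole pipeline can be validated by
recovering that correlation from simulated recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss

from .paradigm import (
    DEFAULT_CODE_MAP,
    InvalidSpecError,
    SessionPlan,
    StimulusParams,
    render_tracks,
)
from .erp import ContinuousRecording
from .tapping import TapSeries

__all__ = [
    "SubjectParams",
    "PopulationSpec",
    "sample_population",
    "evoked_kernel",
    "kernel_extrema",
    "simulate_recording",
    "simulate_taps",
    "one_over_f_noise",
]

KERNEL_DURATION = 0.500  # s


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one synthetic subject."""

    gain: float = 1.0  # expectancy gain g >= 0
    kappa: float = 4.0  # von Mises concentration of tap phases
    noise_sd: float = 15.0  # uV, total background-noise SD
    n1_amp: float = -2.0  # uV, negative
    p2_amp: float = 3.0  # uV, positive
    n1_lat: float = 0.122  # s, bump centre
    p2_lat: float = 0.174  # s
    deviant_lat_shift: float = 0.020  # s, deviant bumps later by this much
    bump_sd: float = 0.025  # s, Gaussian bump width

    def __post_init__(self) -> None:
        if self.gain < 0 or self.kappa < 0 or self.noise_sd < 0:
            raise InvalidSpecError("gain, kappa and noise_sd must be >= 0")
        if not self.n1_amp < 0 < self.p2_amp:
            raise InvalidSpecError("need n1_amp < 0 < p2_amp")
        for lat in (self.n1_lat, self.p2_lat):
            if not 0 < lat < 0.300:
                raise InvalidSpecError("latencies must lie in (0, 300) ms")


@dataclass(frozen=True)
class PopulationSpec:
    """A synthetic cohort with a target g-kappa rank correlation."""

    n_subjects: int = 34
    rho_pop: float = 0.6  # target Spearman between gain and kappa
    gain_range: tuple = (0.0, 3.0)
    kappa_range: tuple = (1.0, 20.0)
    noise_sd_range: tuple = (12.0, 18.0)
    n1_amp_range: tuple = (-3.0, -1.0)
    p2_amp_range: tuple = (2.0, 4.0)
    lat_jitter: float = 0.010  # s, uniform jitter on both bump centres
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise InvalidSpecError("need at least 3 subjects")
        if not -1.0 <= self.rho_pop <= 1.0:
            raise InvalidSpecError("rho_pop must lie in [-1, 1]")


def sample_population(spec: PopulationSpec) -> list[SubjectParams]:
    """Draw a cohort whose (gain, kappa) Spearman correlation targets
    ``rho_pop`` via a Gaussian copula.

    The latent bivariate-normal correlation is ``2 sin(pi * rho / 6)``, the
    exact inverse of the Spearman correlation of a Gaussian pair, so the
    *population* rank correlation equals ``rho_pop``; uniforms from the
    copula are mapped linearly onto the stated marginal ranges.  Nuisance
    parameters (noise SD, component amplitudes, latency jitter) are drawn
    independently.
    """
    rng = np.random.default_rng(spec.master_seed)
    r = 2.0 * np.sin(np.pi * spec.rho_pop / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n_subjects)
    u = ss.norm.cdf(z)

    def span(lo_hi, q):
        lo, hi = lo_hi
        return lo + (hi - lo) * q

    subjects = []
    for i in range(spec.n_subjects):
        jit = rng.uniform(-spec.lat_jitter, spec.lat_jitter)
        subjects.append(
            SubjectParams(
                gain=span(spec.gain_range, u[i, 0]),
                kappa=span(spec.kappa_range, u[i, 1]),
                noise_sd=rng.uniform(*spec.noise_sd_range),
                n1_amp=rng.uniform(*spec.n1_amp_range),
                p2_amp=rng.uniform(*spec.p2_amp_range),
                n1_lat=0.122 + jit,
                p2_lat=0.174 + jit,
            )
        )
    return subjects


def evoked_kernel(params: SubjectParams, is_deviant: bool, rate: float = 500.0) -> np.ndarray:
    """The N1-P2 response kernel, 500 ms long, sampled at ``rate``.

    Two Gaussian bumps: ``n1_amp`` at ``n1_lat`` and ``p2_amp`` at
    ``p2_lat``.  For deviants the amplitudes scale by ``(1 + gain)`` and
    both latencies shift by ``deviant_lat_shift``.
    """
    t = np.arange(int(round(KERNEL_DURATION * rate))) / rate
    scale = 1.0 + params.gain if is_deviant else 1.0
    shift = params.deviant_lat_shift if is_deviant else 0.0
    sd = params.bump_sd
    return scale * (
        params.n1_amp * np.exp(-((t - params.n1_lat - shift) ** 2) / (2 * sd**2))
        + params.p2_amp * np.exp(-((t - params.p2_lat - shift) ** 2) / (2 * sd**2))
    )


def kernel_extrema(params: SubjectParams, is_deviant: bool) -> tuple[float, float]:
    """Latencies (s) of the composite kernel's N1 minimum and P2 maximum.

    With overlapping bumps the emergent component latencies differ from the
    bump centres; these are the ground-truth values a latency-recovery
    check should compare against.  Computed on a 0.1-ms grid.
    """
    rate = 10000.0
    k = evoked_kernel(params, is_deviant, rate=rate)
    t = np.arange(len(k)) / rate
    return float(t[int(np.argmin(k))]), float(t[int(np.argmax(k))])


def one_over_f_noise(
    n: int, rate: float, sd: float, rng: np.random.Generator, pink_fraction: float = 0.8
) -> np.ndarray:
    """Background noise: 1/f-power ("pink") + white mixture, total SD ``sd``.

    ``pink_fraction`` is the share of the variance carried by the 1/f
    component (default 80/20 split).
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])  # amplitude ~ f^-1/2 => power ~ 1/f
    pink = np.fft.irfft(spec * shape, n)
    pink /= pink.std()
    white /= white.std()
    mix = np.sqrt(pink_fraction) * pink + np.sqrt(1 - pink_fraction) * white
    return sd * mix / mix.std()


def simulate_recording(
    plan: SessionPlan,
    params: SubjectParams,
    rate: float = 4000.0,
    seed: int = 0,
    *,
    code_map: dict | None = None,
    stim: StimulusParams | None = None,
) -> ContinuousRecording:
    """Simulate the Cz + trigger recording of one passive-listening session.

    Cz = background noise + the subject's standard kernel at every audible
    non-deviant beat and deviant kernel at every deviant; the trigger
    channel carries the amplitude-coded event pulses.  Rates down to
    500 Hz are supported (trigger-onset precision 2 ms); lower rates are
    refused.
    """
    if rate < 500:
        raise InvalidSpecError("rate below 500 Hz loses trigger-onset precision")
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    stim = stim or StimulusParams()
    rng = np.random.default_rng(seed)

    events = plan.session_events()
    n = int(round(plan.total_duration * rate))
    cz = one_over_f_noise(n, rate, params.noise_sd, rng)

    k_std = evoked_kernel(params, is_deviant=False, rate=rate)
    k_dev = evoked_kernel(params, is_deviant=True, rate=rate)
    audible = events[events["label"] != "omitted"]
    for onset, label in zip(audible["onset"], audible["label"]):
        k = k_dev if label == "deviant" else k_std
        i0 = int(round(onset * rate))
        end = min(i0 + len(k), n)
        if i0 < n:
            cz[i0:end] += k[: end - i0]

    _, trigger = render_tracks(plan, stim=stim, code_map=code_map, rate=rate)
    trigger = trigger[:n] if len(trigger) >= n else np.pad(trigger, (0, n - len(trigger)))
    return ContinuousRecording(np.vstack([cz, trigger]), rate, ["Cz", "TRIG"])


def simulate_taps(
    grid: pd.DataFrame,
    params: SubjectParams,
    seed: int = 0,
    *,
    miss_prob: float = 0.0,
) -> TapSeries:
    """Simulate tapping against a 600-ms grid.

    One tap per nominal slot — including omitted-beat slots, since the task
    instructs tapping through omissions — at slot time plus
    ``(ioi / 2 pi) * theta`` with ``theta ~ von Mises(0, kappa)``.  Taps can
    be dropped independently with ``miss_prob``.
    """
    if params.kappa < 0:
        raise InvalidSpecError("kappa must be >= 0")
    if not 0 <= miss_prob < 1:
        raise InvalidSpecError("miss_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    slots = grid["onset"].to_numpy(dtype=float)
    if len(slots) > 1:
        ioi = float(np.median(np.diff(slots)))
    else:
        ioi = 0.6
    theta = rng.vonmises(0.0, params.kappa, size=len(slots)) if params.kappa > 0 else rng.uniform(-np.pi, np.pi, len(slots))
    taps = slots + (ioi / (2 * np.pi)) * theta
    if miss_prob > 0:
        taps = taps[rng.random(len(taps)) >= miss_prob]
    taps = np.unique(np.sort(taps))
    return TapSeries(taps, source="simulated")
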