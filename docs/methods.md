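# Methods

## The paradigm and why it is shaped this way

The passive-listening session interleaves two conditions, 8 trials each,
alternating long/short and starting with long; trials are equal length
(112.5 s for a 30-minute session of 16 trials). The point of the design is
*adaptation control*: auditory evoked responses shrink when a sound follows
a short inter-onset interval (IOI), so comparing responses to rare versus
common beats is only meaningful if both are preceded by the same local
stimulus history. Here both key-event types — the long condition's inserted
extra beat ("deviant") and the short condition's gap-closing beat
("standard") — are preceded by audible IOIs of exactly 800 then 400 ms, and
differ only in how predictable they are from the global context.

**Deviant insertion.** A deviant only has the 800-then-400-ms context when
the previous 800-ms gap contains no deviant; deviants in adjacent gaps (or
in a trial's first gap) would break it. Insertion therefore runs
sequentially over gaps with compensated probability `p/(1−p)` whenever the
previous gap is empty (first gap always skipped, capped at 1 for p ≥ 0.5).
The stationary marginal insertion rate is then exactly `p` (= 0.15 by
default), while the context holds for every deviant by construction. A
30-minute session has 8 × 138 eligible gaps, giving ≈ 166 deviants on
average. At `p = 1` the rule degenerates to filling alternating gaps — the
densest packing compatible with the context requirement.

**Standard selection.** A short-condition beat is a standard iff its two
preceding *audible* IOIs are exactly (800 ms, 400 ms), i.e. it follows the
beat that closed a single-omission gap; the first two audible beats of a
trial are never key events. Under independent 15% omissions the expected
rate is `p(1−p)³ ≈ 0.092` per interior slot, ≈ 205 standards per session.
Other selection rules (e.g. excluding slots near trial boundaries) would
give somewhat different counts; this rule is the package's own choice and
is asserted property-by-property in the tests, not claimed to match any
particular prior dataset's bookkeeping.

**Rendering.** Beats are 800-Hz sine bursts, 50 ms long with 10-ms
raised-cosine on/off ramps, placed on the audio track at the nearest
sample. Triggers are 10-ms rectangular pulses whose amplitude encodes the
label (defaults: long base 0.2, short/tapping base 0.4, deviant 0.6,
standard 0.8); any injective positive map is accepted. Inter-trial silence
defaults to 0 s (so 16 × 112.5 s = 30 min exactly) and is configurable.

## Tapping

Tap phases are computed against the *nominal* isochronous grid —
`φ = wrap(2π · frac((t − t₀)/IOI))` into [−π, π) — including omitted-beat
slots, because the task instructs tapping through omissions. Taps before
the first grid line are dropped (no phase context). Vector strength is the
mean resultant length of the unit phasors; circular SD is `√(−2 ln VS)`
(infinite at VS = 0). VS is rotation-invariant, so a constant playback
latency does not affect it; no latency correction is applied by default.
Onset detection from piezo-like waveforms uses an upward
threshold-crossing (default 0.3 × max |signal|) with a 200-ms refractory
period to absorb ringing.

## EEG pipeline numerics

* **Resampling**: polyphase (`scipy.signal.resample_poly`) from the native
  rate to 500 Hz, anti-alias filtering included. Event markers are
  re-indexed by round-half-up.
* **Low-pass filter**: Hamming windowed-sinc FIR, passband edge 30 Hz,
  transition 30→40 Hz, order from the standard Hamming rule
  (3.3 / normalized transition width), forced odd (165 taps at 500 Hz) so
  the symmetric kernel can be applied with zero net group delay
  (centered convolution). Contract, asserted in tests: DC gain 1 ± 1e-3,
  ≥ 20 dB attenuation at 50 Hz, linear phase, impulse peak preserved to
  ±1 sample across the resample+filter chain. The trigger channel is
  carried by sample-picking, never filtered.
* **Epochs**: [−50, +450) ms around each key event at 500 Hz (250
  samples); the extent contains the deviant P2 window with margin. Each
  epoch is baseline-corrected by its own [−50, 0) ms mean. Epochs
  exceeding the recording bounds are dropped and counted.
* **Rejection**: an epoch survives iff every sample satisfies
  |v| ≤ 100 μV; a subject with fewer than 80 surviving epochs is flagged
  excluded and skipped by the study statistics.
* **Component windows**: per condition, N1 = voltage minimum of the grand
  average inside [50, 200] ms, P2 = maximum after the found N1 and ≤ 320
  ms; ties break to the earliest latency. Windows are the latency
  ± halfwidth (50/30/20 ms variants), clipped to the epoch.
* **TRI variants**: mean amplitude over those windows (`mean50`,
  `mean30`, `mean20`); `peak` takes each subject's own extreme voltages
  inside the 50-ms-halfwidth windows; `peak_mean20` averages ±10 ms
  around those per-subject peaks. In every variant the N1-P2 magnitude is
  `P2 − N1` per condition and TRI is deviant minus standard.

## Synthetic subjects

Each audible beat evokes a kernel of two Gaussian bumps (SD 25 ms):
`n1_amp` (default −2 μV) at `n1_lat` (122 ms) and `p2_amp` (+3 μV) at
`p2_lat` (174 ms). Deviant beats evoke the same kernel with amplitudes
scaled by (1 + g) and latencies shifted +20 ms — mirroring the later
deviant component windows the pipeline should discover. Because the bumps
overlap, the *composite* kernel's extrema sit at ≈ 116/177 ms rather than
the bump centres; `kernel_extrema()` reports these ground-truth component
latencies, and latency-recovery checks compare against them. Background
noise is a 1/f-power + white mixture (80/20 variance split — EEG spectra
are low-frequency dominated, but no further structure is claimed) with
total SD per subject (default 15 μV, a realistic broadband single-trial
amplitude at a dry Cz electrode). Gain-only modulation is a modelling
choice: the generator does not decompose the deviant effect into separate
amplitude and latency effects per component.

Tapping: one tap per nominal 600-ms slot at
`slot + (IOI/2π)·θ, θ ~ von Mises(0, κ)`, optional independent misses.
The long-run VS of such a tapper is the Bessel ratio `I1(κ)/I0(κ)`, which
the tests use as a closed-form oracle.

Populations couple g and κ through a Gaussian copula whose latent
correlation `2 sin(πρ/6)` exactly inverts the Spearman correlation of a
bivariate Gaussian, so the population rank correlation equals the target
ρ. Marginals are uniform over configurable ranges (g ∈ [0, 3];
κ ∈ [1, 20], which spans VS ≈ 0.45–0.97 and produces the left-skewed VS
distributions typical of adult tappers). Nuisance parameters (noise SD
12–18 μV, component amplitudes, ±10 ms latency jitter) vary independently
across subjects.

**What the generator does not emulate**: multi-channel topography, ocular
or movement artifacts beyond amplitude outliers, drifting tempo or
phase-correction dynamics in tapping, session-level non-stationarity, and
any decomposition of expectancy effects beyond the single gain parameter.
Passing tests therefore demonstrate that the *pipeline* is correct and
sensitive under these conditions, not that real recordings will behave
this benignly.

## Validation strategy and problem sizes

Oracle-style tests pin every arithmetic step (hand-computed vector
strengths, exhaustive-permutation Spearman p-values at n ≤ 10,
brute-force window means, render→decode round trips). Closed-form tests
check sampling limits at 3-standard-error tolerances (von Mises VS at
N = 50 000; Lilliefors type-I error over 500 replicates with a shared
10 000-draw null). The end-to-end property is parameter recovery: 25
cohorts of 34 subjects at population ρ = 0.6, full 30-minute sessions
synthesized at 500 Hz, must place the recovered Spearman(TRI, VS) inside
the n = 34 sampling interval [0.30, 0.80] in at least 80% of cohorts.
The 500-Hz synthesis rate is the analysis rate — simulating at 4 kHz and
decimating changes nothing the pipeline sees except trigger-onset
precision (2 ms at 500 Hz, well under the 100-ms component scale), and
recordings below 500 Hz are refused.

Statistics: Spearman uses average ranks and an exact permutation p below
n = 11, the t approximation (df = n − 2) above. The partial Spearman
rank-residualizes both variables on the covariate's ranks; a variable
fully explained by the covariate has partial correlation 0 by convention
(its residuals are numerical dust), and a constant covariate falls back
to the plain correlation with a warning. Lilliefors p-values come from a
seeded Monte-Carlo null rather than table interpolation, for exact
reproducibility. The TRI–VS correlation is reported two-tailed by
default with a one-tailed option (the hypothesis is directional); no
multiple-testing correction is applied across the window variants, which
are robustness checks reported side by side.

## Known limitations

* EDF files are read (via mne) but not written; recordings are exchanged
  as annotated TSV.
* The trigger decoder assumes well-separated code amplitudes (tolerance:
  half the smallest gap between codes); heavily noise-contaminated
  trigger channels need recoding, not decoding.
* Exact-permutation Spearman enumerates n! permutations and is capped at
  n = 10.
* `find_component_windows` assumes a single dominant N1/P2 pair inside
  the search ranges; multi-peaked grand averages resolve by the
  earliest-extremum tie rule rather than by morphology.
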