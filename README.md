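# oddbeat

Tools for studying the link between **sensorimotor synchronization** and the
brain's response to **violated temporal expectancy**, built around three
pieces:

1. **Paradigm generation** — an adaptation-controlled temporal auditory
   oddball session: a *long* condition (800-ms inter-onset interval, IOI)
   with rare extra beats inserted halfway between beats ("deviants", 15% of
   gaps), alternating with a *short* condition (400-ms IOI) with rare
   omissions (15%). A short-condition beat that closes a single-omission gap
   is an adaptation-matched "standard": both key-event types are preceded by
   audible IOIs of exactly 800 then 400 ms and differ only in expectancy.
   Audio (ramped 800-Hz tone bursts) and amplitude-coded square-wave trigger
   tracks are rendered sample-aligned.

2. **Analysis** — a tapping scorer and an N1-P2 evoked-potential pipeline.
   Tapping against a 600-ms beat grid is scored with **vector strength**

   ```
   VS = (1/N) | Σ_j exp(i φ_j) |,     φ_j = tap phase relative to the grid
   ```

   (1 = perfectly phase-consistent, ≈0 = random) and circular SD
   `√(−2 ln VS)`. EEG at Cz is downsampled to 500 Hz, low-passed at 30 Hz
   (Hamming windowed-sinc FIR, zero net delay), epoched around deviants and
   standards with a 50-ms pre-stimulus baseline, cleaned by a ±100 μV
   rejection rule, and averaged. N1/P2 component windows (±50 ms around the
   grand-average peaks, per condition) yield each subject's N1-P2 magnitude
   `P2_mean − N1_mean` per condition, and the **timing response index**

   ```
   TRI = (deviant N1-P2 magnitude) − (standard N1-P2 magnitude)   [μV]
   ```

   The study statistic is Spearman's ρ between TRI and VS, plus one-tailed
   t contrasts and normality diagnostics.

3. **Synthetic data** — subjects with a known *expectancy gain* g (deviant
   responses scaled by 1+g), von Mises tap jitter of concentration κ, and
   1/f + white EEG noise, with g and κ coupled by a Gaussian copula at a
   chosen population rank correlation. Every stage of the pipeline is
   validated by recovering the generating parameters.

## Worked example

Simulate a subject with expectancy gain 1.2 and realistic noise, run the
full pipeline, and read off their TRI (`examples/02_simulate_subject.py`):

```
kept epochs: {'deviant': 181, 'standard_key': 224}
N1/P2 windows (standard): [70, 170] / [140, 240] ms
deviant N1-P2 magnitude:  3.66 uV
standard N1-P2 magnitude: 1.86 uV
TRI: 1.80 uV -> gain estimate 0.97 (true gain 1.2)
```

The deviant N1-P2 is roughly (1+g) times the standard one, so TRI divided
by the standard magnitude estimates g; with zero noise the identity is
exact, with noise it is unbiased but jittered. A cohort-level run
(`examples/04_run_study.py`, 12 subjects at population ρ = 0.6) prints the
study table and

```
Spearman(TRI, VS): rho=0.364, p=0.2453 (n=12)
deviant > standard N1-P2: t=6.12, df=11, p=3.8e-05
```

— the deviant-vs-standard contrast is strong in every cohort, while the
brain–behavior correlation estimate is noisy at small n and stabilizes
around its population value for realistic cohort sizes (see
`tests/test_acceptance.py`).

The other examples build the paradigm session (`01_build_paradigm.py`) and
score tapping against the Bessel-ratio limit `I1(κ)/I0(κ)`
(`03_score_tapping.py`).

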