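# antiphase

Analysis pipeline for **temporal jamming avoidance** in vocalizing animals:
do callers shift their call onsets into the quiet troughs of
amplitude-modulated (AM) background noise?  The package was built around the
behaviour of echolocating bats (*Carollia perspicillata*-type groups emitting
brief 1–2 ms downward FM sweeps), but every stage operates on generic WAV
audio and call-event tables.

It provides, as importable modules and a CLI:

- **`stimgen`** — band-limited white-noise maskers (e.g. 10–96 kHz
  "broadband", 50–96 kHz "high-frequency") amplitude modulated at 4–80 Hz,
  either steady-state or as a randomly permuted stream of single AM cycles,
  with the realized cycle sequence logged for analysis.
- **`simulate`** — ground-truth synthetic data: phase-locked call trains
  (inhomogeneous Poisson by thinning), call audio rendered into the masker
  at a chosen SNR, and negative binomial count tables.
- **`detect`** — a threshold energy detector for brief ultrasonic calls
  (1 ms minimum duration, 0.9 ms merge gap), detection scoring at 1.5 ms
  onset tolerance, and call-overlap counting.
- **`phase`** — recovery of the AM envelope from recorded audio (Hilbert
  magnitude, zero-phase filtering), trough detection, a trough-anchored
  instantaneous-phase model (phase 0 = trough, π = peak), and phase tagging
  of call onsets; includes the silent-baseline cosine model and
  cross-correlation alignment of random-cycle stimuli.
- **`circstats`** — resultant vectors (ᾱ, R, r̄ = R/n, dispersion n − R),
  Rayleigh uniformity test, von Mises MLE (μ, κ) with a 1000-resample
  bootstrap, Mardia–Watson–Wheeler and Rao homogeneity tests, Bonferroni
  adjustment, circular/linear phase histograms.
- **`ratemodels`** — NB-2 regression of per-block call counts on playback
  condition, ln E[nᵢ] = Intercept + β₁I(cond = 2) + β₂I(cond = 3),
  likelihood-ratio ANOVA, incidence-rate ratios, marginal-mean contrasts.
- **`classify`** — conversion of bootstrapped circular means μ into
  within-cycle timing measures (t_from_peak = μT/2π − T/2,
  t_to_trough = T − μT/2π, T = 1/f), and linear discriminant classification
  of modulation rate from either measure to adjudicate whether call timing
  is anchored to amplitude **peaks** or to **terminal troughs**.

## Worked example

```python
import numpy as np
from antiphase import stimgen, simulate, detect, phase, circstats

# 60 s broadband masker, 8 Hz AM
spec = stimgen.MaskerSpec(carrier_band=(10, 96), sample_rate=192_000,
                          duration=60.0, am_schedule=8.0, rng_seed=101)
masker, cycles = spec.render()

# phase-locked call train (preferred phase 3π/2 = falling edge, κ = 2)
behav = simulate.BehaviorModel(baseline_rate=110.0,
                               phase_preference_mu=3 * np.pi / 2,
                               phase_preference_kappa=2.0, rng_seed=102)
truth = phase.phase_model_from_cycles(cycles)
events = simulate.simulate_call_train(behav, truth, 60.0, refractory_s=0.0)
audio = simulate.synth_call_audio(events, masker, snr_db=20)

# measure: detect calls, recover the envelope, tag onsets with phase
detected = detect.detect_calls(audio)
env = phase.extract_envelope_steady(audio, 8.0)
model = phase.phase_model_from_envelope(env, [8.0])
tagged = phase.tag_call_onsets(detected, model)
phases = tagged.loc[tagged["tagged"], "onset_phase_rad"].to_numpy()

fit = circstats.vm_mle(phases)
ray = circstats.rayleigh_test(phases)
print(f"n={len(phases)}  mu={fit.mu:.3f}  kappa={fit.kappa:.2f}  "
      f"rayleigh p={ray.p_value:.3g}")
```

Output:

```
n=1479  mu=4.713  kappa=1.79  rayleigh p=2.5e-319
```

The recovered mean phase 4.713 rad matches the generative preference
3π/2 ≈ 4.712 (the falling edge of the AM cycle, just before the terminal
trough), and the Rayleigh test decisively rejects uniformity — the
measurement chain recovers the simulated anti-phase calling pattern.
The concentration estimate (1.79 vs the generative 2.0) is slightly
flattened by detection timing jitter and the merging of near-simultaneous
calls, which is why κ recovery is separately validated at the MLE level.

The same end-to-end run is available from the shell:

```bash
antiphase run-all --out demo_run --seed 5
```

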