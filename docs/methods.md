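# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `antiphase` package.

## Phase convention

All phases are radians in [0, 2π), anchored at the amplitude **trough**:
phase 0 (= 2π) is the cycle boundary (envelope minimum), π is the amplitude
peak at mid-cycle.  Times are seconds (float64), rates Hz, event intervals
half-open [onset, offset), sample indexing 0-based.  Under this convention a
preference for calling on the falling edge just before the terminal trough
appears as a circular mean near 3π/2.

## Stimulus synthesis (`stimgen`)

Maskers are Gaussian white noise band-limited by FFT-domain masking —
exact band edges, no filter transition bands, and bit-identical output for a
fixed seed.  The AM envelope is a raised cosine

    e(t) = d·(1 − cos 2πf(t − t₀))/2 + (1 − d)

per cycle of rate f starting at t₀, with depth d (default 1.0, i.e. the
envelope reaches zero at each trough).  The raised cosine was chosen because
it places troughs exactly at cycle boundaries, matching the trough-as-cycle-
start convention of the phase model; the true analogue stimuli are only ever
shown schematically, so the exact envelope shape is a package design choice.
Generated stimuli are spectrally flat: speaker calibration / dB roll-off
compensation is out of scope, and playback level exists only as a
normalized amplitude.

The random-cycle masker allots equal playback time to each modulation rate
inside every (default 15 min) block, converts that time to whole single
cycles, pools and shuffles them.  Long-run occupancy time is therefore
uniform across rates (required for fair per-rate rate comparisons), while
the local cycle order is unpredictable.  The steady-state program plays one
block per rate (default 8 rates × 7.5 min = 60 min) in seeded random order.

## Synthetic behaviour (`simulate`)

Call trains are an inhomogeneous Poisson process sampled by thinning, with
intensity

    λ(t) = r₀ · s · exp(κ·(cos(φ(t) − μ) − 1)),

the von Mises density normalized by its maximum, so the peak rate r₀
(calls/s), the masking suppression factor s, and the preference parameters
(μ, κ) stay orthogonal.  Defaults: μ = 3π/2 (falling edge), κ = 2,
r₀ = 30 calls/s, s = 1.

A refractory period (default 10 ms, the scale of the species-typical ~11 Hz
spontaneous call rhythm) removes unrealistically short inter-call intervals.
**Caveat:** dead-time thinning is not phase-neutral — at high rates it
preferentially removes calls inside the high-intensity phase band, biasing
the realized circular mean by a few hundredths of a radian and flattening
κ.  Recovery tests that must isolate measurement error therefore simulate
with `refractory_s=0`, where the realized phase distribution is exactly
vM(μ, κ).

Call durations are log-normal with median 3.4 ms (σ = 0.7, giving an IQR
near 3.3 ms) truncated to [1, 15] ms — the short-call regime of
echolocation pulses, without any claim about the true duration
distribution.  Call waveforms are Hann-windowed linear downward FM sweeps
(90 → 60 kHz) scaled so their RMS sits a chosen SNR above the masker RMS.

Count tables are NB-2 draws (gamma–Poisson mixture; variance μ + μ²/θ) per
(group × day × condition) cell, with condition effects specified as
incidence-rate ratios against the silent baseline.  Defaults emulate the
study layout: 4 groups × 5 days, 1 h blocks, baseline 4000 calls/block,
dispersion θ = 5.

What the generator does **not** emulate: social-call repertoire structure,
multi-individual attribution, spatial acoustics, echoes, recording
artifacts.  Passing tests demonstrate that the analysis recovers known
parameters under its own model assumptions — not that those assumptions
hold for any particular colony recording.

## Call detection (`detect`)

The detector is a deliberately simple stand-in for a trained neural
segmenter: short-time RMS (0.5 ms window) of the audio band-passed to
50–96 kHz (4th-order Butterworth, zero-phase), thresholded at a multiple
(default 4×) of the median RMS.  The median is the noise floor, so
detection is exactly invariant to overall gain.  Post-processing follows
the event-prediction rules used with this kind of data: events closer than
0.9 ms are merged, events shorter than 1 ms dropped.  Scoring is greedy
one-to-one onset matching within 1.5 ms.  Offsets are retained but flagged
low-confidence — short calls decay into their own echoes, so only onsets
are analysed downstream.  Overlap is strictly positive interval
intersection (touching endpoints do not count).

In dense call trains (tens of calls/s) the merge rule absorbs
near-simultaneous calls; recall figures are therefore quoted on isolated
events, and dense-regime phase statistics tolerate the resulting mild
flattening of κ.

## Envelope recovery and phase tagging (`phase`)

Steady-state recordings: narrow bandpass in a probe band inside the carrier
(default 10.1–10.5 kHz; if that band holds no energy — the high-frequency
masker — a warning is issued and 50.1–50.5 kHz is used) → Hilbert
magnitude → downsample ÷10 → bandpass at modulation rate ± 1 Hz
(2nd order) → demean → zero-pad 20 samples.  A modulation-index check
(rate-band envelope SD relative to carrier level, threshold 0.1) flags
unmodulated audio.

Random-cycle recordings: bandpass 15–60 kHz → Hilbert → ÷10 → 70 Hz
lowpass → 12-point moving average, then cross-correlation against the
analytic envelope implied by the logged cycle sequence.  The correlation
peak gives the alignment lag; the even-length moving average delays the
measured envelope by exactly half a sample, which is subtracted, leaving a
residual alignment error of ~0.5 envelope samples (≈26 µs at 19.2 kHz).  A
normalized peak correlation below 0.2 raises an alignment error.

**All filtering is zero-phase (forward–backward).**  A causal IIR filter's
group delay would shift every tagged phase by a rate-dependent offset,
corrupting the core measurement; forward–backward filtering doubles the
effective order but has exactly zero phase.

Troughs are local minima with minimum separation 0.7× the shortest
expected period and prominence ≥ 10% of the envelope range (robust to
residual ripple; the peak-picking parameters are package choices).  Phase
ramps linearly 0 → 2π between consecutive troughs; each cycle's deviation
of trough interval from its nominal period is kept as the model's timing
error.  Onsets outside the first/last trough are left untagged and excluded
from circular analyses.  Phase lookup is exact piecewise-linear
interpolation (error bounded well below the 1.5 ms detection tolerance).

Silent-baseline files use a fictitious cosine envelope aligned to the start
of the file.  "Aligned" is interpreted as **envelope maximum at t = 0**, so
under the trough-zero convention the phase at t = 0 is π and troughs fall
at (k + ½)/f.  This interpretation is a deliberate disambiguation (the
alternative — trough at t = 0 — only rotates the null distribution and
cannot create spurious clustering); it is centralized in
`simulate_silent_phase` should a user need the other convention.

## Circular statistics (`circstats`)

Mean direction ᾱ = atan2(Σ sin αⱼ, Σ cos αⱼ); resultant length
R = √((Σ sin)² + (Σ cos)²); mean resultant r̄ = R/n ∈ [0, 1]; angular
dispersion n − R.  The mean is flagged undefined when R ≈ 0.

- **Rayleigh test**: Z = n r̄², p from the standard asymptotic series with
  finite-n correction, p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)).
- **von Mises MLE**: μ̂ = ᾱ; κ̂ solves A(κ) = I₁(κ)/I₀(κ) = r̄ by Newton
  iteration seeded with the usual small/large-r̄ rational approximations,
  using exponentially scaled Bessel functions for overflow safety.  κ̂ is
  capped at 500 and flagged for (near-)degenerate samples.  The identity
  A(κ̂) = r̄ holds to 1e-8 (tested).
- **Bootstrap**: n_boot = 1000 resamples with replacement by default;
  percentile CIs, with μ replicates recentred around the point estimate
  (wrapped to (−π, π]) before taking percentiles, to avoid artifacts at the
  0/2π seam.
- **Mardia–Watson–Wheeler**: uniform-scores statistic (average ranks on
  ties), χ² with 2(k − 1) df; groups smaller than 10 fall back to a seeded
  permutation p-value.
- **Rao homogeneity**: delta-method χ² tests with k − 1 df — tangents of
  group mean directions for equality of means, group mean resultant lengths
  for equality of dispersions.  All groups are pre-rotated by the pooled
  mean direction, which keeps the tangents well-conditioned and makes both
  statistics exactly rotation-invariant.  Post-hoc pairwise tests are
  Bonferroni-adjusted over C(k, 2) pairs.

All four tests hold their nominal 5% type-I error to within ±1% in
10,000-replicate null simulations (acceptance suite).

One documented discrepancy: published analyses of this kind sometimes
report small *negative* "r" values for near-uniform samples, which the mean
resultant length (bounded to [0, 1]) cannot produce; those values
presumably reflect a bias-corrected effect-size variant whose exact
definition is not stated.  This package reports the raw r̄ only.

## Count models (`ratemodels`)

NB-2 regression (log link, variance μ + αμ²) with the silent baseline as
reference level, fitted by full ML including the dispersion parameter
(statsmodels).  Exponentiated coefficients are incidence-rate ratios with
Wald 95% CIs.  The condition factor is tested by a likelihood-ratio ANOVA:
both the condition model and the intercept-only model are evaluated as NB
GLMs at the full model's dispersion, χ² = 2Δℓ with k − 1 df — the standard
partial-LRT construction for a single factor.  Marginal means are linear
predictor values per condition with delta-method SEs; pairwise contrasts
are z-tests, Bonferroni-adjusted.

Equal-duration (1 h) blocks need no offset; unequal exposures (e.g.
per-rate occupancy time inside the random masker, computed from the cycle
sequence by `rate_exposures`) enter as a log-exposure offset, which is
opt-in because the default block design is balanced.  A condition with all-
zero counts would make the log-link inestimable; such conditions get ½
added to each of their blocks, with a warning.

## Timing-anchor classification (`classify`)

The timing measures treat μ dimensionally as an angle and convert it to
within-cycle time before differencing — mu_time = μ/(2π)·T with T = 1/f in
ms — because mixing radians with 1/f directly is not dimensionally
coherent and only the time-converted reading yields millisecond measures:

    t_from_peak = mu_time − T/2      t_to_trough = T − mu_time

with the identity t_from_peak + t_to_trough = T/2 holding algebraically.
Because of that identity the two predictors are exactly collinear within
class, so the "full" two-predictor LDA has a singular pooled within-class
covariance; a conditioning check (condition number > 1e6) switches the
solver to Ledoit–Wolf shrinkage and flags the model as regularized.

The analysis splits the bootstrapped measures 0.6:0.4 stratified on
modulation rate, centres and scales predictors with training-set statistics
only (a Pipeline, so CV folds are also leak-free), trains with 10-fold CV
repeated 10 times, and evaluates on the held-out 40%: confusion matrix,
Clopper–Pearson exact binomial 95% CI for accuracy, per-class one-vs-rest
F1 with macro average, and one-vs-rest ROC/AUC (macro-averaged for > 2
classes).  Posterior ties resolve to the lowest class index (scikit-learn's
argmax convention); CV fold assignment is seeded.

## Problem sizes used in tests

The test and acceptance suites run entirely on synthetic data at desk
scale: 60 s of 192 kHz audio for the end-to-end recovery (~2000 calls),
20 s for alignment, 10,000 replicates for test calibration, 100 simulated
count tables of 40 blocks/condition for NB recovery, and 1000 bootstrap-
mean samples (250 per rate × 4 rates) for the classifier.  These sizes were
chosen as the smallest at which the targeted effects are statistically
unambiguous.

## Known limitations

- The detector is an energy threshold, not a trained segmenter; its
  false-negative behaviour in dense call clusters (merge rule) differs from
  a network segmenter's, and no claim of equivalence is made.
- Rao's homogeneity tests assume reasonably concentrated unimodal groups;
  with near-uniform data the tangent statistic is ill-conditioned.
- The NB models are fixed-effects only; group is a design cell, not a
  random effect.
- Bootstrap percentile CIs for μ slightly undercover at small n (~92% at
  n = 200); coverage reaches the nominal regime by n ≈ 500.
- Envelope recovery above ~40 Hz modulation is increasingly limited by the
  ÷10 downsampling and trough-picking resolution; the package's accuracy
  guarantees are stated for rates ≤ 16 Hz, the regime where anti-phase
  calling is expected.
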