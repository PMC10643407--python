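"""Envelope recovery and trough-anchored instantaneous-phase tagging.

The amplitude-modulation envelope of a recorded masker is recovered from the
audio itself (steady-state playback) or by aligning a known cycle sequence to
the audio via cross-correlation (random playback).  Envelope troughs define
cycle boundaries; instantaneous phase ramps linearly from 0 at each trough to
2*pi at the next, so phase 0 is always the amplitude trough and phase pi the
peak.  Call onsets are tagged with the phase at their onset time.

All filtering is zero-phase (forward-backward), because a causal filter's
group delay would bias every tagged phase by a rate-dependent offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .stimgen import CycleSequence, Waveform, am_envelope


class PhaseModelError(ValueError):
    """Raised when an envelope cannot support a phase model."""


class AlignmentError(RuntimeError):
    """Raised when cross-correlation alignment of the cycle sequence fails."""


@dataclass(frozen=True)
class EnvelopeSignal:
    """A recovered modulation envelope sampled at ``sample_rate`` from time ``t0``."""

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.sample_rate


def _sosfiltfilt_bandpass(x, lo_hz, hi_hz, fs, order):
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _band_power_fraction(x: np.ndarray, fs: float, lo_hz: float, hi_hz: float) -> float:
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    p = np.abs(np.fft.rfft(x)) ** 2
    total = p.sum()
    if total == 0:
        return 0.0
    sel = (freqs >= lo_hz) & (freqs <= hi_hz)
    # compare mean in-band density to mean overall density
    return float(p[sel].mean() / p.mean())


DOWNSAMPLE_FACTOR = 10
EDGE_PAD_SAMPLES = 20


def extract_envelope_steady(
    audio: Waveform,
    modulation_rate: float,
    probe_band_khz: tuple[float, float] = (10.1, 10.5),
    alternate_probe_band_khz: tuple[float, float] = (50.1, 50.5),
) -> EnvelopeSignal:
    """Recover the AM envelope of a steady-state masker recording.

    Pipeline: narrow bandpass in a probe band inside the masker's carrier
    (3rd-order Butterworth, zero-phase) -> Hilbert magnitude -> downsample by
    10 -> bandpass at modulation_rate +/- 1 Hz (2nd order) -> demean ->
    zero-pad 20 samples at both ends.

    If the default probe band holds no masker energy (high-frequency masker),
    a warning is issued and ``alternate_probe_band_khz`` is used instead.
    """
    band = probe_band_khz
    density_ratio = _band_power_fraction(
        audio.samples, audio.sample_rate, band[0] * 1000, band[1] * 1000
    )
    if density_ratio < 0.02:
        warnings.warn(
            f"probe band {band} kHz holds almost no energy "
            f"(density ratio {density_ratio:.3g}); falling back to "
            f"{alternate_probe_band_khz} kHz",
            stacklevel=2,
        )
        band = alternate_probe_band_khz
    narrow = _sosfiltfilt_bandpass(
        audio.samples, band[0] * 1000, band[1] * 1000, audio.sample_rate, order=3
    )
    mag = np.abs(signal.hilbert(narrow))
    env = mag[::DOWNSAMPLE_FACTOR]
    fs_env = audio.sample_rate / DOWNSAMPLE_FACTOR
    level = env.mean()  # carrier level before rate-band filtering
    lo = max(modulation_rate - 1.0, 0.1)
    env = _sosfiltfilt_bandpass(env, lo, modulation_rate + 1.0, fs_env, order=2)
    env = env - env.mean()
    # modulation index: rate-band envelope variation relative to carrier level
    if level > 0 and np.std(env) / level < 0.1:
        warnings.warn(
            f"modulation index {np.std(env) / level:.3g} is near zero after "
            "rate-band filtering; audio may be unmodulated", stacklevel=2
        )
    env = np.pad(env, EDGE_PAD_SAMPLES)
    return EnvelopeSignal(env, fs_env, t0=-EDGE_PAD_SAMPLES / fs_env)


def extract_envelope_random(
    audio: Waveform,
    cycle_sequence: CycleSequence,
    band_khz: tuple[float, float] = (15.0, 60.0),
    min_peak_corr: float = 0.2,
) -> tuple[EnvelopeSignal, float]:
    """Recover an aligned envelope for a random-cycle masker recording.

    The measured envelope (bandpass 15-60 kHz -> Hilbert -> downsample by 10
    -> 70 Hz lowpass -> 12-point moving average) is cross-correlated with the
    modulation signal implied by the known cycle sequence; the lag at the
    correlation peak aligns the analytic envelope to the recording.  Returns
    the aligned, demeaned, zero-padded model envelope and the lag in seconds
    (positive = stimulus starts after recording onset).
    """
    filt = _sosfiltfilt_bandpass(
        audio.samples, band_khz[0] * 1000, band_khz[1] * 1000, audio.sample_rate, order=3
    )
    mag = np.abs(signal.hilbert(filt))
    env = mag[::DOWNSAMPLE_FACTOR]
    fs_env = audio.sample_rate / DOWNSAMPLE_FACTOR
    sos = signal.butter(2, 70.0, btype="lowpass", fs=fs_env, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = np.convolve(env, np.ones(12) / 12.0, mode="same")
    env = env - env.mean()

    n_model = int(round(cycle_sequence.total_duration * fs_env))
    t_model = np.arange(n_model) / fs_env
    model = am_envelope(t_model, cycle_sequence, depth=1.0)
    model = model - model.mean()

    corr = signal.correlate(env, model, mode="full")
    lags = signal.correlation_lags(len(env), len(model), mode="full")
    peak_idx = int(np.argmax(corr))
    denom = np.linalg.norm(env) * np.linalg.norm(model)
    peak_corr = corr[peak_idx] / denom if denom > 0 else 0.0
    if peak_corr < min_peak_corr:
        raise AlignmentError(
            f"cycle-sequence alignment failed: normalized correlation peak "
            f"{peak_corr:.3f} < {min_peak_corr}"
        )
    # the even-length (12-point) moving average delays the measured envelope
    # by half a sample; compensate so the lag is unbiased
    lag_samples = int(lags[peak_idx])
    lag_s = (lag_samples - 0.5) / fs_env

    aligned = np.pad(model, EDGE_PAD_SAMPLES)
    t0 = lag_s - EDGE_PAD_SAMPLES / fs_env
    return EnvelopeSignal(aligned, fs_env, t0=t0), lag_s


def detect_troughs(
    envelope: EnvelopeSignal,
    expected_rates,
    min_separation_factor: float = 0.7,
    prominence_fraction: float = 0.10,
) -> np.ndarray:
    """Find envelope minima (cycle boundaries), returned as ordered times.

    Minima must be separated by at least ``min_separation_factor`` times the
    shortest expected cycle and be prominent relative to the envelope range,
    which rejects residual ripple without missing true troughs.
    """
    rates = np.atleast_1d(np.asarray(expected_rates, dtype=np.float64))
    min_period = 1.0 / rates.max()
    distance = max(1, int(min_separation_factor * min_period * envelope.sample_rate))
    rng_amp = np.ptp(envelope.values)
    if rng_amp == 0:
        raise PhaseModelError("flat envelope: no troughs to detect")
    idx, _ = signal.find_peaks(
        -envelope.values, distance=distance, prominence=prominence_fraction * rng_amp
    )
    if len(idx) < 2:
        raise PhaseModelError(
            f"found {len(idx)} trough(s); at least 2 are needed for a phase model"
        )
    return envelope.t0 + idx / envelope.sample_rate


@dataclass(frozen=True)
class EnvelopePhaseModel:
    """Trough-anchored instantaneous phase: 0 at each trough, linear to 2*pi.

    ``cycle_rates`` labels each of the ``len(trough_times) - 1`` cycles with
    its nominal modulation rate; ``timing_error`` holds each cycle's deviation
    of trough interval from the nominal period (a measure of the temporal
    accuracy of the phase model).
    """

    trough_times: np.ndarray
    cycle_rates: np.ndarray
    timing_error: np.ndarray = field(repr=False)

    @property
    def n_cycles(self) -> int:
        return len(self.trough_times) - 1

    @property
    def start(self) -> float:
        return float(self.trough_times[0])

    @property
    def end(self) -> float:
        return float(self.trough_times[-1])

    def covers(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        return (t >= self.start) & (t <= self.end)

    def phase_at(self, t) -> np.ndarray:
        """Instantaneous phase in [0, 2*pi); NaN outside the modelled span."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        idx = np.searchsorted(self.trough_times, t, side="right") - 1
        idx = np.clip(idx, 0, self.n_cycles - 1)
        span = self.trough_times[idx + 1] - self.trough_times[idx]
        frac = (t - self.trough_times[idx]) / span
        phase = (2 * np.pi * frac) % (2 * np.pi)
        phase[~self.covers(t)] = np.nan
        return phase

    def rate_at(self, t) -> np.ndarray:
        """Nominal modulation rate (Hz) of the cycle containing each time."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        idx = np.searchsorted(self.trough_times, t, side="right") - 1
        idx = np.clip(idx, 0, self.n_cycles - 1)
        out = self.cycle_rates[idx].astype(np.float64)
        out[~self.covers(t)] = np.nan
        return out

    def sample_phase(self, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample (times, phase) over the modelled span at ``sample_rate``."""
        t = np.arange(self.start, self.end, 1.0 / sample_rate)
        return t, self.phase_at(t)


def build_phase_model(
    trough_times,
    cycle_rates=None,
    expected_rates=None,
) -> EnvelopePhaseModel:
    """Construct the phase model from ordered trough times.

    Cycle rates are taken from ``cycle_rates`` (one per cycle) or, failing
    that, inferred per cycle as the member of ``expected_rates`` nearest to
    the reciprocal trough interval.
    """
    troughs = np.asarray(trough_times, dtype=np.float64)
    if len(troughs) < 2:
        raise PhaseModelError("at least 2 troughs are required")
    if np.any(np.diff(troughs) <= 0):
        raise PhaseModelError("trough times must be strictly increasing")
    intervals = np.diff(troughs)
    if cycle_rates is not None:
        rates = np.asarray(cycle_rates, dtype=np.float64)
        if len(rates) != len(intervals):
            raise PhaseModelError(
                f"{len(rates)} cycle rates given for {len(intervals)} cycles"
            )
    elif expected_rates is not None:
        cand = np.atleast_1d(np.asarray(expected_rates, dtype=np.float64))
        rates = cand[np.argmin(np.abs(intervals[:, None] - 1.0 / cand[None, :]), axis=1)]
    else:
        rates = 1.0 / intervals
    timing_error = intervals - 1.0 / rates
    return EnvelopePhaseModel(troughs, rates, timing_error)


def simulate_silent_phase(
    modulation_rate: float, file_duration: float
) -> EnvelopePhaseModel:
    """Fictitious phase model for silent-baseline files.

    The simulated envelope is a cosine aligned to the start of the file
    (amplitude maximum at t = 0), so troughs fall at t = (k + 1/2) / f and
    the phase at t = 0 is pi.  A leading virtual trough before t = 0 lets
    calls from the very start of the file be tagged.
    """
    if modulation_rate <= 0:
        raise ValueError("modulation rate must be positive")
    f = modulation_rate
    k = np.arange(-1, int(np.floor(file_duration * f - 0.5)) + 1)
    troughs = (k + 0.5) / f
    return build_phase_model(troughs, cycle_rates=np.full(len(troughs) - 1, f))


def phase_model_from_cycles(cycle_sequence) -> EnvelopePhaseModel:
    """Exact phase model implied by a known cycle sequence (no audio involved)."""
    return build_phase_model(
        cycle_sequence.boundaries(), cycle_rates=cycle_sequence.rates
    )


def phase_model_from_envelope(
    envelope: EnvelopeSignal, expected_rates, **trough_kwargs
) -> EnvelopePhaseModel:
    """Convenience: detect troughs on an envelope and build the phase model."""
    troughs = detect_troughs(envelope, expected_rates, **trough_kwargs)
    return build_phase_model(troughs, expected_rates=expected_rates)


def tag_call_onsets(events: pd.DataFrame, model: EnvelopePhaseModel) -> pd.DataFrame:
    """Tag each call onset with instantaneous phase and cycle rate.

    Adds ``onset_phase_rad``, ``cycle_rate_hz`` and boolean ``tagged``
    columns; onsets outside the modelled [first trough, last trough] span are
    left untagged (NaN phase) and must be excluded from circular analyses.
    """
    out = events.copy()
    onsets = out["onset_s"].to_numpy(dtype=np.float64)
    out["onset_phase_rad"] = model.phase_at(onsets)
    out["cycle_rate_hz"] = model.rate_at(onsets)
    out["tagged"] = model.covers(onsets)
    return out
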