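"""Synthesis of band-limited, amplitude-modulated noise maskers.

Maskers are Gaussian white noise restricted to a carrier band (e.g. 10-96 kHz
"broadband" or 50-96 kHz "high-frequency"), amplitude modulated by a raised
cosine whose troughs sit at cycle boundaries.  The modulation schedule is
either a single steady rate or an explicit ordered sequence of single AM
cycles (the "random masker"), recorded as a :class:`CycleSequence` so that
downstream phase modelling knows the exact cycle layout.

Phase convention throughout the package: phase 0 (= 2*pi) is the amplitude
trough at a cycle boundary, phase pi is the amplitude peak mid-cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile


class InvalidSpecError(ValueError):
    """Raised when a stimulus specification is physically inconsistent."""


@dataclass(frozen=True)
class Waveform:
    """Sampled audio: ``samples`` (float64, peak-normalized) at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def normalized(self) -> "Waveform":
        peak = np.max(np.abs(self.samples))
        if peak == 0:
            return self
        return Waveform(self.samples / peak, self.sample_rate)

    def to_wav(self, path, subtype: str = "float32") -> None:
        """Write to WAV; ``subtype`` is ``"float32"`` or ``"pcm16"``."""
        x = self.normalized().samples
        if subtype == "pcm16":
            data = np.round(x * 32767).astype(np.int16)
        elif subtype == "float32":
            data = x.astype(np.float32)
        else:
            raise ValueError(f"unsupported WAV subtype: {subtype!r}")
        wavfile.write(path, int(self.sample_rate), data)

def read_wav(path) -> Waveform:
    """Read a WAV file into a float64 :class:`Waveform` scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = np.asarray(data, dtype=np.float64)
    return Waveform(data, float(rate))


@dataclass(frozen=True)
class CycleSequence:
    """Ordered amplitude-modulation cycles: rate (Hz) and duration (= 1/rate) each.

    ``start_times`` gives the onset of each cycle; consecutive cycles abut, so
    cycle k spans [start_times[k], start_times[k] + 1/rates[k]).
    """

    rates: np.ndarray  # Hz, one entry per cycle
    start_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=np.float64)
        if rates.ndim != 1 or len(rates) == 0:
            raise InvalidSpecError("cycle sequence needs at least one cycle")
        if np.any(rates <= 0):
            raise InvalidSpecError("every modulation rate must be > 0")
        object.__setattr__(self, "rates", rates)
        if self.start_times is None:
            starts = np.concatenate([[0.0], np.cumsum(1.0 / rates)[:-1]])
            object.__setattr__(self, "start_times", starts)
        else:
            object.__setattr__(
                self, "start_times", np.asarray(self.start_times, dtype=np.float64)
            )

    @property
    def durations(self) -> np.ndarray:
        return 1.0 / self.rates

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def total_duration(self) -> float:
        return float(self.end_times[-1])

    def boundaries(self) -> np.ndarray:
        """Cycle-boundary (trough) times: n_cycles + 1 values."""
        return np.concatenate([self.start_times, [self.end_times[-1]]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle_index": np.arange(len(self.rates)),
                "rate_hz": self.rates,
                "start_s": self.start_times,
                "end_s": self.end_times,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "CycleSequence":
        df = pd.read_csv(path)
        return CycleSequence(df["rate_hz"].to_numpy(), df["start_s"].to_numpy())


@dataclass(frozen=True)
class MaskerSpec:
    """Full definition of an AM-noise masker stimulus.

    carrier_band : (low, high) in kHz; must satisfy low < high <= Nyquist.
    am_schedule  : a single modulation rate in Hz, or a CycleSequence.
    modulation_depth : 1.0 means envelope reaches zero at each trough.
    """

    carrier_band: tuple[float, float]
    sample_rate: float = 192_000.0
    duration: float = 60.0
    am_schedule: float | CycleSequence = 8.0
    modulation_depth: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.carrier_band
        if not (0 <= lo < hi):
            raise InvalidSpecError(f"carrier band must satisfy 0 <= low < high, got {self.carrier_band}")
        if hi * 1000.0 > self.sample_rate / 2:
            raise InvalidSpecError(
                f"carrier band top {hi} kHz exceeds Nyquist ({self.sample_rate / 2000} kHz)"
            )
        if self.duration <= 0:
            raise InvalidSpecError("duration must be positive")
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise ValueError("modulation depth must lie in [0, 1]")

    def render(self) -> tuple[Waveform, CycleSequence]:
        """Synthesize the masker: band-limited noise times the AM envelope."""
        carrier = make_carrier_noise(
            self.carrier_band, self.duration, self.sample_rate, self.rng_seed
        )
        return apply_am(carrier, self.am_schedule, self.modulation_depth)


def make_carrier_noise(
    band_khz: tuple[float, float],
    duration: float,
    sample_rate: float,
    seed: int,
) -> Waveform:
    """Gaussian white noise band-limited to ``band_khz`` by FFT-domain masking.

    FFT masking gives exact band edges and bit-reproducible output for a fixed
    seed, unlike an IIR design whose transition bands leak energy.
    """
    lo, hi = band_khz
    if hi * 1000.0 > sample_rate / 2:
        raise InvalidSpecError(
            f"band top {hi} kHz exceeds Nyquist {sample_rate / 2000:.1f} kHz"
        )
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    keep = (freqs >= lo * 1000.0) & (freqs <= hi * 1000.0)
    spec[~keep] = 0.0
    y = np.fft.irfft(spec, n=n)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = y / peak
    return Waveform(y, sample_rate)


def am_envelope(
    t: np.ndarray, schedule: float | CycleSequence, depth: float = 1.0
) -> np.ndarray:
    """Raised-cosine AM envelope with troughs at cycle boundaries.

    Within a cycle of rate f starting at t0:
    e(t) = depth * (1 - cos(2*pi*f*(t - t0))) / 2 + (1 - depth),
    so e = 1 - depth at the trough (cycle edges) and 1 at mid-cycle.
    """
    t = np.asarray(t, dtype=np.float64)
    if not isinstance(schedule, CycleSequence):
        f = float(schedule)
        local = t * f - np.floor(t * f)
        shape = (1.0 - np.cos(2 * np.pi * local)) / 2.0
    else:
        idx = np.searchsorted(schedule.start_times, t, side="right") - 1
        idx = np.clip(idx, 0, len(schedule.rates) - 1)
        local = (t - schedule.start_times[idx]) * schedule.rates[idx]
        local = np.clip(local, 0.0, 1.0)
        shape = (1.0 - np.cos(2 * np.pi * local)) / 2.0
    return depth * shape + (1.0 - depth)


def apply_am(
    waveform: Waveform,
    schedule: float | CycleSequence,
    depth: float = 1.0,
) -> tuple[Waveform, CycleSequence]:
    """Amplitude-modulate ``waveform`` and return it with the realized cycles.

    A scalar ``schedule`` is expanded into the integer number of whole cycles
    covering the waveform (the trailing partial cycle, if any, still follows
    the same raised cosine).
    """
    if not (0.0 <= depth <= 1.0):
        raise ValueError(f"modulation depth must lie in [0, 1], got {depth}")
    t = waveform.times
    env = am_envelope(t, schedule, depth)
    out = Waveform(waveform.samples * env, waveform.sample_rate)
    if isinstance(schedule, CycleSequence):
        realized = schedule
    else:
        n_cycles = max(1, int(np.ceil(waveform.duration * float(schedule) - 1e-9)))
        realized = CycleSequence(np.full(n_cycles, float(schedule)))
    return out, realized


def make_random_cycle_sequence(
    rates,
    total_duration: float,
    seed: int,
    block_duration: float = 15 * 60.0,
) -> CycleSequence:
    """Pseudo-random permutation-with-repetition of single AM cycles.

    The stream is assembled in blocks (default 15 min).  Each block allots
    equal playback time to every rate, converts that time to whole cycles
    (time * rate of them), pools the cycles and shuffles them, so long-run
    occupancy time is uniform across rates while the local order is random.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if len(rates) == 0:
        raise InvalidSpecError("need at least one modulation rate")
    rng = np.random.default_rng(seed)
    n_blocks = max(1, int(round(total_duration / block_duration)))
    per_rate_time = min(block_duration, total_duration) / len(rates)
    all_rates: list[np.ndarray] = []
    for _ in range(n_blocks):
        pool = np.concatenate(
            [np.full(max(1, int(round(per_rate_time * r))), r) for r in rates]
        )
        rng.shuffle(pool)
        all_rates.append(pool)
    return CycleSequence(np.concatenate(all_rates))


def make_random_masker(
    rates,
    total_duration: float,
    sample_rate: float,
    seed: int,
    band_khz: tuple[float, float] = (10.0, 96.0),
    depth: float = 1.0,
    block_duration: float = 15 * 60.0,
) -> tuple[Waveform, CycleSequence]:
    """Render a random masker: band-limited noise under a shuffled cycle stream."""
    seq = make_random_cycle_sequence(rates, total_duration, seed, block_duration)
    carrier = make_carrier_noise(band_khz, seq.total_duration, sample_rate, seed)
    wav, _ = apply_am(carrier, seq, depth)
    return wav, seq


@dataclass(frozen=True)
class PlaybackBlock:
    rate_hz: float
    start_s: float
    end_s: float


def make_steady_state_program(
    rates, block_duration: float, seed: int
) -> list[PlaybackBlock]:
    """Randomly ordered program of per-rate steady-state blocks.

    Each rate appears exactly once for ``block_duration`` seconds; total
    program length is ``len(rates) * block_duration``.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if block_duration <= 0:
        raise InvalidSpecError("block duration must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rates))
    blocks = []
    t = 0.0
    for i in order:
        blocks.append(PlaybackBlock(float(rates[i]), t, t + block_duration))
        t += block_duration
    return blocks
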