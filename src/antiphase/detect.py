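"""Threshold-based call-event detection, detection scoring, and overlap counts.

The detector is a deliberately simple energy detector: short-time RMS of the
audio band-passed to the echolocation band (50-96 kHz), thresholded relative
to the noise floor (median RMS), with the post-processing rules used for
event prediction in this kind of data: a minimum event duration of 1 ms and
merging of events separated by less than 0.9 ms.  Detection is scored by
greedy one-to-one onset matching within a 1.5 ms tolerance.

The threshold is noise-floor-relative, so detection is invariant to overall
gain scaling of the recording.  Offsets are retained but are low-confidence:
short calls decay into their own echoes, so only onsets are analysed further.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .stimgen import Waveform


@dataclass(frozen=True)
class DetectionParams:
    energy_threshold: float = 4.0  # multiple of the noise-floor (median) RMS
    min_event_duration_ms: float = 1.0
    min_gap_ms: float = 0.9
    onset_tolerance_ms: float = 1.5
    detection_band_khz: tuple[float, float] = (50.0, 96.0)
    rms_window_ms: float = 0.5

    def __post_init__(self):
        for name in ("energy_threshold", "min_event_duration_ms", "min_gap_ms",
                     "onset_tolerance_ms", "rms_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def detect_calls(audio: Waveform, params: DetectionParams | None = None) -> pd.DataFrame:
    """Detect call events as supra-threshold bursts of in-band energy.

    Returns a table with ``onset_s``, ``offset_s``, ``duration_ms`` and an
    ``offset_confident`` flag (always False: offsets are ill-defined for
    short calls and kept only as rough duration estimates).
    """
    params = params or DetectionParams()
    fs = audio.sample_rate
    lo, hi = params.detection_band_khz
    if fs < 2 * hi * 1000:
        raise ValueError(
            f"sample rate {fs} Hz cannot represent the {hi} kHz band top"
        )
    hi_hz = min(hi * 1000, 0.999 * fs / 2)
    sos = signal.butter(4, [lo * 1000, hi_hz], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, audio.samples)
    win = max(3, int(round(params.rms_window_ms / 1000 * fs)))
    power = ndimage.uniform_filter1d(x**2, size=win)
    rms = np.sqrt(np.maximum(power, 0.0))
    floor = np.median(rms)
    if floor == 0:
        return _empty_events()
    above = rms > params.energy_threshold * floor
    if not above.any():
        return _empty_events()

    # contiguous supra-threshold runs -> candidate events
    idx = np.flatnonzero(above)
    run_starts = [idx[0]]
    run_ends = []
    gaps = np.flatnonzero(np.diff(idx) > 1)
    for g in gaps:
        run_ends.append(idx[g])
        run_starts.append(idx[g + 1])
    run_ends.append(idx[-1])
    onsets = np.asarray(run_starts) / fs
    offsets = (np.asarray(run_ends) + 1) / fs

    # merge events whose boundary gap is below min_gap
    min_gap = params.min_gap_ms / 1000.0
    merged_on, merged_off = [onsets[0]], [offsets[0]]
    for on, off in zip(onsets[1:], offsets[1:]):
        if on - merged_off[-1] < min_gap:
            merged_off[-1] = off
        else:
            merged_on.append(on)
            merged_off.append(off)
    onsets = np.asarray(merged_on)
    offsets = np.asarray(merged_off)

    # drop events shorter than the minimum duration
    keep = (offsets - onsets) >= params.min_event_duration_ms / 1000.0
    onsets, offsets = onsets[keep], offsets[keep]
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "offset_s": offsets,
            "duration_ms": (offsets - onsets) * 1000.0,
            "offset_confident": False,
        }
    )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {"onset_s": pd.Series(dtype=float), "offset_s": pd.Series(dtype=float),
         "duration_ms": pd.Series(dtype=float),
         "offset_confident": pd.Series(dtype=bool)}
    )


@dataclass(frozen=True)
class DetectionScore:
    precision: float
    recall: float
    f1: float
    median_error_ms: float
    n_matched: int
    n_predicted: int
    n_truth: int
    recall_defined: bool = True


def evaluate_detection(
    predicted_onsets, truth_onsets, tolerance_ms: float = 1.5
) -> DetectionScore:
    """Score predicted against true onsets by greedy one-to-one matching.

    Both lists must be time-sorted.  Each truth onset is matched to the
    nearest unmatched prediction within ``tolerance_ms``; precision, recall
    and F1 follow, plus the median absolute temporal error of the matches.
    """
    pred = np.asarray(predicted_onsets, dtype=np.float64)
    truth = np.asarray(truth_onsets, dtype=np.float64)
    if np.any(np.diff(pred) < 0) or np.any(np.diff(truth) < 0):
        raise ValueError("onset lists must be time-sorted")
    tol = tolerance_ms / 1000.0
    used = np.zeros(len(pred), dtype=bool)
    errors = []
    for t in truth:
        cand = np.flatnonzero(~used & (np.abs(pred - t) <= tol))
        if len(cand):
            j = cand[np.argmin(np.abs(pred[cand] - t))]
            used[j] = True
            errors.append(abs(pred[j] - t))
    n_match = len(errors)
    precision = n_match / len(pred) if len(pred) else (1.0 if len(truth) == 0 else 0.0)
    if len(truth) == 0:
        if len(pred):
            warnings.warn("no truth events but predictions exist: recall undefined",
                          stacklevel=2)
        return DetectionScore(
            precision=0.0 if len(pred) else 1.0, recall=float("nan"),
            f1=float("nan"), median_error_ms=float("nan"),
            n_matched=0, n_predicted=len(pred), n_truth=0, recall_defined=False,
        )
    recall = n_match / len(truth)
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    med = float(np.median(errors) * 1000.0) if errors else float("nan")
    return DetectionScore(
        precision=float(precision), recall=float(recall), f1=float(f1),
        median_error_ms=med, n_matched=n_match,
        n_predicted=len(pred), n_truth=len(truth),
    )


def find_overlaps(events: pd.DataFrame) -> pd.DataFrame:
    """Flag pairs of events with strictly positive interval intersection.

    Touching endpoints do not count as overlap.  Returns one row per
    overlapping pair (indices into ``events`` plus the overlap duration);
    use :func:`overlap_counts` for per-condition totals.
    """
    df = events.sort_values("onset_s").reset_index()
    onsets = df["onset_s"].to_numpy()
    offsets = df["offset_s"].to_numpy()
    rows = []
    active: list[int] = []  # indices of events whose offset may still overlap
    for i in range(len(df)):
        active = [j for j in active if offsets[j] > onsets[i]]
        for j in active:
            ov = min(offsets[i], offsets[j]) - onsets[i]
            if ov > 0:
                rows.append(
                    {"index_a": int(df.loc[j, "index"]),
                     "index_b": int(df.loc[i, "index"]),
                     "overlap_s": float(ov)}
                )
        active.append(i)
    return pd.DataFrame(rows, columns=["index_a", "index_b", "overlap_s"])


def overlap_counts(events: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Count overlapping pairs per condition cell (grouping columns ``by``)."""
    out = []
    for key, grp in events.groupby(by):
        pairs = find_overlaps(grp)
        key = key if isinstance(key, tuple) else (key,)
        out.append(dict(zip(by, key)) | {"n_overlapping_pairs": len(pairs)})
    return pd.DataFrame(out)
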