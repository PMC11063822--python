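"""Burst detection and locomotor-parameter extraction for ventral-root envelopes.

The locomotor parameters follow the standard definitions for drug-induced
fictive locomotion: frequency is the number of bursts divided by the length
of the analysis window; burst duration is offset minus onset; cycle period is
the reciprocal of the frequency; duty cycle is burst duration over cycle
period; amplitude is the peak-minus-valley excursion of each burst.  Each
parameter's coefficient of variation (sample SD over mean) quantifies rhythm
regularity.

Burst detection uses a fractional-range threshold: bursts are maximal
intervals where the envelope exceeds
``valley_floor + threshold_frac * (global_peak - valley_floor)``, merged when
separated by less than ``min_interval_s`` and discarded when shorter than
``min_duration_s``.  All three knobs are explicit parameters with logged
defaults (0.3 / 0.2 s / 0.3 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BurstEvent:
    """One detected burst: boundaries, peak and preceding-trough amplitudes."""

    onset: float
    offset: float
    peak_time: float
    peak_amp: float
    valley_amp: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"onset must precede offset, got ({self.onset}, {self.offset})")
        if not self.onset <= self.peak_time <= self.offset:
            raise ValueError("peak_time must lie within [onset, offset]")
        if self.peak_amp < self.valley_amp:
            raise ValueError("peak_amp must be >= valley_amp")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def amplitude(self) -> float:
        return self.peak_amp - self.valley_amp

    def shifted(self, dt: float) -> "BurstEvent":
        return BurstEvent(self.onset + dt, self.offset + dt, self.peak_time + dt,
                          self.peak_amp, self.valley_amp)


@dataclass
class LocomotorParams:
    """The five locomotor parameters plus per-parameter CVs for one window.

    With zero bursts the frequency is 0 and every ratio parameter is missing
    (``None``), not 0.
    """

    frequency: float
    burst_duration: Optional[float]
    cycle_period: Optional[float]
    duty_cycle: Optional[float]
    amplitude: Optional[float]
    cv: Dict[str, float]
    n_bursts: int
    window: Tuple[float, float]


def rectify_and_smooth(raw: np.ndarray, fs: float, smooth_window_s: float = 0.1,
                       ) -> np.ndarray:
    """Full-wave rectify then moving-average smooth a raw channel.

    Output is non-negative and the same length as the input (edges handled by
    nearest-sample padding).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("input series must not be empty")
    if smooth_window_s < 1.0 / fs:
        raise ValueError(f"smooth_window_s must be >= 1/fs = {1.0 / fs}")
    win = max(1, int(round(smooth_window_s * fs)))
    return uniform_filter1d(np.abs(raw), size=win, mode="nearest")


def _runs_above(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def detect_bursts(envelope: np.ndarray, fs: float, threshold_frac: float = 0.3,
                  min_duration_s: float = 0.2, min_interval_s: float = 0.3,
                  ) -> List[BurstEvent]:
    """Detect bursts in a rectified envelope with a fractional-range threshold.

    The threshold sits ``threshold_frac`` of the way from the envelope's
    global minimum (valley floor) to its global maximum.  Supra-threshold
    intervals closer than ``min_interval_s`` are merged; intervals shorter
    than ``min_duration_s`` are dropped.  Each event carries its internal
    peak and the minimum of the preceding inter-burst gap as its valley.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        raise ValueError("envelope must not be empty")
    floor = env.min()
    peak = env.max()
    if peak <= floor:
        logger.warning("flat envelope: no bursts detectable")
        return []
    thr = floor + threshold_frac * (peak - floor)
    runs = _runs_above(env > thr)
    if not runs:
        return []

    # merge runs separated by less than min_interval_s
    merged: List[List[int]] = [list(runs[0])]
    gap_n = min_interval_s * fs
    for start, stop in runs[1:]:
        if start - merged[-1][1] < gap_n:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    min_n = min_duration_s * fs
    kept = [(a, b) for a, b in merged if (b - a) >= min_n]

    events: List[BurstEvent] = []
    prev_stop = 0
    for start, stop in kept:
        seg = env[start:stop]
        ipk = start + int(np.argmax(seg))
        gap = env[prev_stop:start]
        valley = float(gap.min()) if gap.size else float(env[start])
        valley = min(valley, float(seg.max()))
        events.append(BurstEvent(
            onset=start / fs,
            offset=stop / fs,
            peak_time=ipk / fs,
            peak_amp=float(env[ipk]),
            valley_amp=valley,
        ))
        prev_stop = stop
    return events


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n - 1 denominator) divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def _safe_cv(values: np.ndarray) -> Optional[float]:
    try:
        return coefficient_of_variation(values)
    except ValueError:
        return None


def locomotor_parameters(events: Sequence[BurstEvent], window: Tuple[float, float],
                         ) -> LocomotorParams:
    """Compute the locomotor parameters for the events inside ``window``.

    A burst belongs to the window if its onset lies inside it, which keeps
    frequency = count / window length exact.  CVs are computed per burst for
    duration, period and amplitude, and over per-cycle instantaneous
    frequencies (1 / inter-onset interval) for frequency.
    """
    start, end = window
    if end <= start:
        raise ValueError(f"window length must be > 0, got {window}")
    length = end - start
    inside = [ev for ev in events if start <= ev.onset < end]
    n = len(inside)
    frequency = n / length
    if n == 0:
        return LocomotorParams(frequency=0.0, burst_duration=None, cycle_period=None,
                               duty_cycle=None, amplitude=None, cv={}, n_bursts=0,
                               window=window)
    durations = np.array([ev.duration for ev in inside])
    amplitudes = np.array([ev.amplitude for ev in inside])
    onsets = np.array([ev.onset for ev in inside])
    periods = np.diff(onsets)
    burst_duration = float(durations.mean())
    cycle_period = 1.0 / frequency
    cv: Dict[str, float] = {}
    for name, vals in (("duration", durations), ("amplitude", amplitudes),
                       ("period", periods)):
        c = _safe_cv(vals)
        if c is not None:
            cv[name] = c
    if periods.size >= 2 and np.all(periods > 0):
        c = _safe_cv(1.0 / periods)
        if c is not None:
            cv["frequency"] = c
    return LocomotorParams(
        frequency=frequency,
        burst_duration=burst_duration,
        cycle_period=cycle_period,
        duty_cycle=burst_duration / cycle_period,
        amplitude=float(amplitudes.mean()),
        cv=cv,
        n_bursts=n,
        window=window,
    )


def windowed_frequency(events: Sequence[BurstEvent], bin_s: float = 120.0,
                       t_start: float = 0.0, t_stop: Optional[float] = None,
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-bin burst rate over time (bursts counted by onset, partial trailing
    bin dropped).  Returns (bin centers in s, frequencies in Hz)."""
    if bin_s <= 0:
        raise ValueError(f"bin_s must be > 0, got {bin_s}")
    if not events:
        return np.array([]), np.array([])
    onsets = np.array([ev.onset for ev in events])
    if t_stop is None:
        t_stop = float(max(ev.offset for ev in events))
    n_bins = int(np.floor((t_stop - t_start) / bin_s))
    if n_bins <= 0:
        return np.array([]), np.array([])
    edges = t_start + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(onsets, bins=edges)
    centers = edges[:-1] + bin_s / 2.0
    return centers, counts / bin_s


#: Analysis windows per experimental condition, all in seconds:
#: chronic silencing uses the 5 min window 25-30 min after drug-induced
#: activity onset; acute (CNO) compares the last 4 min before CNO with the
#: last 4 min of CNO before washout; optogenetic protocols use a 20 s
#: pre-light baseline, the light window itself, and an equally long
#: post-light window.
def select_analysis_window(condition: str, annotations: Mapping[str, float],
                           ) -> Dict[str, Tuple[float, float]]:
    def need(key: str) -> float:
        if key not in annotations:
            raise ValueError(f"condition '{condition}' requires annotation '{key}'")
        return float(annotations[key])

    if condition == "chronic":
        onset = need("drug_onset")
        return {"analysis": (onset + 25 * 60.0, onset + 30 * 60.0)}
    if condition == "acute":
        cno_on = need("cno_onset")
        washout = need("cno_washout")
        return {"baseline": (cno_on - 4 * 60.0, cno_on),
                "cno": (washout - 4 * 60.0, washout)}
    if condition == "light":
        on = need("light_on")
        off = need("light_off")
        dur = off - on
        return {"baseline": (on - 20.0, on),
                "light": (on, off),
                "post": (off, off + dur)}
    raise ValueError(f"unknown condition '{condition}'")


#: Root-choice convention: flexor (L2) roots for all locomotor parameters,
#: except lower-lumbar (L5/L6) optogenetic stimulation, analyzed on the
#: extensor (L5) roots.
_PROTOCOL_ROOT = {
    "chronic": "L2",
    "acute": "L2",
    "broad_light": "L2",
    "local_L1L2": "L2",
    "local_L5L6": "L5",
}


def choose_analysis_root(protocol: str) -> str:
    try:
        return _PROTOCOL_ROOT[protocol]
    except KeyError:
        raise ValueError(
            f"unknown protocol '{protocol}'; known: {sorted(_PROTOCOL_ROOT)}") from None


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def events_to_frame(events: Sequence[BurstEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "onset_s": ev.onset, "offset_s": ev.offset, "peak_time_s": ev.peak_time,
        "peak_amp": ev.peak_amp, "valley_amp": ev.valley_amp,
    } for ev in events])


def params_to_row(params: LocomotorParams, **extra) -> Dict[str, object]:
    row: Dict[str, object] = {
        "frequency_hz": params.frequency,
        "burst_duration_s": params.burst_duration,
        "cycle_period_s": params.cycle_period,
        "duty_cycle": params.duty_cycle,
        "amplitude": params.amplitude,
        "n_bursts": params.n_bursts,
        "window_start_s": params.window[0],
        "window_end_s": params.window[1],
    }
    for name, value in params.cv.items():
        row[f"cv_{name}"] = value
    row.update(extra)
    return row
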