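"""Synthetic fictive-locomotion recordings and calcium movies with known ground truth.

The generators emulate the experimental conditions the analysis modules must
handle: drug-induced rhythmic ventral-root bursting at 0.1-0.5 Hz with
controllable duty cycle and amplitude, left-right and flexor-extensor phase
offsets, dose-dependent frequency steps (different NMDA concentrations),
slow minutes-scale frequency decline mimicking chemogenetic (CNO) silencing,
short light epochs with elevated frequency mimicking optogenetic activation,
and 10 frame/s calcium movies with spatially clustered left-right anti-phase
oscillators convolved with an indicator-decay kernel.

Bursts are rendered directly as smooth rectified envelopes (raised-cosine
onset/offset with a flat middle) rather than as raw extracellular waveforms,
because all downstream analyses operate on rectified envelopes.  Additive
Gaussian noise models residual fluctuation on the envelope.  Every generator
takes a required seed and is bit-reproducible: identical seed and parameters
yield identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import ROLES, CalciumMovie, Recording

#: Phase offsets (degrees, relative to the left L2 reference) realizing the
#: alternating gait the drug-induced rhythm shows: left-right alternation on
#: both segments and ipsilateral flexor-extensor alternation.
ALTERNATING_OFFSETS_DEG: Dict[str, float] = {
    "lL2": 0.0,
    "rL2": 180.0,
    "lL5": 180.0,
    "rL5": 0.0,
}

#: Fraction of each burst spent in the raised-cosine rise (and again in the
#: fall); the remaining half of the burst is a flat plateau.
RAMP_FRACTION = 0.25


@dataclass(frozen=True)
class Epoch:
    """One stationary stretch of programmed rhythm."""

    start: float
    end: float
    frequency: float
    duty: float
    amplitude: float = 1.0

    def validate(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"epoch end must exceed start, got ({self.start}, {self.end})")
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if not 0 < self.duty <= 1:
            raise ValueError(f"duty must be in (0, 1], got {self.duty}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass
class SynthSchedule:
    """Programmed conditions for a synthetic ventral-root recording.

    ``epochs`` must be ordered and non-overlapping.  ``channel_phase_offsets``
    give each channel's burst-onset shift in degrees of the locomotor cycle
    relative to the left-L2 reference.  ``duration`` defaults to the last
    epoch's end.
    """

    epochs: List[Epoch]
    channel_phase_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(ALTERNATING_OFFSETS_DEG))
    noise_sd: float = 0.0
    fs: float = 1000.0
    seed: int = 0
    duration: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("epochs must not be empty")
        for ep in self.epochs:
            ep.validate()
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"epochs must be ordered and non-overlapping, got {a} then {b}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        unknown = set(self.channel_phase_offsets) - set(ROLES)
        if unknown:
            raise ValueError(f"channel_phase_offsets has unknown roles: {sorted(unknown)}")
        if self.duration is None:
            self.duration = max(ep.end for ep in self.epochs)
        elif self.duration < max(ep.end for ep in self.epochs):
            raise ValueError("duration must cover all epochs")


@dataclass(frozen=True)
class Oscillator:
    """A rectangular rhythmic source in a calcium movie (raw-pixel footprint)."""

    row0: int
    row1: int
    col0: int
    col1: int
    side: str            # "left" or "right" hemicord
    phase: float         # burst-onset phase in cycle fractions, [0, 1)
    amplitude: float = 1.0

    def validate(self, shape: Tuple[int, int]) -> None:
        H, W = shape
        if not (0 <= self.row0 < self.row1 <= H and 0 <= self.col0 < self.col1 <= W):
            raise ValueError(f"oscillator footprint {self} outside frame of shape {shape}")
        if self.side not in ("left", "right"):
            raise ValueError(f"oscillator side must be 'left' or 'right', got {self.side}")
        if not 0 <= self.phase < 1:
            raise ValueError(f"oscillator phase must be in [0, 1), got {self.phase}")


@dataclass
class SynthGroundTruth:
    """Everything a generator programmed, for recovery testing.

    ``bursts`` maps each channel role to an (n, 2) array of (onset, offset)
    times in seconds.  Movie generators fill the oscillator fields instead.
    """

    epochs: List[Epoch] = field(default_factory=list)
    bursts: Dict[str, np.ndarray] = field(default_factory=dict)
    channel_phase_offsets: Dict[str, float] = field(default_factory=dict)
    plateau_hz: Optional[Tuple[float, float]] = None
    light_windows: Optional[List[Tuple[float, float]]] = None
    oscillators: Optional[List[Oscillator]] = None
    decay_tau: Optional[float] = None
    movie_frequency: Optional[float] = None


# ---------------------------------------------------------------------------
# envelope rendering
# ---------------------------------------------------------------------------

def _render_envelope(n: int, fs: float, bursts: Sequence[Tuple[float, float]],
                     amplitudes: Sequence[float]) -> np.ndarray:
    """Render a burst train as a smooth non-negative envelope.

    Each burst rises over a raised-cosine ramp of RAMP_FRACTION of its
    duration, holds a flat plateau at its programmed amplitude, and falls
    symmetrically.
    """
    env = np.zeros(n)
    for (onset, offset), amp in zip(bursts, amplitudes):
        i0 = max(0, int(round(onset * fs)))
        i1 = min(n, int(round(offset * fs)))
        if i1 <= i0:
            continue
        t = (np.arange(i0, i1) / fs) - onset
        dur = offset - onset
        ramp = RAMP_FRACTION * dur
        w = np.ones(i1 - i0)
        rising = t < ramp
        w[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / ramp))
        falling = t > dur - ramp
        w[falling] = 0.5 * (1.0 - np.cos(np.pi * (dur - t[falling]) / ramp))
        env[i0:i1] = np.maximum(env[i0:i1], amp * w)
    return env


def _epoch_bursts(ep: Epoch, shift_s: float) -> List[Tuple[float, float]]:
    """Burst (onset, offset) times for one epoch, onsets shifted by ``shift_s``.

    Bursts belong to the epoch if their onset lies inside [start, end)."""
    T = 1.0 / ep.frequency
    out = []
    k = 0
    while True:
        onset = ep.start + shift_s + k * T
        if onset >= ep.end - 1e-12:
            break
        out.append((onset, onset + ep.duty * T))
        k += 1
    return out


# ---------------------------------------------------------------------------
# ventral-root generators
# ---------------------------------------------------------------------------

def generate_ventral_root(schedule: SynthSchedule) -> Tuple[Recording, SynthGroundTruth]:
    """Render a four-channel ventral-root recording from a schedule.

    Returns the recording and a ground truth listing every programmed burst
    per channel.  Identical schedules (including seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(schedule.seed)
    n = int(round(schedule.fs * schedule.duration))
    truth = SynthGroundTruth(
        epochs=list(schedule.epochs),
        channel_phase_offsets=dict(schedule.channel_phase_offsets),
    )
    channels: Dict[str, np.ndarray] = {}
    for role in ROLES:
        offset_deg = schedule.channel_phase_offsets.get(role, 0.0)
        bursts: List[Tuple[float, float]] = []
        amps: List[float] = []
        for ep in schedule.epochs:
            shift = (offset_deg % 360.0) / 360.0 / ep.frequency
            eb = _epoch_bursts(ep, shift)
            bursts.extend(eb)
            amps.extend([ep.amplitude] * len(eb))
        env = _render_envelope(n, schedule.fs, bursts, amps)
        if schedule.noise_sd > 0:
            env = env + rng.normal(0.0, schedule.noise_sd, n)
        channels[role] = env
        clipped = np.array([(on, min(off, schedule.duration)) for on, off in bursts],
                           dtype=float).reshape(-1, 2)
        truth.bursts[role] = clipped
    rec = Recording(fs=schedule.fs, channels=channels)
    return rec, truth


def generate_dose_series(frequencies: Sequence[float], base_schedule: SynthSchedule,
                         ) -> List[Tuple[Recording, SynthGroundTruth]]:
    """One recording per programmed frequency, other parameters shared.

    Emulates locomotor episodes at the different NMDA concentrations, which
    set distinct stable frequencies.  Recording *i* uses seed
    ``base_schedule.seed + i`` so the dose points carry independent noise.
    """
    if len(frequencies) == 0:
        raise ValueError("frequencies must not be empty")
    out = []
    for i, f in enumerate(frequencies):
        if f <= 0:
            raise ValueError(f"frequency must be > 0, got {f}")
        epochs = [replace(ep, frequency=f) for ep in base_schedule.epochs]
        sched = SynthSchedule(
            epochs=epochs,
            channel_phase_offsets=dict(base_schedule.channel_phase_offsets),
            noise_sd=base_schedule.noise_sd,
            fs=base_schedule.fs,
            seed=base_schedule.seed + i,
            duration=base_schedule.duration,
        )
        out.append(generate_ventral_root(sched))
    return out


def generate_cno_timecourse(baseline_hz: float, percent_change: float, onset_s: float,
                            ramp_s: float, total_s: float, *, duty: float = 0.3,
                            amplitude: float = 1.0, noise_sd: float = 0.0,
                            fs: float = 1000.0, seed: int = 0,
                            channel_phase_offsets: Optional[Mapping[str, float]] = None,
                            ) -> Tuple[Recording, SynthGroundTruth]:
    """Recording whose burst rate ramps linearly to a new plateau.

    The instantaneous rate holds ``baseline_hz`` until ``onset_s``, moves
    linearly over ``ramp_s`` to ``baseline_hz * (1 + percent_change / 100)``,
    then holds that plateau until ``total_s``.  Emulates the slow frequency
    decline during CNO-mediated chemogenetic silencing.
    """
    if percent_change <= -100:
        raise ValueError(f"percent_change must be > -100, got {percent_change}")
    if baseline_hz <= 0:
        raise ValueError(f"baseline_hz must be > 0, got {baseline_hz}")
    if total_s <= onset_s + ramp_s:
        raise ValueError("total_s must exceed onset_s + ramp_s")
    if ramp_s < 0 or onset_s < 0:
        raise ValueError("onset_s and ramp_s must be >= 0")
    offsets = dict(ALTERNATING_OFFSETS_DEG if channel_phase_offsets is None
                   else channel_phase_offsets)
    plateau_hz = baseline_hz * (1.0 + percent_change / 100.0)

    def rate(t: np.ndarray) -> np.ndarray:
        r = np.full_like(t, baseline_hz, dtype=float)
        if ramp_s > 0:
            in_ramp = (t >= onset_s) & (t < onset_s + ramp_s)
            r[in_ramp] = baseline_hz + (plateau_hz - baseline_hz) * (t[in_ramp] - onset_s) / ramp_s
        r[t >= onset_s + ramp_s] = plateau_hz
        return r

    # Burst onsets are where the integrated instantaneous rate crosses
    # successive integers (a rate-1 phase oscillator read out at each cycle).
    dt = 1e-3
    tgrid = np.arange(0.0, total_s, dt)
    phase = np.concatenate(([0.0], np.cumsum(rate(tgrid)) * dt))
    tgrid = np.append(tgrid, total_s)
    n_cycles = int(math.floor(phase[-1]))
    ref_onsets = np.interp(np.arange(n_cycles), phase, tgrid)

    rng = np.random.default_rng(seed)
    n = int(round(fs * total_s))
    truth = SynthGroundTruth(channel_phase_offsets=offsets,
                             plateau_hz=(baseline_hz, plateau_hz))
    channels: Dict[str, np.ndarray] = {}
    local_period = 1.0 / rate(ref_onsets)
    for role in ROLES:
        frac = (offsets.get(role, 0.0) % 360.0) / 360.0
        onsets = ref_onsets + frac * local_period
        offs = onsets + duty * local_period
        keep = onsets < total_s
        bursts = list(zip(onsets[keep], offs[keep]))
        env = _render_envelope(n, fs, bursts, [amplitude] * len(bursts))
        if noise_sd > 0:
            env = env + rng.normal(0.0, noise_sd, n)
        channels[role] = env
        truth.bursts[role] = np.array(
            [(on, min(off, total_s)) for on, off in bursts], dtype=float).reshape(-1, 2)
    rec = Recording(fs=fs, channels=channels,
                    annotations={"cno_onset": onset_s, "cno_washout": total_s})
    return rec, truth


def generate_light_epoch(baseline_hz: float, light_hz: float, light_window_s: float,
                         *, light_onsets_s: Sequence[float], total_s: float,
                         duty: float = 0.3, amplitude: float = 1.0,
                         noise_sd: float = 0.0, fs: float = 1000.0, seed: int = 0,
                         channel_phase_offsets: Optional[Mapping[str, float]] = None,
                         ) -> Tuple[Recording, SynthGroundTruth]:
    """Recording whose frequency steps to ``light_hz`` during light epochs.

    ``baseline_hz`` may be 0 (non-rhythmic baseline), in which case bursts
    occur only inside the light windows.  Windows must fit in the recording
    and must not overlap.
    """
    if light_hz < 0 or baseline_hz < 0:
        raise ValueError("frequencies must be >= 0")
    if light_window_s <= 0:
        raise ValueError(f"light_window_s must be > 0, got {light_window_s}")
    onsets = sorted(light_onsets_s)
    if not onsets:
        raise ValueError("light_onsets_s must not be empty")
    windows = [(o, o + light_window_s) for o in onsets]
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping light epochs: {(a0, a1)} and {(b0, b1)}")
    if windows[0][0] < 0 or windows[-1][1] > total_s:
        raise ValueError("light epochs must fit inside the recording")
    offsets = dict(ALTERNATING_OFFSETS_DEG if channel_phase_offsets is None
                   else channel_phase_offsets)

    # Build stationary segments: baseline / light / baseline / ...
    segments: List[Epoch] = []
    cursor = 0.0
    for w0, w1 in windows:
        if w0 > cursor and baseline_hz > 0:
            segments.append(Epoch(cursor, w0, baseline_hz, duty, amplitude))
        if light_hz > 0:
            segments.append(Epoch(w0, w1, light_hz, duty, amplitude))
        cursor = w1
    if total_s > cursor and baseline_hz > 0:
        segments.append(Epoch(cursor, total_s, baseline_hz, duty, amplitude))

    rng = np.random.default_rng(seed)
    n = int(round(fs * total_s))
    truth = SynthGroundTruth(epochs=segments, channel_phase_offsets=offsets,
                             light_windows=windows)
    channels: Dict[str, np.ndarray] = {}
    for role in ROLES:
        offset_deg = offsets.get(role, 0.0)
        bursts: List[Tuple[float, float]] = []
        amps: List[float] = []
        for ep in segments:
            shift = (offset_deg % 360.0) / 360.0 / ep.frequency
            eb = _epoch_bursts(ep, shift)
            bursts.extend(eb)
            amps.extend([ep.amplitude] * len(eb))
        env = _render_envelope(n, fs, bursts, amps)
        if noise_sd > 0:
            env = env + rng.normal(0.0, noise_sd, n)
        channels[role] = env
        truth.bursts[role] = np.array(
            [(on, min(off, total_s)) for on, off in bursts], dtype=float).reshape(-1, 2)
    ann = {"light_on": windows[0][0], "light_off": windows[0][1]}
    rec = Recording(fs=fs, channels=channels, annotations=ann)
    return rec, truth


# ---------------------------------------------------------------------------
# calcium movies
# ---------------------------------------------------------------------------

def default_landmarks(shape: Tuple[int, int]) -> Dict[str, float]:
    """Landmarks for a raw synthetic field: edges inset by two pixels, central
    canal slightly off the geometric midline (so the two hemifields need
    different scale factors, as real sections do)."""
    H, W = shape
    left, right = 2, W - 3
    dorsal, ventral = 2, H - 3
    return {
        "cc_row": dorsal + 0.45 * (ventral - dorsal),
        "cc_col": left + 0.55 * (right - left),
        "left_col": float(left),
        "right_col": float(right),
        "dorsal_row": float(dorsal),
        "ventral_row": float(ventral),
    }


def default_oscillators(landmarks: Mapping[str, float], lr_phase_offset: float,
                        amplitude: float = 1.0) -> List[Oscillator]:
    """Two rhythmic sources per hemicord in the dorsolateral intermediate
    zone (where the rhythmic cell bodies sit), left side at phase 0 and right
    side offset by ``lr_phase_offset`` cycles."""
    d, v = landmarks["dorsal_row"], landmarks["ventral_row"]
    l, r, cc = landmarks["left_col"], landmarks["right_col"], landmarks["cc_col"]
    rows = (d + 0.30 * (v - d), d + 0.45 * (v - d))
    rows2 = (d + 0.50 * (v - d), d + 0.60 * (v - d))
    out = []
    for side in ("left", "right"):
        phase = 0.0 if side == "left" else lr_phase_offset % 1.0
        if side == "left":
            cols = (l + 0.15 * (cc - l), l + 0.40 * (cc - l))
            cols2 = (l + 0.45 * (cc - l), l + 0.65 * (cc - l))
        else:
            cols = (cc + 0.60 * (r - cc), cc + 0.85 * (r - cc))
            cols2 = (cc + 0.35 * (r - cc), cc + 0.55 * (r - cc))
        out.append(Oscillator(int(rows[0]), int(rows[1]), int(cols[0]), int(cols[1]),
                              side, phase, amplitude))
        out.append(Oscillator(int(rows2[0]), int(rows2[1]), int(cols2[0]), int(cols2[1]),
                              side, phase, 0.7 * amplitude))
    return out


def oscillator_drive(n_frames: int, fs: float, frequency: float, phase: float,
                     decay_tau: float, duty: float = 0.3) -> np.ndarray:
    """Periodic burst drive convolved with a single-exponential indicator
    kernel; returned with unit peak."""
    duration = n_frames / fs
    shift = (phase % 1.0) / frequency
    ep = Epoch(0.0, duration, frequency, duty, 1.0)
    bursts = _epoch_bursts(ep, shift)
    drive = _render_envelope(n_frames, fs, bursts, [1.0] * len(bursts))
    t_k = np.arange(0, max(5.0 * decay_tau, 1.0 / fs), 1.0 / fs)
    kernel = np.exp(-t_k / decay_tau)
    kernel /= kernel.sum()
    trace = np.convolve(drive, kernel)[:n_frames]
    peak = trace.max()
    if peak > 0:
        trace = trace / peak
    return trace


def generate_calcium_movie(*, frequency: float = 0.4, duration_s: float = 180.0,
                           fs: float = 10.0, shape: Tuple[int, int] = (200, 250),
                           oscillators: Optional[Sequence[Oscillator]] = None,
                           lr_phase_offset: float = 0.5, duty: float = 0.3,
                           decay_tau: float = 0.4, noise_sd: float = 0.0,
                           background: float = 100.0, amplitude: float = 50.0,
                           seed: int = 0,
                           landmarks: Optional[Mapping[str, float]] = None,
                           ) -> Tuple[CalciumMovie, SynthGroundTruth]:
    """Synthetic calcium movie with left/right phase-offset oscillators.

    Each oscillator emits a periodic raised-cosine burst drive at
    ``frequency`` Hz, convolved with a single-exponential indicator kernel of
    time constant ``decay_tau`` seconds, scaled by ``amplitude`` on top of a
    constant ``background``, plus optional Gaussian noise.  Right-hemifield
    oscillators are offset from the left by ``lr_phase_offset`` cycles.
    Landmark annotations are included so the movie can be normalized.
    """
    n_frames_f = duration_s * fs
    if abs(n_frames_f - round(n_frames_f)) > 1e-9:
        raise ValueError(f"duration_s * fs must be an integer, got {n_frames_f}")
    n_frames = int(round(n_frames_f))
    H, W = shape
    lms = dict(default_landmarks(shape) if landmarks is None else landmarks)
    if oscillators is None:
        oscillators = default_oscillators(lms, lr_phase_offset, amplitude=1.0)
    for osc in oscillators:
        osc.validate(shape)
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    if decay_tau <= 0:
        raise ValueError(f"decay_tau must be > 0, got {decay_tau}")

    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, H, W), background, dtype=np.float32)
    for osc in oscillators:
        trace = oscillator_drive(n_frames, fs, frequency, osc.phase, decay_tau, duty)
        patch = (amplitude * osc.amplitude) * trace.astype(np.float32)
        frames[:, osc.row0:osc.row1, osc.col0:osc.col1] += patch[:, None, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)

    movie = CalciumMovie(frames=frames, fs=fs, landmarks=lms, normalized=False)
    truth = SynthGroundTruth(
        oscillators=list(oscillators),
        decay_tau=decay_tau,
        movie_frequency=frequency,
    )
    return movie, truth
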