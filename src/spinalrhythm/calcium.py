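"""Grid-ROI calcium-imaging pipeline: field normalization, dF extraction,
oscillation-index maps and cross-correlation phase maps.

Pipeline stages, in order:

1. :func:`normalize_field` resamples the imaged transverse section so the
   four cord edges meet the field border and the central canal sits on the
   vertical midline of a fixed 400-row x 500-column field (each hemifield is
   scaled independently).
2. :func:`build_grid` tiles the normalized field into 500 rectangular ROIs,
   250 per hemifield.
3. :func:`extract_delta_f` converts each ROI's mean intensity to
   dF = F_t - F0, with F0 the mean of the last 100 frames, and normalizes
   all traces by the single maximum dF over all ROIs.
4. :func:`preprocess_traces` applies a zero-phase low-pass filter and a slow
   rolling-percentile baseline adjustment.
5. :func:`oscillation_index` measures rhythmicity as the peak-minus-trough
   span of the normalized autocorrelation (0 for noise, up to 2 for a
   perfect oscillation); :func:`normalize_index_map` and
   :func:`average_maps_and_reference` turn per-ROI indices into maps and
   pick the reference ROI.
6. :func:`phase_map` and :func:`root_phase_comparison` express each ROI's
   cross-correlation lag against the reference ROI (or a ventral-root burst
   train) in locomotor-cycle units, where 0.5 is strict alternation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.ndimage import percentile_filter

from .bursts import BurstEvent
from .core import CalciumMovie

logger = logging.getLogger(__name__)

#: Normalized field geometry: 400 rows x 500 columns, canal at column 249.5.
FIELD_SHAPE = (400, 500)
N_ROIS = 500
#: Tile geometry per hemifield: 10 tile columns x 25 tile rows of 25 x 16 px.
TILE_W, TILE_H = 25, 16
TILES_X, TILES_Y = 10, 25


# ---------------------------------------------------------------------------
# field normalization
# ---------------------------------------------------------------------------

def _interp_indices(src: np.ndarray, size_in: int,
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbour indices and fractional weight for 1-D linear interpolation."""
    x0 = np.clip(np.floor(src).astype(int), 0, size_in - 1)
    x1 = np.clip(x0 + 1, 0, size_in - 1)
    w = np.clip(src - x0, 0.0, 1.0).astype(np.float32)
    return x0, x1, w


def normalize_field(movie: CalciumMovie) -> CalciumMovie:
    """Resample a movie onto the canonical 400 x 500 field.

    The left cord edge maps to column 0, the right edge to column 499, the
    dorsal edge to row 0, the ventral edge to row 399 and the central canal
    to the column boundary 249.5; the two hemifields are scaled
    independently so the canal lands on the midline.  Intensities are
    interpolated bilinearly.
    """
    lm = movie.landmarks
    left, right = lm["left_col"], lm["right_col"]
    dorsal, ventral = lm["dorsal_row"], lm["ventral_row"]
    cc = lm["cc_col"]
    if not left < cc < right:
        raise ValueError("degenerate landmarks: central canal must lie strictly "
                         "between the left and right edges")
    if not dorsal < ventral:
        raise ValueError("degenerate landmarks: dorsal edge must be above ventral edge")

    H_out, W_out = FIELD_SHAPE
    half = W_out // 2
    c = np.arange(W_out, dtype=float)
    src_x = np.empty(W_out)
    # column 0 -> left edge, column (half - 0.5) -> canal, column W-1 -> right edge
    src_x[:half] = left + c[:half] * (cc - left) / (half - 0.5)
    src_x[half:] = cc + (c[half:] - (half - 0.5)) * (right - cc) / (half - 0.5)
    src_y = dorsal + np.arange(H_out) * (ventral - dorsal) / (H_out - 1)

    frames = np.asarray(movie.frames, dtype=np.float32)
    T, H_in, W_in = frames.shape
    x0, x1, wx = _interp_indices(src_x, W_in)
    y0, y1, wy = _interp_indices(src_y, H_in)
    # rows first (smaller intermediate), then columns chunked over frames to
    # keep temporaries cache-sized
    rows = frames[:, y0, :] * (1.0 - wy)[None, :, None]
    rows += frames[:, y1, :] * wy[None, :, None]      # (T, 400, W_in)
    out = np.empty((T, H_out, W_out), dtype=np.float32)
    step = max(1, int(2e7 // (H_out * W_out)))
    for s in range(0, T, step):
        blk = rows[s:s + step]
        tmp = np.take(blk, x0, axis=-1)
        tmp *= (1.0 - wx)
        tmp2 = np.take(blk, x1, axis=-1)
        tmp2 *= wx
        tmp += tmp2
        out[s:s + step] = tmp

    new_landmarks = {
        "cc_row": (lm["cc_row"] - dorsal) * (H_out - 1) / (ventral - dorsal),
        "cc_col": half - 0.5,
        "left_col": 0.0,
        "right_col": float(W_out - 1),
        "dorsal_row": 0.0,
        "ventral_row": float(H_out - 1),
    }
    return CalciumMovie(frames=out, fs=movie.fs, landmarks=new_landmarks,
                        normalized=True)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIGrid:
    """500 rectangular footprints tiling the normalized field.

    ``footprints[i]`` is (row0, row1, col0, col1), half-open, for ROI id
    ``ids[i]``.  Ids 1-250 tile the right hemifield (columns 250-499), ids
    251-500 the left hemifield (columns 0-249); within each hemifield the
    raster runs lateral to medial, then dorsal to ventral.
    """

    footprints: np.ndarray   # (500, 4) int
    ids: np.ndarray          # (500,) int, 1..500
    sides: np.ndarray        # (500,) '<U5', "right" or "left"

    def footprint(self, roi_id: int) -> Tuple[int, int, int, int]:
        idx = int(np.flatnonzero(self.ids == roi_id)[0])
        return tuple(self.footprints[idx])


def build_grid(shape: Tuple[int, int] = FIELD_SHAPE) -> ROIGrid:
    """Tile a normalized 400 x 500 field into the canonical 500-ROI grid."""
    if tuple(shape) != FIELD_SHAPE:
        raise ValueError(f"grid requires a normalized {FIELD_SHAPE} field, got {shape}")
    footprints = np.zeros((N_ROIS, 4), dtype=int)
    ids = np.zeros(N_ROIS, dtype=int)
    sides = np.empty(N_ROIS, dtype="<U5")
    idx = 0
    for side, base_id in (("right", 1), ("left", 251)):
        for i in range(TILES_Y):            # dorsal -> ventral
            for j in range(TILES_X):        # lateral -> medial
                if side == "right":
                    col0 = 500 - TILE_W * (j + 1)
                else:
                    col0 = TILE_W * j
                row0 = TILE_H * i
                footprints[idx] = (row0, row0 + TILE_H, col0, col0 + TILE_W)
                ids[idx] = base_id + i * TILES_X + j
                sides[idx] = side
                idx += 1
    return ROIGrid(footprints=footprints, ids=ids, sides=sides)


# ---------------------------------------------------------------------------
# dF extraction and preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ROITraceSet:
    """Per-ROI dF traces (n_roi x T), plus the baseline and normalization
    bookkeeping."""

    traces: np.ndarray
    fs: float
    grid: ROIGrid
    f0: np.ndarray
    global_max: float
    normalized: bool
    filtered: bool = False

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def trace(self, roi_id: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.grid.ids == roi_id)[0])
        return self.traces[idx]


def extract_delta_f(movie: CalciumMovie, grid: ROIGrid,
                    n_baseline_frames: int = 100) -> ROITraceSet:
    """dF = F_t - F0 per ROI, normalized by the global maximum dF.

    F_t is the mean intensity over the ROI footprint; F0 is the mean of F_t
    over the last ``n_baseline_frames`` frames.  All traces share one
    divisor, the maximum dF over all ROIs and frames; if that maximum is not
    positive the traces are returned unnormalized and flagged.
    """
    T = movie.n_frames
    if T <= n_baseline_frames:
        raise ValueError(
            f"movie has {T} frames; needs more than n_baseline_frames = {n_baseline_frames}")
    frames = movie.frames
    raw = np.empty((N_ROIS, T), dtype=float)
    fp = grid.footprints
    canonical = (frames.shape[1:] == FIELD_SHAPE
                 and np.all(fp[:, 1] - fp[:, 0] == TILE_H)
                 and np.all(fp[:, 3] - fp[:, 2] == TILE_W)
                 and np.all(fp[:, 0] % TILE_H == 0) and np.all(fp[:, 2] % TILE_W == 0))
    if canonical:
        # one pass over the stack: tile means via reshape, then gather per ROI
        tiles = frames.reshape(T, FIELD_SHAPE[0] // TILE_H, TILE_H,
                               FIELD_SHAPE[1] // TILE_W, TILE_W).mean(axis=(2, 4))
        raw[:] = tiles[:, fp[:, 0] // TILE_H, fp[:, 2] // TILE_W].T
    else:
        for i, (r0, r1, c0, c1) in enumerate(fp):
            raw[i] = frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    f0 = raw[:, -n_baseline_frames:].mean(axis=1)
    df = raw - f0[:, None]
    gmax = float(df.max())
    if gmax > 0:
        return ROITraceSet(traces=df / gmax, fs=movie.fs, grid=grid, f0=f0,
                           global_max=gmax, normalized=True)
    logger.warning("global max dF <= 0; traces returned unnormalized")
    return ROITraceSet(traces=df, fs=movie.fs, grid=grid, f0=f0,
                       global_max=gmax, normalized=False)


def preprocess_traces(ts: ROITraceSet, lowpass_hz: float = 2.0,
                      baseline_window_s: float = 20.0,
                      baseline_percentile: float = 10.0) -> ROITraceSet:
    """Zero-phase low-pass filter then slow-baseline subtraction.

    The low-pass is a 4th-order Butterworth applied forward-backward; the
    baseline is a rolling percentile (default 10th over 20 s), subtracted
    along with any residual mean so the output is zero-centred.
    """
    nyquist = ts.fs / 2.0
    if lowpass_hz >= nyquist:
        raise ValueError(f"lowpass_hz must be < Nyquist ({nyquist} Hz), got {lowpass_hz}")
    sos = signal.butter(4, lowpass_hz, btype="low", fs=ts.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.traces, axis=1)
    win = max(1, int(round(baseline_window_s * ts.fs)))
    baseline = percentile_filter(filtered, baseline_percentile, size=(1, win),
                                 mode="nearest")
    out = filtered - baseline
    out -= out.mean(axis=1, keepdims=True)
    return ROITraceSet(traces=out, fs=ts.fs, grid=ts.grid, f0=ts.f0,
                       global_max=ts.global_max, normalized=ts.normalized,
                       filtered=True)


# ---------------------------------------------------------------------------
# oscillation index
# ---------------------------------------------------------------------------

def autocorrelation(trace: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation r(k) for k = 0..max_lag, normalized so r(0) = 1 and
    so a pure periodic signal attains ~1 again at one-period lag (the lag-k
    product sum is divided by the number of overlapping samples)."""
    x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    n = x.size
    denom = float(np.dot(x, x)) / n
    if denom <= 0:
        return np.zeros(max_lag + 1)
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = (np.dot(x[:-k], x[k:]) / (n - k)) / denom
    return r


def oscillation_index(trace: np.ndarray, fs: float, expected_period: float,
                      ) -> float:
    """Peak-minus-trough span of the normalized autocorrelation.

    The first side peak is sought at lags between 0.5x and 2x the expected
    locomotor period (taken from the concurrent root rhythm); the trough is
    the autocorrelation minimum between zero lag and that peak.  A perfectly
    periodic trace scores ~2 (peak +1, trough -1); white noise scores ~0.
    Returns 0 when no side peak exists in the search range.
    """
    x = np.asarray(trace, dtype=float)
    if expected_period <= 0:
        raise ValueError(f"expected_period must be > 0, got {expected_period}")
    if x.size / fs < 10 * expected_period:
        raise ValueError("trace must span at least 10 expected cycles")
    lo = max(1, int(round(0.5 * expected_period * fs)))
    hi = min(x.size - 2, int(round(2.0 * expected_period * fs)))
    if hi <= lo:
        return 0.0
    r = autocorrelation(x, hi)
    if not np.any(r):
        return 0.0
    peak_lag = lo + int(np.argmax(r[lo:hi + 1]))
    trough = float(r[1:peak_lag + 1].min())
    index = float(r[peak_lag]) - trough
    return max(index, 0.0)


@dataclass
class OscillationMap:
    """Per-ROI oscillation indices, raw and normalized by the single maximum
    over all 500 ROIs (one divisor for both hemifields)."""

    raw: np.ndarray
    normalized_values: np.ndarray
    grid: ROIGrid
    all_zero: bool = False
    reference_roi: Optional[int] = None


def oscillation_map(ts: ROITraceSet, expected_period: float) -> np.ndarray:
    """Raw oscillation index for each of the 500 ROI traces."""
    if not ts.filtered:
        logger.warning("oscillation_map on unfiltered traces; run preprocess_traces first")
    return np.array([oscillation_index(tr, ts.fs, expected_period)
                     for tr in ts.traces])


def normalize_index_map(raw: np.ndarray, grid: ROIGrid) -> OscillationMap:
    """Divide every ROI's index by the single maximum over all 500 ROIs."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (N_ROIS,):
        raise ValueError(f"expected {N_ROIS} raw indices, got shape {raw.shape}")
    m = raw.max()
    if m <= 0:
        logger.warning("all-zero oscillation map")
        return OscillationMap(raw=raw, normalized_values=np.zeros_like(raw),
                              grid=grid, all_zero=True)
    return OscillationMap(raw=raw, normalized_values=raw / m, grid=grid)


def average_maps_and_reference(maps: Sequence[OscillationMap],
                               ) -> Tuple[OscillationMap, int]:
    """Element-wise mean of normalized maps; the reference ROI is the argmax
    of the averaged map (ties broken toward the lowest ROI id, logged)."""
    if not maps:
        raise ValueError("need at least one map")
    grid = maps[0].grid
    for m in maps[1:]:
        if not np.array_equal(m.grid.footprints, grid.footprints):
            raise ValueError("all maps must share the same grid")
    mean_norm = np.mean([m.normalized_values for m in maps], axis=0)
    mean_raw = np.mean([m.raw for m in maps], axis=0)
    best = mean_norm.max()
    tied = np.flatnonzero(mean_norm == best)
    if len(tied) > 1:
        logger.info("reference ROI tie among ids %s; taking the lowest",
                    grid.ids[tied].tolist())
    ref_id = int(grid.ids[tied].min())
    avg = OscillationMap(raw=mean_raw, normalized_values=mean_norm, grid=grid,
                         all_zero=bool(best <= 0), reference_roi=ref_id)
    return avg, ref_id


# ---------------------------------------------------------------------------
# phase maps
# ---------------------------------------------------------------------------

@dataclass
class PhaseMap:
    """Per-ROI phase relative to the reference, in locomotor-cycle units
    [0, 1); NaN where the ROI trace is flat.  Positive phase means the ROI
    lags the reference."""

    phases: np.ndarray
    cycle_period: float
    reference_roi: int
    grid: ROIGrid


def _xcorr_lag(x: np.ndarray, ref: np.ndarray, fs: float, max_lag_s: float,
               ) -> Optional[float]:
    """Lag (seconds) of the cross-correlation maximum of ``x`` against
    ``ref`` within +-max_lag_s, with 3-point parabolic refinement.  Positive
    lag means ``x`` is delayed relative to ``ref``.  None for a flat trace."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    ref = np.asarray(ref, dtype=float) - np.mean(ref)
    if np.ptp(x) == 0 or np.ptp(ref) == 0:
        return None
    c = signal.correlate(x, ref, mode="full")
    lags = signal.correlation_lags(len(x), len(ref), mode="full")
    max_k = int(round(max_lag_s * fs))
    window = (lags >= -max_k) & (lags <= max_k)
    cw = c[window]
    lw = lags[window]
    i = int(np.argmax(cw))
    lag = float(lw[i])
    if 0 < i < len(cw) - 1:
        y0, y1, y2 = cw[i - 1], cw[i], cw[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag += 0.5 * float((y0 - y2) / denom)
    return lag / fs


def phase_map(ts: ROITraceSet, reference_roi: int, cycle_period: float) -> PhaseMap:
    """Cross-correlation phase of every ROI against the reference ROI.

    The lag of the cross-correlation maximum within +-half the locomotor
    cycle period, divided by the period and mapped to [0, 1).  The reference
    ROI's phase is exactly 0; flat traces give NaN.
    """
    if cycle_period <= 0:
        raise ValueError(f"cycle_period must be > 0, got {cycle_period}")
    ref = ts.trace(reference_roi)
    if np.ptp(ref) == 0:
        raise ValueError("reference ROI trace is flat")
    phases = np.full(len(ts.traces), np.nan)
    for i, tr in enumerate(ts.traces):
        lag = _xcorr_lag(tr, ref, ts.fs, cycle_period / 2.0)
        if lag is not None:
            phases[i] = (lag / cycle_period) % 1.0
    ref_idx = int(np.flatnonzero(ts.grid.ids == reference_roi)[0])
    phases[ref_idx] = 0.0
    return PhaseMap(phases=phases, cycle_period=cycle_period,
                    reference_roi=reference_roi, grid=ts.grid)


def burst_indicator(events: Sequence[BurstEvent], n_samples: int, fs: float,
                    ) -> np.ndarray:
    """0/1 indicator of burst occupancy sampled on the movie's time base."""
    out = np.zeros(n_samples)
    for ev in events:
        i0 = max(0, int(round(ev.onset * fs)))
        i1 = min(n_samples, int(round(ev.offset * fs)))
        out[i0:i1] = 1.0
    return out


def root_phase_comparison(ts: ROITraceSet, root_events: Dict[str, Sequence[BurstEvent]],
                          cycle_period: float, lowpass_hz: float = 2.0,
                          ) -> Dict[str, np.ndarray]:
    """Per-ROI cross-correlation phase against ventral-root burst trains.

    ``root_events`` maps a label (e.g. ``ipsi``/``contra``) to that root's
    burst events; each train is rendered as a burst-occupancy indicator on
    the movie's time base, low-pass filtered like the traces, and used as
    the cross-correlation reference.  Phases are in cycle units in [0, 1).
    """
    if cycle_period <= 0:
        raise ValueError(f"cycle_period must be > 0, got {cycle_period}")
    n = ts.n_frames
    duration = n / ts.fs
    sos = signal.butter(4, min(lowpass_hz, 0.49 * ts.fs), btype="low", fs=ts.fs,
                        output="sos")
    out: Dict[str, np.ndarray] = {}
    for label, events in root_events.items():
        overlapping = [ev for ev in events if ev.onset < duration and ev.offset > 0]
        if not overlapping:
            raise ValueError(f"root '{label}' has no bursts overlapping the movie")
        ind = burst_indicator(overlapping, n, ts.fs)
        ind = signal.sosfiltfilt(sos, ind - ind.mean())
        phases = np.full(len(ts.traces), np.nan)
        for i, tr in enumerate(ts.traces):
            lag = _xcorr_lag(tr, ind, ts.fs, cycle_period / 2.0)
            if lag is not None:
                phases[i] = (lag / cycle_period) % 1.0
        out[label] = phases
    return out
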