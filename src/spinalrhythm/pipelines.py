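"""Convenience chains over the library building blocks.

These helpers wire the common paths — recording to burst events, root pair
to cycle phases, movie to oscillation/phase maps — so the analysis drivers,
tests and the reproduction script stay thin.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bursts import BurstEvent, detect_bursts, rectify_and_smooth
from .calcium import (OscillationMap, PhaseMap, ROITraceSet, average_maps_and_reference,
                      build_grid, extract_delta_f, normalize_field,
                      normalize_index_map, oscillation_map, phase_map,
                      preprocess_traces)
from .circular import PhaseSeries, extract_cycle_phases
from .core import CalciumMovie, Recording


def channel_events(rec: Recording, role: str, smooth_window_s: float = 0.1,
                   **detect_kwargs) -> List[BurstEvent]:
    """Rectify+smooth one channel and detect its bursts."""
    env = rectify_and_smooth(rec.channels[role], rec.fs, smooth_window_s)
    return detect_bursts(env, rec.fs, **detect_kwargs)


def pair_phases(rec: Recording, ref_role: str, test_role: str,
                smooth_window_s: float = 0.1, **detect_kwargs) -> PhaseSeries:
    """Cycle-by-cycle phases of ``test_role`` within ``ref_role`` cycles."""
    ref = channel_events(rec, ref_role, smooth_window_s, **detect_kwargs)
    test = channel_events(rec, test_role, smooth_window_s, **detect_kwargs)
    return extract_cycle_phases(ref, test, pair=(ref_role, test_role))


def movie_maps(movie: CalciumMovie, expected_period: float,
               lowpass_hz: float = 2.0,
               ) -> Tuple[ROITraceSet, OscillationMap, PhaseMap]:
    """Full single-preparation calcium pipeline.

    Normalizes the field, builds the 500-ROI grid, extracts and preprocesses
    dF traces, computes the oscillation map, picks the reference ROI from it
    and returns the phase map against that reference.
    """
    norm = movie if movie.normalized else normalize_field(movie)
    grid = build_grid(norm.frames.shape[1:])
    ts = extract_delta_f(norm, grid)
    ts = preprocess_traces(ts, lowpass_hz=lowpass_hz)
    raw = oscillation_map(ts, expected_period)
    omap = normalize_index_map(raw, grid)
    avg, ref_id = average_maps_and_reference([omap])
    pmap = phase_map(ts, ref_id, expected_period)
    return ts, avg, pmap
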