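"""Shared fixtures: synthetic recordings and movies reused across test modules.

Heavy artifacts (the movie pipeline) are session-scoped so they are built
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinalrhythm import calcium as ca
from spinalrhythm.pipelines import channel_events, movie_maps
from spinalrhythm.synth import (ALTERNATING_OFFSETS_DEG, Epoch, SynthSchedule,
                                generate_calcium_movie, generate_ventral_root)


@pytest.fixture(scope="session")
def alt_schedule() -> SynthSchedule:
    """Two minutes of noiseless alternating rhythm at 0.3 Hz."""
    return SynthSchedule(epochs=[Epoch(0.0, 120.0, 0.3, 0.3)], seed=11)


@pytest.fixture(scope="session")
def alt_recording(alt_schedule):
    return generate_ventral_root(alt_schedule)


@pytest.fixture(scope="session")
def alt_events(alt_recording):
    rec, _ = alt_recording
    return {role: channel_events(rec, role) for role in rec.channels}


@pytest.fixture(scope="session")
def small_movie():
    """One-minute anti-phase movie at 0.4 Hz with mild noise."""
    return generate_calcium_movie(frequency=0.4, duration_s=60.0, fs=10.0,
                                  shape=(120, 150), noise_sd=1.0, seed=3)


@pytest.fixture(scope="session")
def small_movie_maps(small_movie):
    movie, truth = small_movie
    ts, omap, pmap = movie_maps(movie, expected_period=1.0 / 0.4)
    return movie, truth, ts, omap, pmap


@pytest.fixture(scope="session")
def grid():
    return ca.build_grid()
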