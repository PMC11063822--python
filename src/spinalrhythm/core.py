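"""Shared in-memory containers for electrophysiology recordings and calcium movies.

A :class:`Recording` holds rectified ventral-root envelopes from the isolated
neonatal mouse spinal cord: up to four named channels (left/right lumbar
segment 2 and 5), a common sampling rate and duration.  A
:class:`CalciumMovie` holds a frames x height x width fluorescence stack with
the anatomical landmarks (central canal, cord edges) needed to normalize the
imaged field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

import numpy as np

#: Channel roles, in canonical order: left/right flexor-related (L2) roots,
#: left/right extensor-related (L5) roots.
ROLES = ("lL2", "rL2", "lL5", "rL5")


@dataclass
class Recording:
    """Multi-channel ventral-root envelope recording.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    channels : mapping of role -> 1-D array
        Rectified envelope per channel, arbitrary units.  Roles are a subset
        of :data:`ROLES`; all channels must have equal length.
    annotations : dict
        Event-time annotations in seconds (e.g. ``drug_onset``, ``cno_onset``,
        ``cno_washout``, ``light_on``, ``light_off``).
    """

    fs: float
    channels: Dict[str, np.ndarray]
    annotations: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not self.channels:
            raise ValueError("channels must not be empty")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"all channels must have equal length, got {lengths}")
        unknown = set(self.channels) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown channel roles: {sorted(unknown)}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


#: Landmark keys required to normalize an imaged field.
LANDMARK_KEYS = ("cc_row", "cc_col", "left_col", "right_col", "dorsal_row", "ventral_row")


@dataclass
class CalciumMovie:
    """Fluorescence stack with anatomical landmarks.

    ``frames`` is a (T, H, W) array in arbitrary intensity units.  Landmarks
    locate the central canal (``cc_row``/``cc_col``) and the four cord edges
    in pixel coordinates of the raw field.  A *normalized* movie is exactly
    400 rows x 500 columns with the central canal on the vertical midline
    (column boundary 249.5).
    """

    frames: np.ndarray
    fs: float
    landmarks: Mapping[str, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        missing = [k for k in LANDMARK_KEYS if k not in self.landmarks]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")
        T, H, W = self.frames.shape
        lm = self.landmarks
        if not (0 <= lm["cc_row"] < H and 0 <= lm["cc_col"] < W):
            raise ValueError("central canal landmark outside frame")
        for key, bound in (("left_col", W), ("right_col", W)):
            if not (0 <= lm[key] < bound):
                raise ValueError(f"landmark {key} outside frame")
        for key, bound in (("dorsal_row", H), ("ventral_row", H)):
            if not (0 <= lm[key] < bound):
                raise ValueError(f"landmark {key} outside frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration(self) -> float:
        return self.n_frames / self.fs

    def with_frames(self, frames: np.ndarray, *, normalized: bool | None = None,
                    landmarks: Mapping[str, float] | None = None) -> "CalciumMovie":
        return CalciumMovie(
            frames=frames,
            fs=self.fs,
            landmarks=self.landmarks if landmarks is None else landmarks,
            normalized=self.normalized if normalized is None else normalized,
        )
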