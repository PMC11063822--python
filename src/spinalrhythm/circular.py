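"""Circular statistics for left-right and flexor-extensor coordination.

Phases are extracted cycle by cycle: each reference-root cycle is the
interval between consecutive burst onsets, and the phase of the test root is
the position of its burst onset within that cycle, expressed in degrees.
0 deg means synchronous activity of the two roots, 180 deg strict
alternation.  The mean angle gives the preferred phase; the resultant vector
length r (0..1) measures how concentrated the phases are around it.

Two tests are provided: the Rayleigh test for non-uniformity (is there
coupling at all?) and the Watson-Williams test for equality of mean
directions across groups.  Both are implemented from the standard
closed-form approximations and are cross-checked against permutation oracles
in the test suite.

Angles are degrees in [0, 360) at the API surface and radians internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .bursts import BurstEvent

logger = logging.getLogger(__name__)

#: Mean resultant length below which the Watson-Williams concentration
#: correction becomes unreliable; results are flagged, not suppressed.
LOW_CONCENTRATION_RBAR = 0.45


@dataclass
class PhaseSeries:
    """Cycle-by-cycle phases of a test root within a reference root's cycles."""

    pair: Tuple[str, str]
    angles: np.ndarray          # degrees in [0, 360)
    n_skipped_empty: int = 0    # reference cycles with no test onset
    n_skipped_multiple: int = 0  # reference cycles with >1 test onset

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float) % 360.0

    @property
    def n_cycles(self) -> int:
        return len(self.angles)


@dataclass
class CircularSummary:
    """Group-level coordination summary across preparations."""

    pair: Tuple[str, str]
    per_preparation_means: List[float]
    per_preparation_r: List[float]
    grand_mean: Optional[float]
    r: float                    # resultant length of the per-preparation means
    n: int                      # number of preparations
    rayleigh_p: Optional[float]


def extract_cycle_phases(ref_events: Sequence[BurstEvent],
                         test_events: Sequence[BurstEvent],
                         pair: Tuple[str, str] = ("ref", "test")) -> PhaseSeries:
    """Phase of each test-burst onset within the enclosing reference cycle.

    For reference cycle [onset_i, onset_{i+1}) the phase is
    ``360 * (t_test - onset_i) / (onset_{i+1} - onset_i)``.  Cycles containing
    zero or multiple test onsets are skipped and counted, not interpolated.
    """
    ref_onsets = np.array([ev.onset for ev in ref_events])
    test_onsets = np.array([ev.onset for ev in test_events])
    if len(ref_onsets) < 4:
        raise ValueError(
            f"need at least 3 reference cycles (4 onsets), got {len(ref_onsets)} onsets")
    angles = []
    skipped_empty = 0
    skipped_multiple = 0
    for a, b in zip(ref_onsets, ref_onsets[1:]):
        inside = test_onsets[(test_onsets >= a) & (test_onsets < b)]
        if len(inside) == 1:
            angles.append(360.0 * (inside[0] - a) / (b - a))
        elif len(inside) == 0:
            skipped_empty += 1
        else:
            skipped_multiple += 1
    if skipped_empty or skipped_multiple:
        logger.info("extract_cycle_phases: skipped %d empty and %d multi-onset cycles",
                    skipped_empty, skipped_multiple)
    return PhaseSeries(pair=pair, angles=np.array(angles),
                       n_skipped_empty=skipped_empty,
                       n_skipped_multiple=skipped_multiple)


def circular_mean(angles_deg: Sequence[float],
                  weights: Optional[Sequence[float]] = None,
                  ) -> Tuple[Optional[float], float]:
    """Mean angle (degrees in [0, 360), None if undefined) and resultant
    length r of a sample of angles."""
    ang = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if ang.size == 0:
        raise ValueError("need at least one angle")
    rad = np.deg2rad(ang)
    w = np.ones_like(rad) if weights is None else np.asarray(weights, dtype=float)
    c = float(np.sum(w * np.cos(rad)) / np.sum(w))
    s = float(np.sum(w * np.sin(rad)) / np.sum(w))
    r = math.hypot(c, s)
    if r < 1e-12:
        return None, 0.0
    return math.degrees(math.atan2(s, c)) % 360.0, r


def rayleigh_test(angles_deg: Sequence[float],
                  weights: Optional[Sequence[float]] = None) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    ``Z = n * rbar**2`` with the standard small-sample correction
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` (the same
    approximation the pycircstat family uses).  If ``weights`` are given
    (e.g. each preparation's own r), the resultant is weighted; the default
    is unweighted.
    """
    ang = np.asarray(angles_deg, dtype=float)
    n = ang.size
    if n < 3:
        raise ValueError(f"Rayleigh test needs n >= 3, got {n}")
    _, rbar = circular_mean(ang, weights=weights)
    R = n * rbar
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - R ** 2)) - (1.0 + 2.0 * n))
    return float(min(max(p, 0.0), 1.0))


def _kappa_ml(rbar: float) -> float:
    """Maximum-likelihood estimate of the von Mises concentration from the
    mean resultant length (Fisher's piecewise approximation)."""
    if rbar < 0.53:
        return 2.0 * rbar + rbar ** 3 + 5.0 * rbar ** 5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar ** 3 - 4.0 * rbar ** 2 + 3.0 * rbar)


@dataclass
class WatsonWilliamsResult:
    statistic: float
    df: Tuple[int, int]
    p: float
    low_concentration: bool


def watson_williams_test(groups_deg: Sequence[Sequence[float]]) -> WatsonWilliamsResult:
    """Watson-Williams F test for equality of mean directions across groups.

    Uses the concentration-corrected F statistic; the correction assumes
    reasonably concentrated samples, so results with pooled mean resultant
    length below 0.45 carry ``low_concentration=True``.
    """
    if len(groups_deg) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups_deg]
    for i, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {i} has n = {g.size} < 3")
    k = len(groups)
    N = sum(g.size for g in groups)
    # per-group and pooled resultant lengths (unnormalized)
    R_groups = []
    C_tot = S_tot = 0.0
    for g in groups:
        rad = np.deg2rad(g)
        c, s = float(np.sum(np.cos(rad))), float(np.sum(np.sin(rad)))
        R_groups.append(math.hypot(c, s))
        C_tot += c
        S_tot += s
    R_within = sum(R_groups)
    R_total = math.hypot(C_tot, S_tot)
    rbar_w = R_within / N
    low = rbar_w < LOW_CONCENTRATION_RBAR
    if low:
        logger.warning("Watson-Williams: pooled rbar %.3f < %.2f, F correction unreliable",
                       rbar_w, LOW_CONCENTRATION_RBAR)
    kappa = _kappa_ml(rbar_w)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - R_within
    if denom <= 0:
        # all angles identical within groups; equal means => F = 0
        F = 0.0 if R_total >= R_within - 1e-12 else math.inf
    else:
        F = correction * ((N - k) * (R_within - R_total)) / ((k - 1) * denom)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, k - 1, N - k))
    return WatsonWilliamsResult(statistic=float(F), df=(k - 1, N - k), p=p,
                                low_concentration=low)


def summarize_coordination(per_prep: Sequence[PhaseSeries],
                           weighted_rayleigh: bool = False) -> CircularSummary:
    """Per-preparation circular means, their grand mean, and a Rayleigh test
    over the per-preparation mean angles.

    The grand mean is the unweighted circular mean of the preparation means.
    With ``weighted_rayleigh`` each preparation's mean angle is weighted by
    its own r in the Rayleigh resultant (off by default).
    """
    if not per_prep:
        raise ValueError("need at least one preparation")
    means: List[float] = []
    rs: List[float] = []
    for ps in per_prep:
        m, r = circular_mean(ps.angles)
        if m is None:
            logger.warning("preparation %s has r = 0; its mean is undefined and skipped",
                           ps.pair)
            continue
        means.append(m)
        rs.append(r)
    if not means:
        raise ValueError("no preparation has a defined mean angle")
    grand_mean, grand_r = circular_mean(means)
    if len(means) >= 3:
        p = rayleigh_test(means, weights=rs if weighted_rayleigh else None)
    else:
        p = None
    return CircularSummary(
        pair=per_prep[0].pair,
        per_preparation_means=means,
        per_preparation_r=rs,
        grand_mean=grand_mean,
        r=grand_r,
        n=len(means),
        rayleigh_p=p,
    )
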