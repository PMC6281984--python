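"""Vector-phase analysis of paired hemoglobin signals.

A sample is the vector ``p = (dHbO, dHbR)``.  Rotating the coordinate frame
by 45 degrees counterclockwise gives total hemoglobin ``dHbT = (dHbO+dHbR)/sqrt(2)``
and cerebral oxygen exchange ``dCOE = (dHbR-dHbO)/sqrt(2)``.  The plane is
divided into eight 45-degree octants ("phases"): phases 3-5 flag an initial
dip, phases 7-8 the canonical hemodynamic response (fourth quadrant: dHbO
rising, dHbR falling).  Two origin-centred circles turn the diagram into a
detector: the resting-state threshold circle of radius R1 (maximum resting
vector magnitude) and a smaller EEG-triggered circle of radius R2 built from
the hemoglobin excursions inside the 1-s window in which EEG band power is
active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preproc import HemoSeries

__all__ = [
    "DIP_PHASES",
    "HEMODYNAMIC_PHASES",
    "ThresholdPair",
    "rotate",
    "magnitude",
    "angle_deg",
    "classify_phase",
    "phase_of_point",
    "resting_radius",
    "eeg_window_radius",
    "track_trajectory",
    "crossing_time",
]

_SQRT2 = np.sqrt(2.0)

#: Octants whose sign pattern matches an initial dip (dCOE > 0, dHbO falling).
DIP_PHASES = frozenset({3, 4, 5})
#: Octants of the canonical hemodynamic response (dHbO > 0 > dHbR).
HEMODYNAMIC_PHASES = frozenset({7, 8})


@dataclass(frozen=True)
class ThresholdPair:
    """Radii of the two detection circles (both centred on the origin).

    ``r1`` is the resting-state threshold circle; ``r2`` the smaller circle
    drawn when the EEG gate fires, tagged with the 1-s window index that
    produced it.
    """

    r1: float
    r2: float
    window_id: int = -1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r1) and np.isfinite(self.r2)):
            raise ValueError("radii must be finite")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("radii must be >= 0")


def rotate(hbo, hbr):
    """45-degree counterclockwise frame rotation -> (dHbT, dCOE).

    Norm-preserving: ``hbt**2 + coe**2 == hbo**2 + hbr**2``.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    return (hbo + hbr) / _SQRT2, (hbr - hbo) / _SQRT2


def magnitude(hbo, hbr) -> np.ndarray:
    """Vector magnitude ``|p| = sqrt(hbo^2 + hbr^2)``."""
    return np.hypot(np.asarray(hbo, float), np.asarray(hbr, float))


def angle_deg(hbo, hbr) -> np.ndarray:
    """Vector angle ``atan2(hbr, hbo)`` in degrees, in (-180, 180]."""
    return np.degrees(np.arctan2(np.asarray(hbr, float), np.asarray(hbo, float)))


def classify_phase(hbo, hbr) -> np.ndarray:
    """Octant label 1..8 for each (hbo, hbr) sample.

    Phase 1 is the first octant above the +dHbO axis, numbering runs
    counterclockwise, and each octant is half-open, closed on its
    counterclockwise edge: phase k covers the angle interval
    ((k-1)*45, k*45] degrees (k = 1..4) and continues through the negative
    angles so that phase 8 is (-45, 0].  The zero vector has no phase and
    raises.
    """
    hbo = np.atleast_1d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_1d(np.asarray(hbr, dtype=float))
    if np.any((hbo == 0) & (hbr == 0)):
        raise ValueError("phase undefined for the zero vector")
    ang = np.degrees(np.arctan2(hbr, hbo))
    k = np.ceil(ang / 45.0).astype(int)
    k[k <= 0] += 8
    return k


def phase_of_point(hbo: float, hbr: float) -> int:
    """Scalar convenience wrapper around :func:`classify_phase`."""
    return int(classify_phase([hbo], [hbr])[0])


def resting_radius(baseline: HemoSeries) -> float:
    """Resting-state threshold radius R1.

    The maximum per-sample paired magnitude ``sqrt(hbo(t)^2 + hbr(t)^2)``
    over the resting baseline segment.
    """
    if len(baseline) == 0:
        raise ValueError("resting baseline segment is empty")
    return float(magnitude(baseline.hbo, baseline.hbr).max())


def eeg_window_radius(hemo_window: HemoSeries) -> float:
    """EEG-window circle radius R2.

    Component-wise maxima over the EEG-active window:
    ``sqrt(max|hbo|^2 + max|hbr|^2)``.  Unlike R1 the maxima are taken
    separately per chromophore; absolute values make the radius well-defined
    in the fourth quadrant where dHbR is negative.
    """
    if len(hemo_window) == 0:
        raise ValueError("EEG-activation window segment is empty")
    return float(
        np.hypot(np.abs(hemo_window.hbo).max(), np.abs(hemo_window.hbr).max())
    )


def track_trajectory(
    h: HemoSeries, thresholds: ThresholdPair, start_index: int = 0
) -> pd.DataFrame:
    """Per-sample trajectory record in the vector-phase diagram.

    Columns: time, hbo, hbr, hbt, coe, magnitude, angle_deg, phase (0 where
    the vector is exactly zero), in_r2, in_r1 (inside = magnitude <= radius).
    """
    if not 0 <= start_index < len(h):
        raise IndexError(f"start_index {start_index} outside series of length {len(h)}")
    hbo = h.hbo[start_index:]
    hbr = h.hbr[start_index:]
    hbt, coe = rotate(hbo, hbr)
    mag = magnitude(hbo, hbr)
    ang = angle_deg(hbo, hbr)
    phase = np.zeros(len(hbo), dtype=int)
    nz = mag > 0
    if nz.any():
        phase[nz] = classify_phase(hbo[nz], hbr[nz])
    return pd.DataFrame(
        {
            "time": (start_index + np.arange(len(hbo))) / h.rate,
            "hbo": hbo,
            "hbr": hbr,
            "hbt": hbt,
            "coe": coe,
            "magnitude": mag,
            "angle_deg": ang,
            "phase": phase,
            "in_r2": mag <= thresholds.r2,
            "in_r1": mag <= thresholds.r1,
        }
    )


def crossing_time(
    times: np.ndarray,
    mags: np.ndarray,
    radius: float,
    t_from: float = -np.inf,
    in_q4: np.ndarray | None = None,
) -> float | None:
    """First *upward* crossing of the magnitude through ``radius``.

    A crossing is a genuine outward transition: the previous sample at or
    below the radius, the arrival sample strictly above it (and, if
    ``in_q4`` is given, in the fourth quadrant at arrival).  A trajectory
    that is already outside the circle and merely stays or decays there
    never crosses — the detector looks for *rising* hemodynamics, not
    elevated ones.  The arrival sample must lie at or after ``t_from``; a
    pair straddling ``t_from`` counts as a crossing observed when
    monitoring began.  The crossing time is linearly interpolated between
    the bracketing samples (exact for rays through the origin) and never
    reported earlier than ``t_from``.  Returns None when no crossing occurs.
    """
    if len(mags) < 2:
        return None
    up = (mags[1:] > radius) & (mags[:-1] <= radius)
    if in_q4 is not None:
        up &= in_q4[1:]
    js = np.flatnonzero(up) + 1
    if np.isfinite(t_from):
        start = int(np.searchsorted(times, t_from))
        js = js[js >= max(start, 1)]
    if js.size == 0:
        return None
    j = int(js[0])
    m0, m1 = mags[j - 1], mags[j]
    frac = (radius - m0) / (m1 - m0) if m1 > m0 else 1.0
    t_cross = float(times[j - 1] + frac * (times[j] - times[j - 1]))
    return t_cross if not np.isfinite(t_from) else max(t_cross, float(t_from))
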