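"""Sound level versus distance and the effective sampled area of a recorder.

A playback trial measures received level (dB) at increasing distances from a
speaker broadcasting a bellow at source level.  The maximum detection
distance is where the level falls to the ambient noise floor (optionally less
a margin: spectrogram inspection can pull calls out of broadband noise, so a
negative-SNR margin is allowed).  The circle of that radius converts to the
effective area sampled by one recorder, in hectares.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "LevelProfile",
    "max_detection_distance",
    "effective_area_ha",
    "compare_profiles",
]


@dataclasses.dataclass(frozen=True)
class LevelProfile:
    """Received sound level (dB) at a series of distances (m) from a source."""

    distances: np.ndarray
    levels: np.ndarray
    ambient_db: float = 42.0

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        l = np.asarray(self.levels, dtype=float)
        if d.shape != l.shape or d.ndim != 1:
            raise ValueError("distances and levels must be 1-d and equally long")
        if np.any(d <= 0):
            raise ValueError("distances must be positive")
        if d.size > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "levels", l)


def max_detection_distance(
    profile: LevelProfile, margin_db: float = 0.0, interpolate: bool = False
) -> float:
    """Distance (m) at which the received level drops to the detection floor.

    The floor is ``ambient_db - margin_db``; a call is considered lost once
    its level no longer exceeds the floor.  By default the smallest tabulated
    distance at or below the floor is returned; with ``interpolate=True`` the
    crossing point between the bracketing distances is found linearly.
    """
    thr = profile.ambient_db - margin_db
    below = profile.levels <= thr
    if not below.any():
        raise ValueError("level never drops to the detection floor: radius exceeds tested range")
    i = int(np.argmax(below))
    if not interpolate or i == 0:
        return float(profile.distances[i])
    d0, d1 = profile.distances[i - 1], profile.distances[i]
    l0, l1 = profile.levels[i - 1], profile.levels[i]
    return float(d0 + (l0 - thr) / (l0 - l1) * (d1 - d0))


def effective_area_ha(radius_m: float) -> float:
    """Area of the detection circle, pi r^2, in hectares."""
    if radius_m < 0:
        raise ValueError("radius must be non-negative")
    return float(np.pi * radius_m**2 / 10_000.0)


def compare_profiles(a: LevelProfile, b: LevelProfile) -> tuple[float, int, float]:
    """Paired two-sided t-test of received levels at matched distances.

    Returns ``(t, df, p_value)``.  Identical profiles give ``(0, n-1, 1)``;
    a constant non-zero offset has zero variance in the differences and is
    rejected as degenerate.
    """
    if a.distances.size != b.distances.size or not np.allclose(a.distances, b.distances):
        raise ValueError("profiles must be tabulated at matched distances")
    diffs = a.levels - b.levels
    n = diffs.size
    if n < 2:
        raise ValueError("need at least two matched distances")
    if np.all(diffs == 0):
        return 0.0, n - 1, 1.0
    if np.std(diffs, ddof=1) == 0:
        raise ValueError("constant non-zero level offset: paired t-test is degenerate")
    t, p = stats.ttest_rel(a.levels, b.levels)
    return float(t), n - 1, float(p)
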