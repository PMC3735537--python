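"""Circular (mod-24 h) phase arithmetic shared across modules.

Phases live on a 24 h circle (zeitgeber hours).  The circular median is
defined operationally as the grid value (0.1 h resolution by default)
minimizing the summed circular distance to the sample; the lowest grid
value wins ties.  This avoids the wrap-around artifact of a plain median
(e.g. {ZT2, ZT22} must summarize near ZT0, not ZT12).
"""

from __future__ import annotations

import numpy as np

PERIOD_H = 24.0


def circ_distance(a, b, period: float = PERIOD_H):
    """Unsigned circular distance in hours, in [0, period/2]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


def circ_signed_difference(a, b, period: float = PERIOD_H):
    """Signed difference a - b wrapped to (-period/2, period/2]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.where(d > period / 2, d - period, d)


def circular_median(phases, grid_step_h: float = 0.1, period: float = PERIOD_H) -> float:
    """Grid minimizer of summed circular distance; lowest value on ties."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular median of an empty set")
    candidates = np.round(np.arange(0.0, period, grid_step_h), 10)
    cost = circ_distance(candidates[:, None], phases[None, :], period).sum(axis=1)
    cost = np.round(cost, 9)  # merge float-noise ties so the lowest candidate wins
    return float(candidates[int(np.argmin(cost))])  # argmin returns the first (lowest) tie


def circular_mad(phases, median_h: float | None = None, period: float = PERIOD_H) -> float:
    """Median of circular distances to the circular median."""
    phases = np.asarray(phases, dtype=float)
    if median_h is None:
        median_h = circular_median(phases, period=period)
    return float(np.median(circ_distance(phases, median_h, period)))


def minimize_circular_pair(a: float, b: float, period: float = PERIOD_H) -> tuple[float, float]:
    """Unwrap ``a`` onto the real line so |a' - b| is minimal.

    Returns (a', b) with a' in {a - period, a, a + period}; when the two
    shifts tie (difference exactly period/2), a is kept as-is.
    """
    candidates = (a, a - period, a + period)  # plain a first so ties keep it
    best = min(candidates, key=lambda c: abs(c - b))
    return best, b
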