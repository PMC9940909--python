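"""Nematic (head-tail symmetric) angle utilities.

Junctions and stripe directions are orientations, not directions: an angle
θ and θ + 180° describe the same line.  All angles in this package are
measured in degrees relative to the DV axis (the +y direction of the
chart), positive counterclockwise in the (x right, y up) chart plane, and
stored in the canonical nematic range (−90°, +90°].

Averages, differences and spreads of such angles are computed in
double-angle space: an angle θ maps to the unit vector
(cos 2θ, sin 2θ); sums of weighted vectors are mapped back by halving the
argument.  This makes every statistic invariant under θ → θ + 180°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "canonical_angle",
    "nematic_difference",
    "nematic_mean",
    "nematic_mean_std",
    "nematic_order",
    "OrientationField",
]


def canonical_angle(angle_deg):
    """Wrap angles (deg) to the canonical nematic range (−90, 90].

    Idempotent; e.g. 95° → −85°, −90° → 90°, 0° → 0°.
    """
    a = np.asarray(angle_deg, dtype=float)
    out = 90.0 - np.mod(90.0 - a, 180.0)
    # mod returns 0 for inputs that are exact multiples of 180 away from 90,
    # which maps them to 90 — the closed end of the interval, as intended.
    if np.isscalar(angle_deg):
        return float(out)
    return out


def nematic_difference(a_deg, b_deg):
    """Nematic difference a ⊖ b in (−90, 90] degrees."""
    return canonical_angle(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def _resultant(angles_deg, weights):
    th2 = np.deg2rad(np.asarray(angles_deg, dtype=float)) * 2.0
    if weights is None:
        w = np.ones_like(th2)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    c = float((w * np.cos(th2)).sum())
    s = float((w * np.sin(th2)).sum())
    return c, s, float(wsum)


def nematic_mean(angles_deg, weights=None) -> float:
    """Weighted nematic circular mean (deg, in (−90, 90]).

    Returns NaN when the total weight is zero or the distribution is
    degenerate (resultant length numerically zero, e.g. equal weight at
    +45° and −45°).
    """
    c, s, wsum = _resultant(angles_deg, weights)
    if wsum <= 0:
        return float("nan")
    r = np.hypot(c, s) / wsum
    if r < 1e-12:
        return float("nan")
    return canonical_angle(np.rad2deg(np.arctan2(s, c)) / 2.0)


def nematic_order(angles_deg, weights=None) -> float:
    """Nematic order parameter q = |⟨e^{2iθ}⟩_w| ∈ [0, 1]."""
    c, s, wsum = _resultant(angles_deg, weights)
    if wsum <= 0:
        return 0.0
    return float(np.hypot(c, s) / wsum)


def nematic_mean_std(angles_deg, weights=None) -> tuple[float, float]:
    """Weighted nematic mean and circular standard deviation (deg).

    The circular std is computed in double-angle space,
    σ₂ = sqrt(−2 ln R) with R the resultant length, and mapped back by
    halving; for a concentrated wrapped-normal distribution it equals the
    underlying σ.
    """
    c, s, wsum = _resultant(angles_deg, weights)
    if wsum <= 0:
        return float("nan"), float("nan")
    r = np.hypot(c, s) / wsum
    if r < 1e-12:
        return float("nan"), float("nan")
    mean = canonical_angle(np.rad2deg(np.arctan2(s, c)) / 2.0)
    std = np.rad2deg(np.sqrt(max(-2.0 * np.log(min(r, 1.0)), 0.0))) / 2.0
    return mean, float(std)


@dataclass
class OrientationField:
    """Gridded nematic angle with a per-pixel weight.

    ``angle_deg`` holds the nematic angle to the DV axis in (−90, 90]
    (NaN where undefined); ``weight`` ≥ 0 is the evidence behind each
    pixel (gradient magnitude, total myosin, ...).  Pixels with zero
    weight carry no orientation information.
    """

    angle_deg: np.ndarray
    weight: np.ndarray
    time_min: float | None = None

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.angle_deg.shape != self.weight.shape:
            raise ValueError("angle and weight grids must have the same shape")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.angle_deg.shape
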