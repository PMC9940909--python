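"""Tissue velocity-field analysis.

Operates on time series of gridded tissue velocities (μm/min) on a
:class:`~gbeorient.chart.ChartGrid`: vorticity and local rotation rate,
Lagrangian advection of points, polylines and scalar patterns, temporal
autocorrelation of flow direction, and simple spatial averages.

Sign conventions: the chart has x to the right (posterior) and y up
(toward the dorsal midline going counterclockwise), so positive vorticity
ω = ∂v_y/∂x − ∂v_x/∂y means counterclockwise rotation.  The local rotation
rate of a material element is ω/2 (the antisymmetric part of the velocity
gradient), reported in degrees per minute.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chart import ChartGrid

__all__ = [
    "VelocityField",
    "RotationRateField",
    "CorrelationMatrix",
    "vorticity",
    "rotation_rate",
    "advect_points",
    "advect_polyline",
    "advect_scalar_field",
    "advect_scalar_series",
    "direction_autocorrelation",
    "nematic_autocorrelation_matrix",
    "spatial_average",
    "write_velocity_csv",
    "read_velocity_csv",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class VelocityField:
    """Time series of gridded tissue velocity on a chart.

    ``vx`` and ``vy`` have shape (nt, ny, nx) in μm/min; ``times`` are the
    frame time stamps in minutes (strictly increasing).
    """

    chart: ChartGrid
    times: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        nt = self.times.size
        expected = (nt, self.chart.ny, self.chart.nx)
        if self.vx.shape != expected or self.vy.shape != expected:
            raise ValueError(f"velocity arrays must have shape {expected}")
        if nt == 0:
            raise ValueError("velocity series must contain at least one frame")
        if nt > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.vx)) and np.all(np.isfinite(self.vy))):
            raise ValueError("velocity values must be finite")

    @property
    def nt(self) -> int:
        return self.times.size

    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def frame_interp(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Velocity grids at time ``t`` by linear interpolation in time.

        Clamped to the first/last frame outside the covered range.
        """
        ts = self.times
        if t <= ts[0]:
            return self.vx[0], self.vy[0]
        if t >= ts[-1]:
            return self.vx[-1], self.vy[-1]
        i = int(np.searchsorted(ts, t) - 1)
        f = (t - ts[i]) / (ts[i + 1] - ts[i])
        return (
            (1 - f) * self.vx[i] + f * self.vx[i + 1],
            (1 - f) * self.vy[i] + f * self.vy[i + 1],
        )

    def sample(self, x: np.ndarray, y: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear (DV-periodic, AP-clamped) velocity at points (x, y), time t."""
        gx, gy = self.frame_interp(t)
        return (
            bilinear_sample(gx, x, y, self.chart),
            bilinear_sample(gy, x, y, self.chart),
        )


@dataclass
class RotationRateField:
    """Gridded local rotation rate ω/2 in degrees per minute."""

    chart: ChartGrid
    times: np.ndarray
    values: np.ndarray  # (nt, ny, nx), deg/min, positive = counterclockwise

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, self.chart.ny, self.chart.nx):
            raise ValueError("rotation-rate array shape must be (nt, ny, nx)")

    def frame_interp(self, t: float) -> np.ndarray:
        ts = self.times
        if t <= ts[0]:
            return self.values[0]
        if t >= ts[-1]:
            return self.values[-1]
        i = int(np.searchsorted(ts, t) - 1)
        f = (t - ts[i]) / (ts[i + 1] - ts[i])
        return (1 - f) * self.values[i] + f * self.values[i + 1]

    def sample(self, x: np.ndarray, y: np.ndarray, t: float) -> np.ndarray:
        return bilinear_sample(self.frame_interp(t), x, y, self.chart)


@dataclass
class CorrelationMatrix:
    """Symmetric, unit-diagonal correlation matrix over time pairs.

    Entries lie in [0, 1]; pairs that could not be evaluated (no weight
    overlap) are NaN and flagged in ``undefined``.
    """

    times: np.ndarray
    values: np.ndarray
    undefined: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = self.times.size
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square over times")
        if self.undefined is None:
            self.undefined = np.isnan(self.values)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        finite = self.values[~self.undefined]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [0, 1]")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("correlation matrix must be symmetric")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.times, columns=self.times)
        df.index.name = "t_min"
        df.to_csv(path)


# ---------------------------------------------------------------------------
# interpolation helpers


def bilinear_sample(grid: np.ndarray, x, y, chart: ChartGrid) -> np.ndarray:
    """Bilinear interpolation on a chart grid: periodic in y, clamped in x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fx = np.clip(x / chart.dx, 0.0, chart.nx - 1.0)
    fy = np.mod(y / chart.dy, chart.ny)
    ix0 = np.floor(fx).astype(int)
    # np.mod can round up to exactly ny for tiny negative inputs
    iy0 = np.mod(np.floor(fy).astype(int), chart.ny)
    ix1 = np.minimum(ix0 + 1, chart.nx - 1)
    iy1 = np.mod(iy0 + 1, chart.ny)
    tx = fx - ix0
    ty = fy - iy0
    g00 = grid[iy0, ix0]
    g01 = grid[iy0, ix1]
    g10 = grid[iy1, ix0]
    g11 = grid[iy1, ix1]
    return (
        g00 * (1 - tx) * (1 - ty)
        + g01 * tx * (1 - ty)
        + g10 * (1 - tx) * ty
        + g11 * tx * ty
    )


# ---------------------------------------------------------------------------
# differential operators


def vorticity(velocity: VelocityField) -> np.ndarray:
    """Curl ω = ∂v_y/∂x − ∂v_x/∂y of each frame, in 1/min.

    Central differences; DV-periodic in y, one-sided at the AP edges.
    Returns an array of shape (nt, ny, nx).
    """
    ch = velocity.chart
    if ch.nx < 2 or ch.ny < 2:
        raise ValueError("vorticity requires at least a 2x2 grid")
    dvy_dx = np.gradient(velocity.vy, ch.dx, axis=2)
    # periodic central difference along y
    dvx_dy = (np.roll(velocity.vx, -1, axis=1) - np.roll(velocity.vx, 1, axis=1)) / (
        2.0 * ch.dy
    )
    return dvy_dx - dvx_dy


def rotation_rate(velocity: VelocityField) -> RotationRateField:
    """Local material rotation rate, (ω/2)·(180/π) deg/min per frame.

    Half the curl is the angular velocity of a local material element
    under the antisymmetric part of the velocity gradient; this is the
    rate at which tissue flow rotates junctions.
    """
    omega = vorticity(velocity)
    return RotationRateField(
        chart=velocity.chart,
        times=velocity.times.copy(),
        values=np.rad2deg(omega / 2.0),
    )


# ---------------------------------------------------------------------------
# Lagrangian advection


def advect_points(
    points: np.ndarray,
    velocity: VelocityField,
    t0: float,
    t1: float,
    dt: float = 0.25,
    return_flags: bool = False,
):
    """Integrate dx/dt = v(x, t) from t0 to t1 with fixed-step RK4.

    ``points`` is an (n, 2) array of (x, y) positions in μm.  Backward
    tracing (t1 < t0) is supported.  Positions are DV-periodic; points
    reaching the AP boundary are clamped there and flagged.

    Returns the advected (n, 2) array, plus a boolean flag array when
    ``return_flags`` is true.
    """
    if velocity.nt == 0:
        raise ValueError("empty velocity series")
    tmin, tmax = velocity.times[0], velocity.times[-1]
    lo, hi = min(t0, t1), max(t0, t1)
    if velocity.nt > 1 and (lo < tmin - 1e-9 or hi > tmax + 1e-9):
        raise ValueError(f"[{lo}, {hi}] min outside velocity coverage [{tmin}, {tmax}]")
    pts = np.array(points, dtype=float).reshape(-1, 2).copy()
    ch = velocity.chart
    span = t1 - t0
    if span == 0:
        out = pts
    else:
        nstep = max(1, int(np.ceil(abs(span) / dt)))
        h = span / nstep
        t = t0
        x, y = pts[:, 0], pts[:, 1]
        for _ in range(nstep):
            k1x, k1y = velocity.sample(x, y, t)
            k2x, k2y = velocity.sample(x + 0.5 * h * k1x, y + 0.5 * h * k1y, t + 0.5 * h)
            k3x, k3y = velocity.sample(x + 0.5 * h * k2x, y + 0.5 * h * k2y, t + 0.5 * h)
            k4x, k4y = velocity.sample(x + h * k3x, y + h * k3y, t + h)
            x = x + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
            y = y + (h / 6.0) * (k1y + 2 * k2y + 2 * k3y + k4y)
            t += h
        out = np.column_stack([x, y])
    xmax = (ch.nx - 1) * ch.dx
    flags = (out[:, 0] < 0) | (out[:, 0] > xmax)
    out[:, 0] = np.clip(out[:, 0], 0.0, xmax)
    out[:, 1] = ch.wrap_y(out[:, 1])
    if return_flags:
        return out, flags
    return out


def advect_polyline(
    polyline: np.ndarray,
    velocity: VelocityField,
    t0: float,
    t1: float,
    dt: float = 0.25,
) -> np.ndarray:
    """Advect every vertex of a polyline; vertex count is preserved."""
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ValueError("polyline must be an (n, 2) array")
    return advect_points(poly, velocity, t0, t1, dt=dt)


def advect_scalar_field(
    field0: np.ndarray,
    velocity: VelocityField,
    t0: float,
    t1: float,
    dt: float = 0.25,
    order: str = "linear",
) -> np.ndarray:
    """Semi-Lagrangian advection of a gridded pattern from t0 to t1.

    Grid points at t1 are traced backward to t0 and the initial pattern is
    sampled there (bilinear for ``order='linear'``, nearest for labels).
    This is the passive-advection prediction for a pattern carried by the
    tissue (what a gene-expression stripe does if turnover is slow).
    """
    ch = velocity.chart
    field0 = np.asarray(field0, dtype=float)
    if field0.shape != (ch.ny, ch.nx):
        raise ValueError("field shape must match the chart grid")
    X, Y = ch.meshgrid()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    back = advect_points(pts, velocity, t1, t0, dt=dt)
    if order == "nearest":
        ix = np.clip(np.round(back[:, 0] / ch.dx).astype(int), 0, ch.nx - 1)
        iy = np.mod(np.round(back[:, 1] / ch.dy).astype(int), ch.ny)
        vals = field0[iy, ix]
    else:
        vals = bilinear_sample(field0, back[:, 0], back[:, 1], ch)
    return vals.reshape(ch.ny, ch.nx)


def advect_scalar_series(
    field0: np.ndarray,
    velocity: VelocityField,
    times: np.ndarray,
    t0: float = 0.0,
    dt: float = 0.25,
    order: str = "linear",
) -> list[np.ndarray]:
    """Incremental semi-Lagrangian advection of a pattern to several times.

    Steps frame to frame (each output is the previous one advected over
    one interval), which is much cheaper than a full backtrack per output
    time at the cost of mild interpolation smoothing — appropriate for
    tracking stripe patterns or region labels through the flow.
    """
    times = np.asarray(times, dtype=float)
    out = []
    current = np.asarray(field0, dtype=float)
    prev_t = t0
    for t in times:
        if t > prev_t:
            current = advect_scalar_field(
                current, velocity, prev_t, t, dt=dt, order=order
            )
            prev_t = t
        out.append(current.copy())
    return out


# ---------------------------------------------------------------------------
# correlation and averaging


def direction_autocorrelation(
    velocity: VelocityField,
    weights: np.ndarray | None = None,
    floor_frac: float = 0.05,
) -> CorrelationMatrix:
    """Temporal autocorrelation of the flow direction.

    C(t1, t2) = clamp₀( ⟨ v̂(x,t1) · v̂(x,t2) ⟩_w ), the weighted mean
    cosine of the angle between unit velocity vectors, clamped to [0, 1]
    (anti-aligned frames map to 0).  The default weight masks out pixels
    whose speed is below ``floor_frac`` of the global maximum in either
    frame; an explicit (nt, ny, nx) non-negative weight array may be
    supplied instead.  Pairs with zero total weight are NaN and flagged.
    """
    if velocity.nt < 2:
        raise ValueError("need at least two frames for an autocorrelation")
    sp = velocity.speed()
    if weights is None:
        floor = floor_frac * sp.max() if sp.max() > 0 else np.inf
        weights = (sp > floor).astype(float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != sp.shape:
        raise ValueError("weights shape must match the velocity series")
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(sp > 0, velocity.vx / sp, 0.0)
        uy = np.where(sp > 0, velocity.vy / sp, 0.0)
    nt = velocity.nt
    vals = np.empty((nt, nt))
    undef = np.zeros((nt, nt), dtype=bool)
    for i in range(nt):
        vals[i, i] = 1.0
        for j in range(i + 1, nt):
            w = weights[i] * weights[j]
            wsum = w.sum()
            if wsum <= 0:
                vals[i, j] = vals[j, i] = np.nan
                undef[i, j] = undef[j, i] = True
                continue
            dot = (w * (ux[i] * ux[j] + uy[i] * uy[j])).sum() / wsum
            vals[i, j] = vals[j, i] = max(0.0, min(1.0, dot))
    return CorrelationMatrix(times=velocity.times.copy(), values=vals, undefined=undef)


def nematic_autocorrelation_matrix(
    angles_deg: np.ndarray,
    weights: np.ndarray,
    times: np.ndarray,
) -> CorrelationMatrix:
    """Shared backend for nematic-orientation autocorrelation matrices.

    C(t1, t2) = clamp₀( ⟨ cos 2(θ(t1) − θ(t2)) ⟩_w ) with pairwise weights
    w(t1)·w(t2); see :func:`gbeorient.stripes.nematic_autocorrelation`.
    """
    angles = np.asarray(angles_deg, dtype=float)
    weights = np.asarray(weights, dtype=float)
    times = np.asarray(times, dtype=float)
    nt = times.size
    if angles.shape[0] != nt or weights.shape != angles.shape:
        raise ValueError("angles/weights must be (nt, ...) matching times")
    th2 = np.deg2rad(angles) * 2.0
    c2, s2 = np.cos(th2), np.sin(th2)
    ok = np.isfinite(th2)
    c2 = np.where(ok, c2, 0.0)
    s2 = np.where(ok, s2, 0.0)
    weights = np.where(ok, weights, 0.0)
    vals = np.empty((nt, nt))
    undef = np.zeros((nt, nt), dtype=bool)
    for i in range(nt):
        vals[i, i] = 1.0
        for j in range(i + 1, nt):
            w = weights[i] * weights[j]
            wsum = w.sum()
            if wsum <= 0:
                vals[i, j] = vals[j, i] = np.nan
                undef[i, j] = undef[j, i] = True
                continue
            # cos 2(θi − θj) expanded to avoid forming the difference
            dot = (w * (c2[i] * c2[j] + s2[i] * s2[j])).sum() / wsum
            vals[i, j] = vals[j, i] = max(0.0, min(1.0, dot))
    return CorrelationMatrix(times=times.copy(), values=vals, undefined=undef)


def spatial_average(field_series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean of each frame over a boolean mask → time series."""
    fields = np.asarray(field_series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if fields.ndim != 3 or fields.shape[1:] != mask.shape:
        raise ValueError("field series must be (nt, ny, nx) matching the mask")
    if not mask.any():
        raise ValueError("mask must contain at least one pixel")
    return fields[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# I/O


def write_velocity_csv(velocity: VelocityField, path: str | Path) -> None:
    """Long-format CSV: t_min, x_um, y_um, vx, vy (one row per grid point)."""
    ch = velocity.chart
    X, Y = ch.meshgrid()
    frames = []
    for k, t in enumerate(velocity.times):
        frames.append(
            pd.DataFrame(
                {
                    "t_min": t,
                    "x_um": X.ravel(),
                    "y_um": Y.ravel(),
                    "vx": velocity.vx[k].ravel(),
                    "vy": velocity.vy[k].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_velocity_csv(path: str | Path, chart: ChartGrid) -> VelocityField:
    """Read a long-format velocity CSV written by :func:`write_velocity_csv`."""
    df = pd.read_csv(path)
    times = np.sort(df["t_min"].unique())
    nt = times.size
    vx = np.empty((nt, chart.ny, chart.nx))
    vy = np.empty((nt, chart.ny, chart.nx))
    for k, t in enumerate(times):
        sub = df[df["t_min"] == t]
        ix = np.round(sub["x_um"].to_numpy() / chart.dx).astype(int)
        iy = np.round(sub["y_um"].to_numpy() / chart.dy).astype(int)
        vx[k][iy, ix] = sub["vx"].to_numpy()
        vy[k][iy, ix] = sub["vy"].to_numpy()
    return VelocityField(chart=chart, times=times, vx=vx, vy=vy)
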