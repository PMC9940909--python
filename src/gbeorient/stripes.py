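"""Pair-rule-gene (PRG) stripe analysis.

PRGs are expressed in seven stripes at regular AP intervals.  Local
cell–cell expression differences are computed as Gaussian-smoothed
gradients; their magnitude shows 14 regularly spaced bands (two flanks
per stripe).  Stripes are segmented by thresholding, inter-stripe lines
are traced along intensity minima, and the local stripe direction is the
gradient direction rotated by 90° (a nematic orientation field weighted
by gradient magnitude).  The gradient-regression operation asks whether a
weighted sum of PRG gradient patterns can reproduce an observed myosin
map:  myosin = Σ_PRGs gradient × weight, fitted by ordinary least
squares with unconstrained signs and no intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .chart import ChartGrid
from .flowfield import CorrelationMatrix, nematic_autocorrelation_matrix
from .nematic import OrientationField, canonical_angle

__all__ = [
    "StripeSet",
    "RegressionResult",
    "DVProfile",
    "smoothed_gradient",
    "gradient_magnitude",
    "count_gradient_bands",
    "segment_stripes",
    "interstripe_lines",
    "stripe_angle_field",
    "nematic_autocorrelation",
    "prg_regression",
    "dv_profile",
]


# ---------------------------------------------------------------------------
# gradients


def _smooth(field: np.ndarray, chart: ChartGrid, sigma_um: float) -> np.ndarray:
    if sigma_um < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_um >= min(chart.ap_length, chart.dv_circumference):
        raise ValueError("smoothing scale exceeds the field extent")
    if sigma_um == 0:
        return np.asarray(field, dtype=float)
    return ndimage.gaussian_filter(
        np.asarray(field, dtype=float),
        (sigma_um / chart.dy, sigma_um / chart.dx),
        mode=("wrap", "nearest"),
    )


def smoothed_gradient(
    field: np.ndarray, chart: ChartGrid, sigma_um: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """(∂f/∂x, ∂f/∂y) of the Gaussian-smoothed field.

    Smoothing is DV-periodic; derivatives are central differences
    (periodic in y, one-sided at the AP edges).  The gradient vector
    points in the direction in which the signal increases most; the
    default σ of 10 μm is about 1.5 cell diameters, so the gradient
    measures local cell–cell expression differences.
    """
    f = _smooth(field, chart, sigma_um)
    gx = np.gradient(f, chart.dx, axis=1)
    gy = (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2.0 * chart.dy)
    return gx, gy


def gradient_magnitude(
    field: np.ndarray, chart: ChartGrid, sigma_um: float = 10.0
) -> np.ndarray:
    """|smoothed gradient| — for a striped pattern, two bands per stripe."""
    gx, gy = smoothed_gradient(field, chart, sigma_um)
    return np.hypot(gx, gy)


def count_gradient_bands(
    field: np.ndarray,
    chart: ChartGrid,
    sigma_um: float = 10.0,
    threshold_frac: float = 0.5,
    min_pixels: int = 20,
) -> int:
    """Count distinct high-gradient bands within the germband.

    Thresholds the smoothed gradient magnitude at ``threshold_frac`` of
    its germband maximum and counts connected components (DV-periodic),
    ignoring specks below ``min_pixels``.  A default seven-stripe pattern
    yields 14 bands.
    """
    gm = gradient_magnitude(field, chart, sigma_um)
    mask = chart.germband_mask
    thr = threshold_frac * gm[mask].max()
    labels, n = _periodic_label((gm >= thr) & mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return int(np.count_nonzero(sizes >= min_pixels))


def _periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected-component labels with DV (row) periodicity."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return labels, 0
    # merge labels that touch across the y boundary
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    top, bot = labels[0], labels[-1]
    for a, b in zip(top, bot):
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    remap = np.zeros(n + 1, dtype=int)
    next_id = 0
    for i in range(1, n + 1):
        r = find(i)
        if remap[r] == 0:
            next_id += 1
            remap[r] = next_id
        remap[i] = remap[r]
    return remap[labels], next_id


# ---------------------------------------------------------------------------
# stripe segmentation


@dataclass
class StripeSet:
    """AP-ordered labelled stripes.

    ``labels`` is an int image: 0 background, 1..k the stripes ordered by
    AP position.  ``smoothed`` keeps the field the segmentation ran on
    (used to trace inter-stripe minima).
    """

    labels: np.ndarray
    chart: ChartGrid
    smoothed: np.ndarray = field(repr=False)

    @property
    def n_stripes(self) -> int:
        return int(self.labels.max())

    def stripe_mask(self, index: int) -> np.ndarray:
        if not (1 <= index <= self.n_stripes):
            raise IndexError("stripe index out of range")
        return self.labels == index

    def ap_centroids(self) -> np.ndarray:
        """Mean AP coordinate (μm) of each stripe, in label order."""
        out = []
        for i in range(1, self.n_stripes + 1):
            cols = np.nonzero(self.labels == i)[1]
            out.append(cols.mean() * self.chart.dx)
        return np.array(out)

    def to_label_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.labels.astype(np.uint16))


def segment_stripes(
    field: np.ndarray,
    chart: ChartGrid,
    threshold_frac: float = 0.5,
    sigma_um: float = 5.0,
    min_dv_span_frac: float = 0.5,
) -> StripeSet:
    """Threshold-based stripe segmentation.

    The field is smoothed, thresholded at ``threshold_frac`` of its
    maximum, and DV-periodic connected components that span at least
    ``min_dv_span_frac`` of the germband DV extent are kept as stripes,
    AP-ordered 1..k.  An empty result is a valid StripeSet with zero
    stripes (a warning-level situation, not an error).
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in (0, 1)")
    sm = _smooth(field, chart, sigma_um)
    peak = sm.max()
    shape = (chart.ny, chart.nx)
    if peak <= 0:
        return StripeSet(np.zeros(shape, dtype=int), chart, sm)
    labels, n = _periodic_label(sm >= threshold_frac * peak)
    gb_rows = np.unique(np.nonzero(chart.germband_mask)[0])
    needed = min_dv_span_frac * gb_rows.size
    kept = []
    for i in range(1, n + 1):
        rows = np.unique(np.nonzero(labels == i)[0])
        span = np.intersect1d(rows, gb_rows, assume_unique=True).size
        if span >= needed:
            cols = np.nonzero(labels == i)[1]
            kept.append((cols.mean(), i))
    kept.sort()
    out = np.zeros(shape, dtype=int)
    for rank, (_, lab) in enumerate(kept, start=1):
        out[labels == lab] = rank
    return StripeSet(out, chart, sm)


def interstripe_lines(stripe_set: StripeSet) -> list[np.ndarray]:
    """One intensity-minimum polyline between each adjacent stripe pair.

    For each pair of AP-consecutive stripes, the per-row minimum of the
    smoothed intensity between their AP centroids is traced across the
    germband DV extent (rows ordered by signed DV distance from the
    ventral midline).  k stripes give k − 1 polylines of (x, y) vertices
    in μm; fewer than 2 stripes give an empty list.
    """
    k = stripe_set.n_stripes
    if k < 2:
        return []
    ch = stripe_set.chart
    sm = stripe_set.smoothed
    centroids = stripe_set.ap_centroids()
    gb_rows = np.unique(np.nonzero(ch.germband_mask)[0])
    # order germband rows by signed DV coordinate (ventral midline = 0)
    y = gb_rows * ch.dy
    signed = np.where(y <= ch.dv_circumference / 2.0, y, y - ch.dv_circumference)
    order = np.argsort(signed)
    rows = gb_rows[order]
    lines = []
    for i in range(k - 1):
        c0 = int(round(centroids[i] / ch.dx))
        c1 = int(round(centroids[i + 1] / ch.dx))
        lo, hi = min(c0, c1), max(c0, c1)
        if hi - lo < 2:
            hi = lo + 2
        verts = []
        for r in rows:
            strip = sm[r, lo : hi + 1]
            xmin = (lo + int(np.argmin(strip))) * ch.dx
            verts.append((xmin, r * ch.dy))
        lines.append(np.array(verts))
    return lines


# ---------------------------------------------------------------------------
# stripe orientation


def stripe_angle_field(
    field: np.ndarray, chart: ChartGrid, sigma_um: float = 10.0
) -> OrientationField:
    """Local stripe direction: the gradient rotated by 90°, as a nematic
    angle to the DV axis, weighted by the gradient magnitude.

    Vertical stripes (parallel to the DV axis) give θ ≈ 0 wherever the
    weight is high; a constant field has zero weight everywhere.
    """
    gx, gy = smoothed_gradient(field, chart, sigma_um)
    w = np.hypot(gx, gy)
    # stripe direction = gradient rotated +90°: (−gy, gx)
    angle = np.full(w.shape, np.nan)
    ok = w > 0
    angle[ok] = canonical_angle(
        np.rad2deg(np.arctan2(gx[ok], -gy[ok])) - 90.0
    )
    return OrientationField(angle, np.where(ok, w, 0.0))


def nematic_autocorrelation(
    orientation_series: list[OrientationField],
    times: np.ndarray | None = None,
) -> CorrelationMatrix:
    """Temporal autocorrelation of a nematic orientation field series.

    C(t₁, t₂) = clamp₀( ⟨ cos 2(θ(t₁) − θ(t₂)) ⟩ ) weighted by the
    product of the two frames' weights: 1 for identical fields, 0 for
    everywhere-orthogonal ones.  Frames with all-zero weight give NaN
    entries, flagged in the matrix rather than silently reported as 1.
    """
    if len(orientation_series) < 2:
        raise ValueError("need at least two frames")
    if times is None:
        times = np.array(
            [
                f.time_min if f.time_min is not None else float(i)
                for i, f in enumerate(orientation_series)
            ]
        )
    angles = np.stack([f.angle_deg for f in orientation_series])
    weights = np.stack([f.weight for f in orientation_series])
    return nematic_autocorrelation_matrix(angles, weights, times)


# ---------------------------------------------------------------------------
# gradient regression


@dataclass
class RegressionResult:
    """Ordinary-least-squares fit of myosin to PRG gradient patterns.

    ``weights`` are the signed per-gene coefficients (positive =
    promotion, negative = inhibition of myosin accumulation);
    ``fitted_map`` is exactly the weighted sum of the gradient maps
    (plus the intercept if fitted).  R² uses the uncentred total sum of
    squares when no intercept is fitted.
    """

    weights: dict[str, float]
    intercept: float
    fitted_map: np.ndarray = field(repr=False)
    residual_map: np.ndarray = field(repr=False)
    r_squared: float
    rank: int
    rank_deficient: bool

    def to_dict(self) -> dict:
        return {
            "weights": {k: float(v) for k, v in self.weights.items()},
            "intercept": float(self.intercept),
            "r_squared": float(self.r_squared),
            "rank": int(self.rank),
            "rank_deficient": bool(self.rank_deficient),
        }


def prg_regression(
    myosin_field: np.ndarray,
    prg_gradient_fields: dict[str, np.ndarray],
    mask: np.ndarray,
    intercept: bool = False,
) -> RegressionResult:
    """Fit myosin = Σ_PRGs gradient × weight over the masked pixels.

    Weights are unconstrained in sign and constant over space.  By
    default there is no intercept.  Collinear regressors are reported
    (``rank_deficient``) and resolved by the minimum-norm solution rather
    than raised.
    """
    if not prg_gradient_fields:
        raise ValueError("need at least one regressor")
    mask = np.asarray(mask, dtype=bool)
    y = np.asarray(myosin_field, dtype=float)[mask]
    names = list(prg_gradient_fields)
    cols = [np.asarray(prg_gradient_fields[n], dtype=float)[mask] for n in names]
    if intercept:
        cols.append(np.ones_like(y))
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted_mask = X @ beta
    resid = y - fitted_mask
    if intercept:
        ss_tot = float(((y - y.mean()) ** 2).sum())
    else:
        ss_tot = float((y**2).sum())
    ss_res = float((resid**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    weights = dict(zip(names, beta[: len(names)]))
    b0 = float(beta[-1]) if intercept else 0.0
    fitted_map = np.full(np.asarray(myosin_field).shape, b0, dtype=float)
    for n in names:
        fitted_map += weights[n] * np.asarray(prg_gradient_fields[n], dtype=float)
    residual_map = np.asarray(myosin_field, dtype=float) - fitted_map
    return RegressionResult(
        weights={k: float(v) for k, v in weights.items()},
        intercept=b0,
        fitted_map=fitted_map,
        residual_map=residual_map,
        r_squared=r2,
        rank=int(rank),
        rank_deficient=rank < X.shape[1],
    )


# ---------------------------------------------------------------------------
# DV decay profiles


@dataclass
class DVProfile:
    """Fold-averaged intensity vs DV distance from the ventral midline,
    normalized to the ventral maximum."""

    dv_um: np.ndarray
    intensity: np.ndarray

    def support_extent(self, floor: float = 0.1) -> float:
        """Largest DV distance (μm) at which the profile still reaches
        ``floor``; 0 if it never does."""
        above = self.intensity >= floor
        if not above.any():
            return 0.0
        return float(self.dv_um[np.flatnonzero(above)[-1]])


def dv_profile(
    field: np.ndarray,
    chart: ChartGrid,
    bin_um: float = 5.0,
    ap_margin_um: float = 30.0,
) -> DVProfile:
    """Mean intensity vs periodic DV distance from the ventral midline.

    The two lateral halves are fold-averaged (the periodic DV distance is
    the same on both); AP columns within ``ap_margin_um`` of the poles
    are excluded; the profile is normalized to its ventral maximum.
    """
    if bin_um <= 0:
        raise ValueError("bin size must be positive")
    f = np.asarray(field, dtype=float)
    dvd = np.asarray(chart.dv_distance(chart.y))
    cols = (chart.x >= ap_margin_um) & (chart.x <= chart.ap_length - ap_margin_um)
    sub = f[:, cols]
    edges = np.arange(0.0, chart.dv_circumference / 2.0 + bin_um, bin_um)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(dvd, edges) - 1, 0, centers.size - 1)
    prof = np.zeros(centers.size)
    for b in range(centers.size):
        rows = idx == b
        prof[b] = sub[rows].mean() if rows.any() else np.nan
    peak = np.nanmax(prof[: max(2, int(20 / bin_um))])  # ventral maximum
    if peak > 0:
        prof = prof / peak
    return DVProfile(dv_um=centers, intensity=prof)
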