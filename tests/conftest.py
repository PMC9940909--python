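"""Shared fixtures: charts, flows, a reference junction ensemble.

Expensive objects (the wild-type flow, a 2000-junction ensemble, a
coarse full-pipeline report) are session-scoped so several test modules
can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import gbeorient as g
from gbeorient import flowfield, junctions, sourcemodel, synthgen
from gbeorient.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def wt_chart():
    return g.make_chart()


@pytest.fixture(scope="session")
def wt_flow(wt_chart):
    spec = synthgen.default_flow_spec(wt_chart)
    flow = synthgen.make_flow_field(wt_chart, spec, np.arange(0.0, 46.0, 1.0))
    return flow


@pytest.fixture(scope="session")
def wt_rotation(wt_flow):
    return flowfield.rotation_rate(wt_flow)


@pytest.fixture(scope="session")
def wt_ensemble(wt_chart, wt_flow):
    """Reference wild-type ensemble: n = 2000 junctions, true τ = 5 min."""
    params = sourcemodel.ModelParams(tau=5.0)
    segments, truth = synthgen.simulate_junction_ensemble(
        wt_chart, wt_flow, params, n_junctions=2000, t_span=(0.0, 35.0), seed=42
    )
    return segments, truth


@pytest.fixture(scope="session")
def wt_observed_fields(wt_chart, wt_ensemble):
    segments, _ = wt_ensemble
    fields = []
    for t in np.arange(10.0, 35.01, 1.0):
        frame = segments[np.isclose(segments.t_min, t)]
        f = junctions.anisotropy_field(
            frame, wt_chart, radius_um=20.0, estimator="recentered"
        )
        f.time_min = float(t)
        fields.append(f)
    return fields


@pytest.fixture(scope="session")
def coarse_wt_report():
    """A fast full-pipeline run (2 μm grid, 800 junctions)."""
    cfg = RunConfig.from_preset("wt", seed=3, n_junctions=800, dx=2.0, dy=2.0)
    return run_pipeline(cfg)


def open_chart(n: int, spacing: float = 1.0) -> g.ChartGrid:
    """Square all-germband chart for image-level fixtures."""
    return g.ChartGrid(
        nx=n,
        ny=n,
        dx=spacing,
        dy=spacing,
        germband_mask=np.ones((n, n), dtype=bool),
    )


def jittered_grid_segments(n_side: int, pitch: float, seed: int, length: float = 10.0):
    """Segments on a jittered grid: junctions tile cells, they do not
    overlap arbitrarily.  Returns (segments, xs, ys, angles)."""
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side))
    n = n_side * n_side
    xs = gx.ravel() * pitch + pitch * 0.8 + rng.uniform(-3, 3, n)
    ys = gy.ravel() * pitch + pitch * 0.8 + rng.uniform(-3, 3, n)
    angles = rng.uniform(-90.0, 90.0, n)
    segs = [
        junctions.JunctionSegment.from_midpoint(x, y, a, length, 1.0)
        for x, y, a in zip(xs, ys, angles)
    ]
    return segs, xs, ys, angles


def match_detections(dets, xs, ys, angles, radius=5.0):
    """Greedy nearest-midpoint matching; returns (recall, angular errors)."""
    if not dets:
        return 0.0, np.array([])
    dxy = np.array([d.midpoint for d in dets])
    da = np.array([d.angle_deg for d in dets])
    hits = 0
    errs = []
    for x, y, a in zip(xs, ys, angles):
        dist = np.hypot(dxy[:, 0] - x, dxy[:, 1] - y)
        j = int(np.argmin(dist))
        if dist[j] < radius:
            hits += 1
            errs.append((da[j] - a + 90.0) % 180.0 - 90.0)
    return hits / len(xs), np.array(errs)


def exponential_age_oracle(
    rho: float, tau: float, source_width: float, n_grid: int = 720
):
    """Steady-state angle distribution of the static-source model under
    constant rotation: the wrapped convolution of the Gaussian source
    with an exponential age tail of angular scale ρτ.

    Returns (theta_grid_deg, density); independent of the simulation
    code path (direct numerical integral).
    """
    theta = np.linspace(-90.0, 90.0, n_grid, endpoint=False)
    src = np.exp(-0.5 * (theta / source_width) ** 2)
    if rho == 0:
        return theta, src / src.sum()
    scale = abs(rho) * tau
    u = np.linspace(0.0, 20.0 * scale, 4000)
    du = u[1] - u[0]
    dens = np.zeros_like(theta)
    sign = np.sign(rho)
    for uk, wk in zip(u, np.exp(-u / scale)):
        shifted = (theta - sign * uk + 90.0) % 180.0 - 90.0
        dens += wk * np.exp(-0.5 * (shifted / source_width) ** 2) * du
    return theta, dens / dens.sum()


def oracle_arithmetic_mean(theta, dens):
    return float(np.sum(theta * dens))


def oracle_circular_mean(theta, dens):
    th2 = np.deg2rad(theta) * 2.0
    c = np.sum(dens * np.cos(th2))
    s = np.sum(dens * np.sin(th2))
    return float(np.rad2deg(np.arctan2(s, c)) / 2.0)
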