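"""Synthetic embryo generator.

Produces charts, tissue flows, pair-rule-gene (PRG) stripe patterns,
junction ensembles, rendered junction images and FRAP traces with the
statistical structure the analysis pipeline assumes, so that every
downstream stage is testable without microscopy data.

What is emulated (wild-type defaults):

* a cylindrical pullback chart, 450 μm AP × 500 μm DV circumference;
* a tissue flow with four Gaussian-core vortices mirror-paired across the
  ventral midline (a strong posterior pair, a weak anterior pair, giving
  two hyperbolic stagnation points) plus a DV-convergent / AP-extending
  component, all modulated by a single ramp/plateau/decay time envelope —
  the flow *direction* pattern is time-independent, only its magnitude
  varies.  Amplitudes are calibrated so the peak local rotation rate is
  ≈ 5°/min near the posterior vortices and < 2°/min anteriorly;
* seven AP stripes of PRG expression with intensity reduced towards the
  dorsal pole, different genes slightly out of register via phase offsets;
* junction ensembles obeying the static-source model: positions advect
  passively, angles rotate with the local tissue rotation rate, and
  myosin follows dm/dt = s(θ) − m/τ with a DV-peaked recruitment
  amplitude decaying away from the ventral furrow;
* noisy blurred line-segment images (fixtures for the Radon detector);
* two-timescale FRAP recovery traces with an immediately-recovering
  mobile pool.

All stochastic outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .chart import ChartGrid, make_chart
from .flowfield import VelocityField, rotation_rate
from .junctions import SEGMENT_COLUMNS
from .kinetics import FrapTrace
from .sourcemodel import ModelParams

__all__ = [
    "Vortex",
    "FlowSpec",
    "StripeSpec",
    "FrapParams",
    "GroundTruth",
    "make_chart",
    "default_flow_spec",
    "make_flow_field",
    "make_prg_pattern",
    "make_prg_patterns",
    "simulate_junction_ensemble",
    "render_junction_image",
    "make_frap_trace",
]


# ---------------------------------------------------------------------------
# flow


@dataclass(frozen=True)
class Vortex:
    """A Gaussian-core vortex: peak rotation rate (signed, deg/min,
    positive counterclockwise) at ``center`` with core radius σ_v (μm)."""

    center: tuple[float, float]
    strength_deg_min: float
    core_radius_um: float = 70.0


@dataclass(frozen=True)
class FlowSpec:
    """Synthetic tissue-flow specification.

    ``envelope_knots`` define a piecewise-linear magnitude envelope g(t)
    on [0, 1] (minutes, value); zero before flow onset at 10 min, ramping
    to the plateau by 20 min, plateau to 25 min, decayed to zero by
    35 min.  ``convergence_amplitude`` sets the irrotational
    DV-convergent / AP-extending component (μm/min).
    """

    vortices: tuple[Vortex, ...]
    convergence_amplitude: float = 1.0
    envelope_knots: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (10.0, 0.0),
        (20.0, 1.0),
        (25.0, 1.0),
        (35.0, 0.0),
    )

    def envelope(self, t):
        knots = np.asarray(self.envelope_knots, dtype=float)
        return np.interp(t, knots[:, 0], knots[:, 1], left=0.0, right=0.0)


def default_flow_spec(chart: ChartGrid, amplitude: float = 1.0) -> FlowSpec:
    """Wild-type flow: two mirror pairs of vortices (posterior strong,
    anterior weak) across the ventral midline, plus convergent extension.

    ``amplitude`` scales every velocity component (mutant presets halve
    it); the direction pattern is unchanged.
    """
    ap = chart.ap_length
    yoff = 0.18 * chart.dv_circumference
    circ = chart.dv_circumference
    # vortex strengths are calibrated so the gridded rotation-rate field
    # (which also feels the mirror partner and the broad 70 μm cores)
    # peaks at 5 deg/min posteriorly and stays below 2 deg/min anteriorly
    s_post, s_ant = 4.59 * amplitude, 1.40 * amplitude
    return FlowSpec(
        vortices=(
            Vortex((0.80 * ap, yoff), s_post),
            Vortex((0.80 * ap, circ - yoff), -s_post),
            Vortex((0.20 * ap, yoff), -s_ant),
            Vortex((0.20 * ap, circ - yoff), s_ant),
        ),
        convergence_amplitude=1.0 * amplitude,
    )


def make_flow_field(
    chart: ChartGrid, flow_spec: FlowSpec, times: np.ndarray
) -> VelocityField:
    """Evaluate the synthetic velocity field on the chart at given times.

    v(x, t) = g(t) · [Σᵢ vortexᵢ(x) + convergence(x)]: the spatial pattern
    is static, only the envelope varies, so the flow direction
    autocorrelation is 1 between any two times with g > 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 1 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be non-empty and strictly increasing")
    X, Y = chart.meshgrid()
    ux = np.zeros_like(X)
    uy = np.zeros_like(Y)
    circ = chart.dv_circumference
    for v in flow_spec.vortices:
        xc, yc = v.center
        if not (0.0 <= xc <= chart.ap_length):
            raise ValueError(f"vortex center x={xc} outside the chart AP range")
        dx = X - xc
        dy0 = np.mod(Y - yc + circ / 2.0, circ) - circ / 2.0
        k = np.deg2rad(v.strength_deg_min)  # rotation rate ω/2 at the core centre
        # sum over periodic images in y so the field is smooth across the
        # DV seam (a plain wrapped Gaussian is discontinuous at the
        # vortex antipode)
        for shift in (-circ, 0.0, circ):
            dy = dy0 + shift
            env = np.exp(-(dx**2 + dy**2) / (2.0 * v.core_radius_um**2))
            ux += -k * dy * env
            uy += k * dx * env
    a = flow_spec.convergence_amplitude
    if a != 0.0:
        # DV convergence toward the ventral midline, AP extension outward
        uy += -a * np.sin(2.0 * np.pi * Y / circ)
        ux += a * (X - chart.ap_length / 2.0) / (chart.ap_length / 2.0)
    g = flow_spec.envelope(times)
    vx = g[:, None, None] * ux[None, :, :]
    vy = g[:, None, None] * uy[None, :, :]
    return VelocityField(chart=chart, times=times, vx=vx, vy=vy)


# ---------------------------------------------------------------------------
# pair-rule stripes


@dataclass(frozen=True)
class StripeSpec:
    """AP stripe pattern of a pair-rule gene.

    Seven Gaussian-profile stripes (FWHM ``width``) at regular ``period``
    spacing along AP, centred on the chart, times a DV modulation with
    maximum 1 at the ventral midline and minimum ``dv_min`` at the dorsal
    pole (set ``dv_min=1`` for no modulation).  ``shape`` is the
    super-Gaussian exponent of the bump (1 = Gaussian).
    """

    n_stripes: int = 7
    period: float = 50.0
    width: float = 20.0
    shape: float = 1.0
    dv_min: float = 0.1
    phase: float = 0.0


def stripe_centers(chart: ChartGrid, spec: StripeSpec) -> np.ndarray:
    offsets = (np.arange(spec.n_stripes) - (spec.n_stripes - 1) / 2.0) * spec.period
    return chart.ap_length / 2.0 + offsets + spec.phase


def dv_modulation_profile(chart: ChartGrid, dv_min: float) -> np.ndarray:
    """Intensity modulation over y: 1 at the ventral midline, dv_min at
    the dorsal pole, cosine-smooth and DV-periodic."""
    y = chart.y
    return dv_min + (1.0 - dv_min) * 0.5 * (
        1.0 + np.cos(2.0 * np.pi * y / chart.dv_circumference)
    )


def make_prg_pattern(chart: ChartGrid, stripe_spec: StripeSpec = StripeSpec()) -> np.ndarray:
    """Non-negative intensity map of a striped PRG expression pattern.

    At t = 0 stripes are parallel to the DV axis.  Raises if the stripes
    do not fit in the chart's AP extent.
    """
    spec = stripe_spec
    if spec.n_stripes < 1 or spec.period <= 0 or spec.width <= 0:
        raise ValueError("stripe count, period and width must be positive")
    if spec.n_stripes * spec.period > chart.ap_length:
        raise ValueError("stripes do not fit within the AP extent")
    centers = stripe_centers(chart, spec)
    sigma = spec.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sigma
    x = chart.x
    profile = np.zeros_like(x)
    for c in centers:
        profile += np.exp(-0.5 * np.abs((x - c) / sigma) ** (2.0 * spec.shape))
    pattern = dv_modulation_profile(chart, spec.dv_min)[:, None] * profile[None, :]
    peak = pattern.max()
    return pattern / peak if peak > 0 else pattern


def make_prg_patterns(
    chart: ChartGrid,
    stripe_spec: StripeSpec = StripeSpec(),
    phases: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-gene stripe patterns, slightly out of register via AP phase
    offsets (μm).  Default emulates Runt / Eve / Ftz."""
    if phases is None:
        phases = {"runt": 0.0, "eve": 10.0, "ftz": -10.0}
    out = {}
    for gene, ph in phases.items():
        spec = StripeSpec(
            n_stripes=stripe_spec.n_stripes,
            period=stripe_spec.period,
            width=stripe_spec.width,
            shape=stripe_spec.shape,
            dv_min=stripe_spec.dv_min,
            phase=ph,
        )
        out[gene] = make_prg_pattern(chart, spec)
    return out


# ---------------------------------------------------------------------------
# junction ensembles


@dataclass
class GroundTruth:
    """True per-junction state of a simulated ensemble.

    Arrays are (n_times, n_junctions): positions, the *unwrapped*
    junction angle (not reduced to the nematic range) and the myosin
    level.  Each emitted segment traces back to one record via
    (time index, junction index).  ``stripe_label`` is filled when a
    stripe label image is supplied.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta_unwrapped: np.ndarray
    myosin: np.ndarray
    tau: float
    params: ModelParams
    birth_time: float
    stripe_label: np.ndarray | None = None

    def label_junctions(self, label_image: np.ndarray, chart: ChartGrid) -> np.ndarray:
        """Stripe label at each junction's initial position."""
        ix = np.clip(np.round(self.x[0] / chart.dx).astype(int), 0, chart.nx - 1)
        iy = np.mod(np.round(self.y[0] / chart.dy).astype(int), chart.ny)
        self.stripe_label = np.asarray(label_image)[iy, ix]
        return self.stripe_label

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tau": self.tau,
            "birth_time": self.birth_time,
            "n_junctions": int(self.x.shape[1]),
            "times": self.times.tolist(),
            "params": asdict(self.params),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _angular_source(params: ModelParams, angle_deg):
    """Angle-dependent part of the recruitment rate (unit amplitude)."""
    from .nematic import nematic_difference

    delta = nematic_difference(angle_deg, params.source_direction)
    return np.exp(-0.5 * (delta / params.source_width) ** 2)


def simulate_junction_ensemble(
    chart: ChartGrid,
    flow: VelocityField,
    model_params: ModelParams,
    n_junctions: int = 2000,
    t_span: tuple[float, float] = (0.0, 35.0),
    seed: int = 0,
    dt: float = 0.1,
    sample_every: float = 1.0,
    length_um: float = 5.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a junction ensemble under the static-source model.

    Junction midpoints advect passively with the flow; each junction's
    angle integrates dθ/dt = local rotation rate; its myosin level
    integrates dm/dt = s₀·s(θ) − m/τ with the Gaussian static source of
    ``model_params``.  The source *direction* is fixed in the embryo
    frame; the amplitude s₀ is a cell-intrinsic recruitment sensitivity,
    evaluated from the DV profile at each junction's birth position and
    carried with the junction thereafter (gene-expression-like cues
    advect with cells).  Junctions persist for the whole run (only m
    changes); lengths are fixed.  Initial angles are uniform on
    (−90, 90] and myosin starts at the zero-flow stationary level.

    Returns a segment table sampled every ``sample_every`` minutes (one
    row per junction per sample time, columns ``SEGMENT_COLUMNS``) and
    the ground truth.
    """
    if model_params.tau <= 0:
        raise ValueError("tau must be positive")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    if flow.nt > 1 and (t0 < flow.times[0] - 1e-9 or t1 > flow.times[-1] + 1e-9):
        raise ValueError("t_span outside the flow's time coverage")
    rng = np.random.default_rng(seed)
    rr = rotation_rate(flow)
    tau = model_params.tau

    # positions: uniform over the germband mask, with sub-pixel jitter
    iy, ix = np.nonzero(chart.germband_mask)
    pick = rng.integers(0, iy.size, size=n_junctions)
    px = ix[pick] * chart.dx + rng.uniform(-0.5, 0.5, n_junctions) * chart.dx
    py = iy[pick] * chart.dy + rng.uniform(-0.5, 0.5, n_junctions) * chart.dy
    px = np.clip(px, 0.0, (chart.nx - 1) * chart.dx)
    py = np.mod(py, chart.dv_circumference)

    theta = rng.uniform(-90.0, 90.0, size=n_junctions)  # unwrapped from here on
    # cell-intrinsic recruitment amplitude, frozen at the birth position
    amp0 = np.exp(
        -np.asarray(chart.dv_distance(py)) / model_params.source_length_scale
    ) * model_params.source_amplitude
    m = tau * amp0 * _angular_source(model_params, theta)

    sample_times = np.arange(t0, t1 + 1e-9, sample_every)
    nt = sample_times.size
    gt_x = np.empty((nt, n_junctions))
    gt_y = np.empty((nt, n_junctions))
    gt_th = np.empty((nt, n_junctions))
    gt_m = np.empty((nt, n_junctions))

    def record(k):
        gt_x[k], gt_y[k], gt_th[k], gt_m[k] = px, py, theta, m

    record(0)
    next_k = 1
    t = t0
    nstep = int(np.ceil((t1 - t0) / dt))
    for _ in range(nstep):
        h = min(dt, t1 - t)
        if h <= 0:
            break
        # RK4 on (x, y, θ); exact exponential (integrating-factor) step
        # for m, which is stiff when τ ≪ dt
        def rhs(xs, ys, tq):
            vx, vy = flow.sample(xs, ys, tq)
            rho = rr.sample(xs, ys, tq)
            return vx, vy, rho

        a1 = rhs(px, py, t)
        th_mid1 = theta + 0.5 * h * a1[2]
        a2 = rhs(px + 0.5 * h * a1[0], py + 0.5 * h * a1[1], t + 0.5 * h)
        th_mid2 = theta + 0.5 * h * a2[2]
        a3 = rhs(px + 0.5 * h * a2[0], py + 0.5 * h * a2[1], t + 0.5 * h)
        th_end = theta + h * a3[2]
        a4 = rhs(px + h * a3[0], py + h * a3[1], t + h)
        # Simpson average of the source along the step
        s_bar = amp0 * (
            _angular_source(model_params, theta)
            + 2.0 * _angular_source(model_params, 0.5 * (th_mid1 + th_mid2))
            + _angular_source(model_params, th_end)
        ) / 4.0
        decay = np.exp(-h / tau)
        m = (m - tau * s_bar) * decay + tau * s_bar
        px = px + (h / 6.0) * (a1[0] + 2 * a2[0] + 2 * a3[0] + a4[0])
        py = py + (h / 6.0) * (a1[1] + 2 * a2[1] + 2 * a3[1] + a4[1])
        theta = theta + (h / 6.0) * (a1[2] + 2 * a2[2] + 2 * a3[2] + a4[2])
        px = np.clip(px, 0.0, (chart.nx - 1) * chart.dx)
        py = np.mod(py, chart.dv_circumference)
        t += h
        while next_k < nt and t >= sample_times[next_k] - 1e-9:
            record(next_k)
            next_k += 1

    from .nematic import canonical_angle

    frames = []
    for k, ts in enumerate(sample_times):
        frames.append(
            pd.DataFrame(
                {
                    "t_min": ts,
                    "x_um": gt_x[k],
                    "y_um": gt_y[k],
                    "angle_deg": canonical_angle(gt_th[k]),
                    "intensity": np.maximum(gt_m[k], 0.0),
                    "length_um": length_um,
                }
            )
        )
    segments = pd.concat(frames, ignore_index=True)[SEGMENT_COLUMNS]
    truth = GroundTruth(
        times=sample_times,
        x=gt_x,
        y=gt_y,
        theta_unwrapped=gt_th,
        myosin=gt_m,
        tau=tau,
        params=model_params,
        birth_time=t0,
    )
    return segments, truth


# ---------------------------------------------------------------------------
# image rendering


def render_junction_image(
    segments,
    chart: ChartGrid,
    line_width: float = 1.5,
    psf_sigma: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render segments as a fluorescence-like image on the chart grid.

    Each segment deposits intensity proportional to its myosin level,
    uniformly along its length; the image is blurred by the line width
    and the point-spread function and additive Gaussian noise is applied.
    Bit-identical for a fixed seed.
    """
    if line_width < 0 or psf_sigma < 0 or noise_sigma < 0:
        raise ValueError("widths and sigmas must be non-negative")
    from .junctions import segments_to_frame

    df = segments_to_frame(segments)
    img = np.zeros((chart.ny, chart.nx))
    step = 0.25  # μm between deposits along a segment
    for r in df.itertuples():
        th = np.deg2rad(r.angle_deg)
        dx, dy = -np.sin(th), np.cos(th)
        npts = max(2, int(np.ceil(r.length_um / step)) + 1)
        tpar = np.linspace(-r.length_um / 2.0, r.length_um / 2.0, npts)
        xs = r.x_um + tpar * dx
        ys = np.mod(r.y_um + tpar * dy, chart.dv_circumference)
        # bilinear deposit, amplitude ∝ intensity (independent of sampling density)
        fx = np.clip(xs / chart.dx, 0.0, chart.nx - 1.001)
        fy = ys / chart.dy
        ix0 = np.floor(fx).astype(int)
        iy0 = np.floor(fy).astype(int) % chart.ny
        tx = fx - np.floor(fx)
        ty = fy - np.floor(fy)
        amp = r.intensity / npts * (r.length_um / step)
        np.add.at(img, (iy0, ix0), amp * (1 - tx) * (1 - ty))
        np.add.at(img, (iy0, np.minimum(ix0 + 1, chart.nx - 1)), amp * tx * (1 - ty))
        np.add.at(img, ((iy0 + 1) % chart.ny, ix0), amp * (1 - tx) * ty)
        np.add.at(
            img, ((iy0 + 1) % chart.ny, np.minimum(ix0 + 1, chart.nx - 1)), amp * tx * ty
        )
    sigma_px = np.hypot(line_width / 2.355, psf_sigma) / chart.dx
    if sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma_px, mode=("wrap", "nearest"))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# FRAP traces


@dataclass(frozen=True)
class FrapParams:
    """Parameters of the synthetic FRAP recovery curve.

    The bleached junction recovers as
    I(t) = 1 − (1 − f_mob)·[A_f e^{−t/τ_f} + (1 − A_f) e^{−t/τ_s}],
    so the first post-bleach frame sits at the mobile fraction f_mob
    (≈ 50% immediate recovery for the wild-type default) and recovery is
    complete (≥ 99% of pre-bleach) by ≈ 210 s.  An optional sinusoidal
    term emulates junctional myosin oscillations (~60 s period).
    """

    mobile_fraction: float = 0.5
    tau_fast_s: float = 8.0
    tau_slow_s: float = 60.0
    fast_amplitude: float = 0.5
    oscillation_amplitude: float = 0.0
    oscillation_period_s: float = 60.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.tau_fast_s <= 0 or self.tau_slow_s <= 0:
            raise ValueError("timescales must be positive")
        if not (0.0 <= self.fast_amplitude <= 1.0):
            raise ValueError("fast_amplitude must lie in [0, 1]")

    def closed_form(self, t_s):
        t = np.asarray(t_s, dtype=float)
        rec = 1.0 - (1.0 - self.mobile_fraction) * (
            self.fast_amplitude * np.exp(-t / self.tau_fast_s)
            + (1.0 - self.fast_amplitude) * np.exp(-t / self.tau_slow_s)
        )
        if self.oscillation_amplitude:
            rec = rec + self.oscillation_amplitude * np.sin(
                2.0 * np.pi * t / self.oscillation_period_s
            ) * (1.0 - np.exp(-t / self.tau_fast_s))
        return rec


def make_frap_trace(
    frap_params: FrapParams = FrapParams(),
    dt: float = 1.5,
    duration: float = 300.0,
    seed: int = 0,
    n_prebleach: int = 5,
) -> FrapTrace:
    """Synthesize a normalized FRAP trace.

    ``n_prebleach`` frames at intensity 1 precede the bleach (negative
    times); t = 0 is the first post-bleach frame, sampled every ``dt``
    seconds (default 1.5 s) for ``duration`` seconds.
    """
    if duration < dt:
        raise ValueError("duration must cover at least one post-bleach frame")
    t_post = np.arange(0.0, duration + 1e-9, dt)
    t_pre = -dt * np.arange(n_prebleach, 0, -1)
    t = np.concatenate([t_pre, t_post])
    intensity = np.concatenate(
        [np.ones_like(t_pre), frap_params.closed_form(t_post)]
    )
    if frap_params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, frap_params.noise_sigma, t.shape)
    return FrapTrace(t_s=t, intensity=np.maximum(intensity, 0.0))
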