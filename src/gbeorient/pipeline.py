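"""End-to-end orchestration of synthetic-embryo runs.

A run generates a synthetic embryo (chart, flow, stripe patterns,
junction ensemble, FRAP trace) for a genotype preset, pushes it through
the analysis stages (stripe segmentation and orientation, flow
autocorrelation, myosin anisotropy fields, the τ fit, FRAP fitting) and
collects the summary quantities into a machine-readable report.

Genotype presets encode only what is documented for each mutant:

* ``wt`` — generator defaults.
* ``twist`` — tissue flow amplitude halved (GBE speed reduced by a
  factor of two), everything else as wild type.
* ``eve`` — myosin effective lifetime reduced to 2.5 min, flow reduced,
  recruitment amplitude reduced, and an abrupt envelope break at 10 min
  (the break's functional form is illustrative, not measured).
* ``fat2`` — rounder egg: DV circumference × 1.3, shorter AP axis,
  reduced flow; the myosin recruitment zone keeps its wild-type DV
  extent while stripes still reach the dorsal pole.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import flowfield, junctions, kinetics, sourcemodel, stripes, synthgen
from .chart import ChartGrid, make_chart
from .nematic import OrientationField, nematic_difference, nematic_mean

__all__ = ["RunConfig", "RunReport", "run_pipeline", "stripe_region_timeseries"]

GENOTYPES = ("wt", "twist", "eve", "fat2", "custom")


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of one synthetic-embryo analysis run."""

    genotype: str = "wt"
    seed: int = 0
    out_dir: str | None = None

    # chart
    ap_length: float = 450.0
    dv_circumference: float = 500.0
    dx: float = 1.0
    dy: float = 1.0
    germband_dv_extent: float = 175.0

    # flow
    flow_amplitude: float = 1.0
    envelope_knots: tuple[tuple[float, float], ...] | None = None

    # model / ensemble
    tau: float = 5.0
    source_width: float = 15.0
    source_amplitude: float = 1.0
    source_length_scale: float = 76.0
    n_junctions: int = 2000
    t_end: float = 35.0

    # analysis
    anisotropy_radius_um: float = 20.0
    fit_window: tuple[float, float] = (10.0, 35.0)
    fit_stride: int = 3
    tau_grid_max: float = 20.0
    autocorr_times: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
    stripe_stride: int = 3

    # FRAP
    frap_tau_fast_s: float = 8.0
    frap_tau_slow_s: float = 60.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype preset {self.genotype!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_preset(cls, genotype: str, seed: int = 0, **overrides) -> "RunConfig":
        presets: dict[str, dict] = {
            "wt": {},
            "custom": {},
            "twist": {"flow_amplitude": 0.5},
            "eve": {
                "tau": 2.5,
                "flow_amplitude": 0.5,
                "source_amplitude": 0.5,
                "frap_tau_slow_s": 30.0,
                # abrupt kinetics change at 10 min: the envelope jumps to
                # its plateau quickly instead of ramping for 10 min
                "envelope_knots": (
                    (0.0, 0.0),
                    (10.0, 0.0),
                    (12.0, 1.0),
                    (25.0, 1.0),
                    (35.0, 0.0),
                ),
            },
            "fat2": {
                "dv_circumference": 650.0,
                "ap_length": 400.0,
                "flow_amplitude": 0.5,
            },
        }
        if genotype not in presets:
            raise ValueError(f"unknown genotype preset {genotype!r}")
        kwargs = {"genotype": genotype, "seed": seed, **presets[genotype]}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    summary: dict
    stripe_timeseries: pd.DataFrame | None = None
    out_dir: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary, indent=2, sort_keys=True))


def _coarsen_chart(chart: ChartGrid, stride: int) -> ChartGrid:
    mask = chart.germband_mask[::stride, ::stride]
    return ChartGrid(
        nx=mask.shape[1],
        ny=mask.shape[0],
        dx=chart.dx * stride,
        dy=chart.dy * stride,
        germband_mask=mask,
    )


def _coarsen_velocity(vf: flowfield.VelocityField, chart_c: ChartGrid, stride: int):
    return flowfield.VelocityField(
        chart=chart_c,
        times=vf.times.copy(),
        vx=vf.vx[:, ::stride, ::stride],
        vy=vf.vy[:, ::stride, ::stride],
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one full synthetic run and return the report.

    Stages: generator → stripe analysis + flow analysis → myosin
    anisotropy fields → static-source τ fit → FRAP kinetics.  Identical
    config and seed give an identical report.  When ``config.out_dir``
    is set, artifacts (report JSON, junction table CSV, stripe label
    TIFF, per-stripe time series CSV, FRAP trace CSV, correlation
    matrices CSV) are written there.
    """
    cfg = config
    rng_seed = int(cfg.seed)
    summary: dict = {"config": dataclasses.asdict(cfg)}

    # --- generator -------------------------------------------------------
    chart = make_chart(
        ap_length=cfg.ap_length,
        dv_circumference=cfg.dv_circumference,
        dx=cfg.dx,
        dy=cfg.dy,
        germband_dv_extent=cfg.germband_dv_extent,
    )
    flow_spec = synthgen.default_flow_spec(chart, amplitude=cfg.flow_amplitude)
    if cfg.envelope_knots is not None:
        flow_spec = dataclasses.replace(flow_spec, envelope_knots=cfg.envelope_knots)
    flow_times = np.arange(0.0, max(cfg.t_end, 35.0) + 11.0, 1.0)
    flow = synthgen.make_flow_field(chart, flow_spec, flow_times)
    rr = flowfield.rotation_rate(flow)

    params = sourcemodel.ModelParams(
        tau=cfg.tau,
        source_width=cfg.source_width,
        source_amplitude=cfg.source_amplitude,
        source_length_scale=cfg.source_length_scale,
    )
    segments, truth = synthgen.simulate_junction_ensemble(
        chart,
        flow,
        params,
        n_junctions=cfg.n_junctions,
        t_span=(0.0, cfg.t_end),
        seed=rng_seed,
    )
    patterns = synthgen.make_prg_patterns(chart)
    runt0 = patterns["runt"]

    # --- stripe analysis -------------------------------------------------
    summary["gradient_band_count"] = stripes.count_gradient_bands(runt0, chart)
    stripe_set = stripes.segment_stripes(runt0, chart)
    lines = stripes.interstripe_lines(stripe_set)
    summary["n_stripes"] = stripe_set.n_stripes
    summary["n_interstripe_lines"] = len(lines)

    # myosin intensity map at flow onset vs PRG gradient regression
    onset = segments[np.isclose(segments.t_min, cfg.fit_window[0])]
    myo_field = junctions.anisotropy_field(
        onset, chart, radius_um=cfg.anisotropy_radius_um
    )
    regress = stripes.prg_regression(
        myo_field.weight,
        {g: stripes.gradient_magnitude(p, chart) for g, p in patterns.items()},
        chart.germband_mask,
    )
    summary["regression"] = regress.to_dict()

    # DV decay profiles (myosin weight vs Runt expression)
    myo_profile = stripes.dv_profile(myo_field.weight, chart)
    runt_profile = stripes.dv_profile(runt0, chart)
    summary["myosin_dv_extent_um"] = myo_profile.support_extent(0.1)
    summary["runt_dv_extent_um"] = runt_profile.support_extent(0.1)

    # --- flow analysis ---------------------------------------------------
    env = flow_spec.envelope(flow.times)
    active = env > 0
    flow_corr = None
    if active.sum() >= 2:
        sub_idx = np.nonzero(active)[0]
        sub_flow = flowfield.VelocityField(
            chart=chart,
            times=flow.times[sub_idx],
            vx=flow.vx[sub_idx],
            vy=flow.vy[sub_idx],
        )
        flow_corr = flowfield.direction_autocorrelation(sub_flow)
        summary["flow_direction_autocorr_min"] = float(np.nanmin(flow_corr.values))
    else:
        summary["flow_direction_autocorr_min"] = None
    rot_mag = np.abs(rr.values)
    summary["rotation_rate_peak_deg_min"] = float(rot_mag[:, chart.germband_mask].max())
    summary["mean_abs_rotation_series"] = {
        "t_min": flow.times.tolist(),
        "value_deg_min": flowfield.spatial_average(
            rot_mag, chart.germband_mask
        ).tolist(),
    }
    summary["mean_speed_series"] = {
        "t_min": flow.times.tolist(),
        "value_um_min": flowfield.spatial_average(
            flow.speed(), chart.germband_mask
        ).tolist(),
    }

    # --- myosin orientation fields and τ fit ------------------------------
    obs_times = np.arange(cfg.fit_window[0], cfg.t_end + 1e-9, 1.0)
    observed: list[OrientationField] = []
    for t in obs_times:
        frame = segments[np.isclose(segments.t_min, t)]
        f = junctions.anisotropy_field(
            frame, chart, radius_um=cfg.anisotropy_radius_um, estimator="recentered"
        )
        f.time_min = float(t)
        observed.append(f)

    fit = sourcemodel.fit_tau(
        observed,
        rr,
        tau_grid=np.arange(0.5, cfg.tau_grid_max + 1e-9, 0.5),
        window=cfg.fit_window,
        stride=cfg.fit_stride,
        smooth_radius_um=cfg.anisotropy_radius_um,
    )
    summary["tau_fit"] = fit.to_dict()

    # rotation-adjusted angle with the fitted tau
    if fit.identifiable:
        preds = sourcemodel.predict_deflection_field(
            rr, fit.tau_hat, output_times=obs_times
        )
        adj_means = []
        for f, p in zip(observed, preds):
            adj = sourcemodel.rotation_adjusted_angle(f, p)
            w = adj.weight * chart.germband_mask
            ok = np.isfinite(adj.angle_deg) & (w > 0)
            adj_means.append(
                float(np.average(np.abs(adj.angle_deg[ok]), weights=w[ok]))
                if ok.any()
                else np.nan
            )
        summary["mean_abs_adjusted_angle_deg"] = {
            "t_min": obs_times.tolist(),
            "value_deg": adj_means,
        }

    # myosin orientation autocorrelation (nearly static pattern)
    ac_times = [t for t in cfg.autocorr_times if cfg.fit_window[0] <= t <= cfg.t_end]
    myo_ac_fields = [observed[int(round(t - cfg.fit_window[0]))] for t in ac_times]
    myo_corr = stripes.nematic_autocorrelation(myo_ac_fields)
    summary["myosin_orientation_autocorr_final"] = float(myo_corr.values[0, -1])

    # stripe orientation autocorrelation (pattern advected by the flow)
    chart_c = _coarsen_chart(chart, cfg.stripe_stride)
    flow_c = _coarsen_velocity(flow, chart_c, cfg.stripe_stride)
    runt0_c = runt0[:: cfg.stripe_stride, :: cfg.stripe_stride]
    runt_series = flowfield.advect_scalar_series(runt0_c, flow_c, np.array(ac_times))
    stripe_fields = []
    for t, f in zip(ac_times, runt_series):
        of = stripes.stripe_angle_field(f, chart_c)
        of.time_min = float(t)
        of.weight *= chart_c.germband_mask
        stripe_fields.append(of)
    stripe_corr = stripes.nematic_autocorrelation(stripe_fields)
    summary["stripe_orientation_autocorr_final"] = float(stripe_corr.values[0, -1])

    # --- per-stripe regional time series ----------------------------------
    ts = stripe_region_timeseries(
        stripe_set,
        flow,
        segments,
        rr,
        fit.tau_hat if fit.identifiable else cfg.tau,
        times=obs_times,
        stride=cfg.stripe_stride,
        radius_um=cfg.anisotropy_radius_um,
    )
    summary["stripe_timeseries_stripes"] = sorted(
        int(s) for s in ts["stripe"].unique()
    )

    # --- kinetics ---------------------------------------------------------
    frap_params = synthgen.FrapParams(
        tau_fast_s=cfg.frap_tau_fast_s,
        tau_slow_s=cfg.frap_tau_slow_s,
        noise_sigma=0.02,
    )
    trace = synthgen.make_frap_trace(frap_params, seed=rng_seed + 1)
    frap_fit = kinetics.fit_frap(trace)
    summary["frap_fit"] = frap_fit.to_dict()
    summary["frap_recovery_time_s"] = kinetics.recovery_time(trace, 0.99)
    summary["lifetime_reconciliation"] = kinetics.reconcile_lifetimes(
        frap_fit, fit.tau_hat if fit.identifiable else None
    )

    # --- artifacts --------------------------------------------------------
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        segments.to_csv(out / "junctions.csv", index=False)
        stripe_set.to_label_tiff(out / "runt_stripes.tif")
        ts.to_csv(out / "stripe_timeseries.csv", index=False)
        trace.to_csv(out / "frap_trace.csv")
        if flow_corr is not None:
            flow_corr.to_csv(out / "flow_direction_autocorr.csv")
        myo_corr.to_csv(out / "myosin_orientation_autocorr.csv")
        stripe_corr.to_csv(out / "stripe_orientation_autocorr.csv")
        report = RunReport(summary=summary, stripe_timeseries=ts, out_dir=str(out))
        report.to_json(out / "report.json")
        return report
    return RunReport(summary=summary, stripe_timeseries=ts, out_dir=None)


def stripe_region_timeseries(
    stripe_set: stripes.StripeSet,
    flow: flowfield.VelocityField,
    segments: pd.DataFrame,
    rr: flowfield.RotationRateField,
    tau: float,
    times: np.ndarray,
    stride: int = 3,
    radius_um: float = 20.0,
    lateral_half: bool = True,
) -> pd.DataFrame:
    """Per-stripe time series of Runt, myosin and adjusted angles.

    Stripe regions are segmented at t = 0 and advected forward with the
    flow to define the regions at each minute; within each region the
    weighted nematic means of the Runt stripe direction, the myosin
    anisotropy direction, their difference, and the rotation-rate
    adjusted myosin angle are recorded.  By default the analysis is
    restricted to one lateral half of the embryo (0 < y < circumference/2),
    matching single-side imaging — the two halves are mirror images with
    opposite rotation sense, so whole-circumference means cancel.
    Regions that empty (advect off the chart) yield NaN rows, flagged in
    the ``truncated`` column.
    """
    ch = stripe_set.chart
    chart_c = _coarsen_chart(ch, stride)
    flow_c = _coarsen_velocity(flow, chart_c, stride)
    labels0 = stripe_set.labels[::stride, ::stride].astype(float)
    runt0 = stripe_set.smoothed[::stride, ::stride]
    times = np.asarray(times, dtype=float)
    label_series = flowfield.advect_scalar_series(
        labels0, flow_c, times, order="nearest"
    )
    runt_series = flowfield.advect_scalar_series(runt0, flow_c, times)
    preds = sourcemodel.predict_deflection_field(rr, tau, output_times=times)
    half_mask = np.ones(chart_c.germband_mask.shape, dtype=bool)
    if lateral_half:
        yc = chart_c.y
        half_mask = ((yc > 0) & (yc < chart_c.dv_circumference / 2.0))[:, None]
        half_mask = np.broadcast_to(half_mask, chart_c.germband_mask.shape)
    rows = []
    for t, labs, runt_t, pred in zip(times, label_series, runt_series, preds):
        runt_of = stripes.stripe_angle_field(runt_t, chart_c)
        frame = segments[np.isclose(segments.t_min, t)]
        myo = junctions.anisotropy_field(
            frame, ch, radius_um=radius_um, estimator="recentered"
        )
        myo_ang = myo.angle_deg[::stride, ::stride]
        myo_w = myo.weight[::stride, ::stride]
        pred_c = pred.angle_deg[::stride, ::stride]
        for s in range(1, stripe_set.n_stripes + 1):
            region = (labs == s) & chart_c.germband_mask & half_mask
            if not region.any():
                rows.append((t, s, np.nan, np.nan, np.nan, np.nan, True))
                continue
            r_ok = region & np.isfinite(runt_of.angle_deg) & (runt_of.weight > 0)
            runt_ang = (
                nematic_mean(runt_of.angle_deg[r_ok], runt_of.weight[r_ok])
                if r_ok.any()
                else np.nan
            )
            m_ok = region & np.isfinite(myo_ang) & (myo_w > 0)
            myo_mean = (
                float(np.average(myo_ang[m_ok], weights=myo_w[m_ok]))
                if m_ok.any()
                else np.nan
            )
            adj = (
                float(
                    np.average(
                        nematic_difference(myo_ang[m_ok], pred_c[m_ok]),
                        weights=myo_w[m_ok],
                    )
                )
                if m_ok.any()
                else np.nan
            )
            myo_vs_runt = (
                nematic_difference(myo_mean, runt_ang)
                if np.isfinite(myo_mean) and np.isfinite(runt_ang)
                else np.nan
            )
            rows.append((t, s, runt_ang, myo_mean, myo_vs_runt, adj, False))
    return pd.DataFrame(
        rows,
        columns=[
            "t_min",
            "stripe",
            "runt_dv_angle_deg",
            "myosin_dv_angle_deg",
            "myosin_runt_angle_deg",
            "adjusted_angle_deg",
            "truncated",
        ],
    )
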