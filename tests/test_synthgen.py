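"""Generator tests: chart conventions, flow calibration, stripe
patterns, junction-ensemble physics, rendering, FRAP traces."""

import numpy as np
import pandas as pd
import pytest

import gbeorient as g
from gbeorient import flowfield, junctions, sourcemodel, synthgen
from gbeorient.nematic import canonical_angle, nematic_mean_std

from conftest import (
    exponential_age_oracle,
    open_chart,
    oracle_circular_mean,
)


class TestChart:
    def test_wild_type_defaults(self, wt_chart):
        assert (wt_chart.nx, wt_chart.ny) == (450, 500)
        assert wt_chart.ap_length == 450.0
        assert wt_chart.dv_circumference == 500.0
        # dorsal midline sits at y = circumference / 2
        assert wt_chart.y[250] == 250.0
        assert wt_chart.dv_distance(250.0) == 250.0
        assert wt_chart.dv_distance(499.0) == 1.0

    def test_fat2_scaling(self):
        fat2 = g.make_chart(ap_length=400.0, dv_circumference=500.0 * 1.3)
        wt = g.make_chart()
        assert fat2.dv_circumference == pytest.approx(1.3 * wt.dv_circumference)
        assert fat2.ap_length < wt.ap_length

    @pytest.mark.parametrize(
        "kwargs", [{"dx": 0.0}, {"dy": -1.0}, {"ap_length": 0.0}]
    )
    def test_degenerate_inputs_raise(self, kwargs):
        with pytest.raises(ValueError):
            g.make_chart(**kwargs)


class TestFlow:
    def test_zero_strengths_give_zero_field(self, wt_chart):
        spec = synthgen.FlowSpec(vortices=(), convergence_amplitude=0.0)
        flow = synthgen.make_flow_field(wt_chart, spec, np.array([20.0]))
        assert np.all(flow.vx == 0) and np.all(flow.vy == 0)

    def test_rotation_rate_calibration(self, wt_chart, wt_rotation):
        """Peak ≈ 5°/min near the posterior vortices, < 2°/min anteriorly."""
        peak = wt_rotation.frame_interp(20.0)
        posterior = np.abs(peak[:, wt_chart.x > 300])
        anterior = np.abs(peak[:, wt_chart.x < 200])
        assert posterior.max() == pytest.approx(5.0, abs=0.25)
        assert anterior.max() < 2.0

    def test_vorticity_mirror_antisymmetry(self, wt_chart, wt_flow):
        """Mirror vortex pairs make ω antisymmetric under y → −y."""
        w = flowfield.vorticity(wt_flow)[20]
        idx = (-np.arange(wt_chart.ny)) % wt_chart.ny
        assert np.abs(w + w[idx, :]).max() < 1e-10 * max(1.0, np.abs(w).max() * 1e10)
        assert np.allclose(w, -w[idx, :], atol=1e-12)

    def test_envelope_zero_before_onset(self, wt_flow):
        spec = synthgen.default_flow_spec(g.make_chart())
        assert np.all(spec.envelope(np.array([0.0, 5.0, 9.9])) == 0.0)
        assert spec.envelope(22.0) == 1.0
        assert spec.envelope(40.0) == 0.0

    def test_direction_stationarity(self, wt_flow):
        """Only the envelope varies: direction autocorrelation is ≥ 0.95
        between any two times with g > 0."""
        active = np.nonzero(wt_flow.speed().max(axis=(1, 2)) > 0)[0]
        sub = flowfield.VelocityField(
            chart=wt_flow.chart,
            times=wt_flow.times[active],
            vx=wt_flow.vx[active],
            vy=wt_flow.vy[active],
        )
        corr = flowfield.direction_autocorrelation(sub)
        assert np.nanmin(corr.values) >= 0.95

    def test_vortex_outside_chart_raises(self, wt_chart):
        spec = synthgen.FlowSpec(vortices=(synthgen.Vortex((999.0, 90.0), 5.0),))
        with pytest.raises(ValueError):
            synthgen.make_flow_field(wt_chart, spec, np.array([0.0]))


class TestStripePatterns:
    def test_seven_stripes_above_half_max(self, wt_chart):
        from scipy import ndimage

        pattern = synthgen.make_prg_pattern(wt_chart)
        assert pattern.min() >= 0
        profile = pattern[0]  # ventral row, full modulation
        labels, n = ndimage.label(profile >= 0.5 * profile.max())
        assert n == 7

    def test_flat_dv_modulation(self, wt_chart):
        spec = synthgen.StripeSpec(dv_min=1.0)
        pattern = synthgen.make_prg_pattern(wt_chart, spec)
        assert np.allclose(pattern, pattern[0][None, :])

    def test_dv_modulation_minimal_at_dorsal_pole(self, wt_chart):
        pattern = synthgen.make_prg_pattern(wt_chart)
        ventral = pattern[0]
        dorsal = pattern[250]
        assert dorsal.max() < ventral.max()
        assert dorsal.max() == pytest.approx(0.1 * ventral.max(), rel=0.05)

    def test_phase_offset_shifts_cross_correlation(self, wt_chart):
        """Two genes offset by 10 μm: brute-force cross-correlation of
        their AP profiles peaks at a 10 μm lag."""
        a = synthgen.make_prg_pattern(wt_chart, synthgen.StripeSpec(phase=0.0))[0]
        b = synthgen.make_prg_pattern(wt_chart, synthgen.StripeSpec(phase=10.0))[0]
        lags = np.arange(-30, 31)
        cc = [
            np.dot(a[30:-30], b[30 + lag : len(b) - 30 + lag]) for lag in lags
        ]
        assert lags[int(np.argmax(cc))] == 10

    def test_too_many_stripes_raise(self, wt_chart):
        with pytest.raises(ValueError):
            synthgen.make_prg_pattern(
                wt_chart, synthgen.StripeSpec(n_stripes=10, period=50.0)
            )


def _uniform_rotation_flow(chart, rho_deg_min, times):
    """v = (0, ω·x) has uniform curl ω = 2·ρ everywhere."""
    omega = np.deg2rad(2.0 * rho_deg_min)
    X, _ = chart.meshgrid()
    vy = omega * X
    nt = len(times)
    return flowfield.VelocityField(
        chart=chart,
        times=np.asarray(times, dtype=float),
        vx=np.zeros((nt,) + X.shape),
        vy=np.broadcast_to(vy, (nt,) + X.shape).copy(),
    )


class TestJunctionEnsemble:
    def test_zero_flow_stationary_state(self, wt_chart):
        """No rotation: intensity-weighted angles follow the source
        profile — circular mean 0 ± 1°, spread ≈ the source width."""
        spec = synthgen.FlowSpec(vortices=(), convergence_amplitude=0.0)
        flow = synthgen.make_flow_field(wt_chart, spec, np.arange(0.0, 41.0, 5.0))
        params = sourcemodel.ModelParams(tau=5.0, source_width=15.0)
        segs, _ = synthgen.simulate_junction_ensemble(
            wt_chart, flow, params, n_junctions=5000, t_span=(0.0, 40.0), seed=11
        )
        last = segs[np.isclose(segs.t_min, 40.0)]
        mean, std = nematic_mean_std(
            last["angle_deg"].to_numpy(), last["intensity"].to_numpy()
        )
        assert abs(mean) <= 1.0
        assert std == pytest.approx(15.0, abs=2.0)

    def test_steady_state_deflection_matches_age_oracle(self, wt_chart):
        """ρ = 3°/min, τ = 5 min: the intensity-weighted mean deflection
        matches the exponential-age integral (≈ ρτ = 15°)."""
        times = np.arange(0.0, 61.0, 5.0)
        flow = _uniform_rotation_flow(wt_chart, 3.0, times)
        params = sourcemodel.ModelParams(tau=5.0, source_width=15.0)
        segs, _ = synthgen.simulate_junction_ensemble(
            wt_chart, flow, params, n_junctions=5000, t_span=(0.0, 60.0), seed=4
        )
        last = segs[np.isclose(segs.t_min, 60.0)]
        mean, _ = nematic_mean_std(
            last["angle_deg"].to_numpy(), last["intensity"].to_numpy()
        )
        theta, dens = exponential_age_oracle(3.0, 5.0, 15.0)
        expected = oracle_circular_mean(theta, dens)
        assert mean == pytest.approx(expected, abs=0.5)
        # arithmetic weighted mean is the unbiased ρτ estimate
        arith = float(
            np.average(last["angle_deg"].to_numpy(), weights=last["intensity"])
        )
        assert arith == pytest.approx(15.0, abs=1.0)

    def test_instantaneous_turnover_limit(self, wt_chart):
        """τ → 0: myosin tracks the source instantly, no deflection."""
        times = np.arange(0.0, 21.0, 5.0)
        flow = _uniform_rotation_flow(wt_chart, 3.0, times)
        params = sourcemodel.ModelParams(tau=0.01, source_width=15.0)
        segs, _ = synthgen.simulate_junction_ensemble(
            wt_chart, flow, params, n_junctions=2000, t_span=(0.0, 20.0), seed=4
        )
        last = segs[np.isclose(segs.t_min, 20.0)]
        mean, _ = nematic_mean_std(
            last["angle_deg"].to_numpy(), last["intensity"].to_numpy()
        )
        assert abs(mean) < 1.0

    def test_junction_conservation_and_determinism(self, wt_chart, wt_flow):
        params = sourcemodel.ModelParams(tau=5.0)
        a, truth = synthgen.simulate_junction_ensemble(
            wt_chart, wt_flow, params, n_junctions=200, t_span=(0.0, 12.0), seed=9
        )
        counts = a.groupby("t_min").size()
        assert (counts == 200).all()  # junctions persist, only m changes
        b, _ = synthgen.simulate_junction_ensemble(
            wt_chart, wt_flow, params, n_junctions=200, t_span=(0.0, 12.0), seed=9
        )
        pd.testing.assert_frame_equal(a, b)
        assert truth.x.shape == (13, 200)

    def test_t_span_outside_flow_coverage_raises(self, wt_chart, wt_flow):
        params = sourcemodel.ModelParams(tau=5.0)
        with pytest.raises(ValueError):
            synthgen.simulate_junction_ensemble(
                wt_chart, wt_flow, params, n_junctions=10, t_span=(0.0, 99.0), seed=0
            )


class TestRendering:
    def test_empty_segments_pure_noise(self):
        chart = open_chart(50)
        img = synthgen.render_junction_image(
            [], chart, noise_sigma=0.5, seed=3
        )
        assert img.shape == (50, 50)
        assert abs(np.mean(img)) < 0.05
        assert np.std(img) == pytest.approx(0.5, rel=0.1)

    def test_ridge_on_segment(self):
        chart = open_chart(60)
        seg = [junctions.JunctionSegment.from_midpoint(30, 30, 40.0, 10.0, 1.0)]
        img = synthgen.render_junction_image(seg, chart, noise_sigma=0.0)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(ix - 30) <= 1 and abs(iy - 30) <= 1

    def test_seed_determinism(self):
        chart = open_chart(40)
        seg = [junctions.JunctionSegment.from_midpoint(20, 20, 10.0, 8.0, 1.0)]
        a = synthgen.render_junction_image(seg, chart, noise_sigma=0.3, seed=5)
        b = synthgen.render_junction_image(seg, chart, noise_sigma=0.3, seed=5)
        assert np.array_equal(a, b)

    def test_negative_width_raises(self):
        with pytest.raises(ValueError):
            synthgen.render_junction_image([], open_chart(20), line_width=-1.0)


class TestFrapTrace:
    def test_fully_mobile_pool_recovers_immediately(self):
        params = synthgen.FrapParams(mobile_fraction=1.0)
        trace = synthgen.make_frap_trace(params)
        t, y = trace.postbleach()
        assert y[0] == pytest.approx(1.0)

    def test_noiseless_trace_equals_closed_form(self):
        params = synthgen.FrapParams(
            mobile_fraction=0.4, tau_fast_s=6.0, tau_slow_s=50.0, fast_amplitude=0.6
        )
        trace = synthgen.make_frap_trace(params, dt=1.5, duration=240.0)
        t, y = trace.postbleach()
        assert np.allclose(y, params.closed_form(t), atol=1e-12)

    def test_default_full_recovery_by_210s(self):
        trace = synthgen.make_frap_trace(synthgen.FrapParams())
        t, y = trace.postbleach()
        assert y[t >= 210.0].min() >= 0.99

    def test_duration_shorter_than_dt_raises(self):
        with pytest.raises(ValueError):
            synthgen.make_frap_trace(synthgen.FrapParams(), dt=5.0, duration=1.0)
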