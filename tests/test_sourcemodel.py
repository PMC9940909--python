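"""Static-source relaxation model: ODE law, field predictions,
rotation-adjusted angles, τ fitting, and ensemble distributions."""

import numpy as np
import pytest

from gbeorient import flowfield, junctions, sourcemodel, synthgen
from gbeorient.nematic import OrientationField
from gbeorient.sourcemodel import (
    DeflectionSeries,
    ModelParams,
    cross_correlation_lag,
    integrate_mean_deflection,
    lifetime_modulation_model,
    simulate_angular_distribution,
)

from conftest import (
    exponential_age_oracle,
    open_chart,
    oracle_arithmetic_mean,
    oracle_circular_mean,
)


class TestMeanDeflectionODE:
    def test_zero_rotation_stays_zero(self):
        t = np.arange(0.0, 30.0, 0.5)
        d = integrate_mean_deflection(t, np.zeros_like(t), tau=5.0)
        assert np.allclose(d.theta_deg, 0.0)

    def test_constant_rotation_closed_form(self):
        """ρ ≡ 3°/min, τ = 5 → θ̄(t) = 15·(1 − e^{−t/5}), to 1e−6 deg."""
        t = np.arange(0.0, 40.01, 0.5)
        d = integrate_mean_deflection(t, np.full_like(t, 3.0), tau=5.0)
        exact = 15.0 * (1.0 - np.exp(-t / 5.0))
        assert np.abs(d.theta_deg - exact).max() < 1e-6

    def test_linear_ramp_lags_by_tau(self):
        """ρ = a·t: after transients θ̄ = a·τ·(t − τ)."""
        t = np.arange(0.0, 60.01, 0.5)
        a = 0.05
        d = integrate_mean_deflection(t, a * t, tau=4.0)
        exact = a * 4.0 * (t - 4.0 * (1.0 - np.exp(-t / 4.0)))
        assert np.abs(d.theta_deg - exact).max() < 1e-6
        late = t > 45.0
        assert np.allclose(d.theta_deg[late], a * 4.0 * (t[late] - 4.0), atol=1e-3)

    def test_exponential_drive_closed_form(self):
        """ρ = e^{−t/T}: θ̄ = (Tτ/(T−τ))(e^{−t/T} − e^{−t/τ})."""
        t = np.arange(0.0, 50.01, 0.02)  # dense sampling of the curved drive
        T, tau = 10.0, 5.0
        d = integrate_mean_deflection(t, np.exp(-t / T), tau=tau)
        exact = (T * tau / (T - tau)) * (np.exp(-t / T) - np.exp(-t / tau))
        assert np.abs(d.theta_deg - exact).max() < 1e-6

    def test_invalid_tau_raises(self):
        t = np.arange(0.0, 5.0)
        with pytest.raises(ValueError):
            integrate_mean_deflection(t, np.zeros_like(t), tau=0.0)

    def test_deflection_series_range_invariant(self):
        with pytest.raises(ValueError):
            DeflectionSeries(np.array([0.0, 1.0]), np.array([0.0, 95.0]))


class TestRecoveryAndLag:
    def test_exponential_recovery_rate(self):
        """After ρ returns to 0, θ̄ decays as e^{−t/τ} (rate within 5%)."""
        t = np.arange(0.0, 80.01, 0.5)
        rho = np.where(t < 20.0, 3.0, 0.0)
        tau = 5.0
        d = integrate_mean_deflection(t, rho, tau=tau)
        decay = d.theta_deg[(t >= 25.0) & (t <= 55.0)]
        td = t[(t >= 25.0) & (t <= 55.0)]
        slope = np.polyfit(td, np.log(decay), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.05)

    def test_lag_law_slow_drive(self):
        """For slowly varying ρ the cross-correlation lag approaches τ."""
        t = np.arange(0.0, 181.0, 1.0)
        rho = 3.0 * np.exp(-0.5 * ((t - 80.0) / 25.0) ** 2)
        for tau in (3.0, 5.0, 8.0):
            d = integrate_mean_deflection(t, rho, tau=tau)
            lag = cross_correlation_lag(t, rho, d.theta_deg, max_lag=30.0)
            assert lag == pytest.approx(tau, abs=1.0)

    def test_envelope_drive_lag(self):
        """The default flow envelope with τ = 5 min delays the deflection
        by ≈ 5 min (within a minute at 1-min sampling)."""
        t = np.arange(0.0, 46.0, 1.0)
        spec = synthgen.FlowSpec(vortices=())
        rho = 5.0 * spec.envelope(t)
        d = integrate_mean_deflection(t, rho, tau=5.0)
        lag = cross_correlation_lag(t, rho, d.theta_deg)
        assert abs(lag - 5.0) <= 1.0


class TestPredictDeflectionField:
    def test_zero_rotation_zero_field(self):
        chart = open_chart(30)
        rr = flowfield.RotationRateField(
            chart=chart,
            times=np.arange(0.0, 11.0, 1.0),
            values=np.zeros((11, 30, 30)),
        )
        fields = sourcemodel.predict_deflection_field(rr, tau=5.0)
        for f in fields:
            assert np.allclose(f.angle_deg, 0.0)

    @pytest.mark.parametrize("mode", ["eulerian", "lagrangian"])
    def test_uniform_rotation_reduces_to_scalar(self, mode):
        chart = open_chart(30)
        times = np.arange(0.0, 21.0, 1.0)
        rho_t = 2.0 * np.sin(times / 5.0) ** 2
        values = rho_t[:, None, None] * np.ones((1, 30, 30))
        rr = flowfield.RotationRateField(chart=chart, times=times, values=values)
        vel = flowfield.VelocityField(
            chart=chart,
            times=times,
            vx=np.zeros((21, 30, 30)),
            vy=np.zeros((21, 30, 30)),
        )
        fields = sourcemodel.predict_deflection_field(
            rr, tau=4.0, mode=mode, velocity=vel, dt=0.1
        )
        scalar = integrate_mean_deflection(times, rho_t, tau=4.0, dt_max=0.1)
        for f, expected in zip(fields, scalar.theta_deg):
            assert np.allclose(f.angle_deg, expected, atol=1e-6)

    def test_wt_prediction_peaks_at_posterior_vortex(self, wt_chart, wt_rotation):
        fields = sourcemodel.predict_deflection_field(
            wt_rotation, tau=5.0, output_times=[25.0]
        )
        peak = np.unravel_index(
            np.argmax(np.abs(fields[0].angle_deg)), fields[0].shape
        )
        y_um, x_um = peak[0] * wt_chart.dy, peak[1] * wt_chart.dx
        dy = min(abs(y_um - 90.0), abs(y_um - 410.0))
        assert np.hypot(x_um - 360.0, dy) < 60.0

    def test_lagrangian_requires_velocity(self, wt_rotation):
        with pytest.raises(ValueError):
            sourcemodel.predict_deflection_field(wt_rotation, 5.0, mode="lagrangian")


class TestRotationAdjustedAngle:
    def test_identical_fields_zero(self):
        a = OrientationField(np.full((10, 10), 20.0), np.ones((10, 10)))
        b = OrientationField(np.full((10, 10), 20.0), np.ones((10, 10)))
        adj = sourcemodel.rotation_adjusted_angle(a, b)
        assert np.allclose(adj.angle_deg, 0.0)

    def test_grid_mismatch_raises(self):
        a = OrientationField(np.zeros((5, 5)), np.ones((5, 5)))
        b = OrientationField(np.zeros((6, 6)), np.ones((6, 6)))
        with pytest.raises(ValueError):
            sourcemodel.rotation_adjusted_angle(a, b)

    def test_true_tau_keeps_adjusted_angle_low(
        self, wt_chart, wt_rotation, wt_observed_fields
    ):
        """With the generating τ = 5 the signed spatial mean of the
        adjusted angle stays ≤ 2° on one lateral half at every time;
        with a badly wrong τ = 1 it exceeds that during peak vorticity."""
        half = np.zeros_like(wt_chart.germband_mask)
        half[(wt_chart.y > 0) & (wt_chart.y < 250.0)] = True
        half &= wt_chart.germband_mask

        def mean_adj(tau, t):
            f = wt_observed_fields[int(t - 10.0)]
            p = sourcemodel.predict_deflection_field(
                wt_rotation, tau, output_times=[t]
            )[0]
            adj = sourcemodel.rotation_adjusted_angle(f, p)
            w = adj.weight * half
            ok = np.isfinite(adj.angle_deg) & (w > 0)
            return float(np.average(adj.angle_deg[ok], weights=w[ok]))

        for t in (15.0, 20.0, 25.0, 30.0, 35.0):
            assert abs(mean_adj(5.0, t)) <= 2.0
        # a badly wrong tau leaves a clear residual in the vortex domain
        half[:, : int(270 / wt_chart.dx)] = False
        assert max(abs(mean_adj(1.0, t)) for t in (22.0, 25.0)) > 2.0


class TestFitTau:
    def test_zero_vorticity_unidentifiable(self):
        chart = open_chart(40)
        times = np.arange(0.0, 21.0, 1.0)
        rr = flowfield.RotationRateField(
            chart=chart, times=times, values=np.zeros((21, 40, 40))
        )
        obs = [
            OrientationField(
                np.zeros((40, 40)), np.ones((40, 40)), time_min=float(t)
            )
            for t in times[10:]
        ]
        result = sourcemodel.fit_tau(obs, rr, window=(10.0, 20.0), stride=1)
        assert not result.identifiable
        assert np.isnan(result.tau_hat)

    def test_eve_configuration_recovery(self, wt_chart):
        """Reduced-flow, short-lifetime configuration: the fitted
        lifetime lands in the 2–3 min range of the generating τ = 2.5."""
        spec = synthgen.default_flow_spec(wt_chart, amplitude=0.5)
        flow = synthgen.make_flow_field(wt_chart, spec, np.arange(0.0, 46.0, 1.0))
        rr = flowfield.rotation_rate(flow)
        params = ModelParams(tau=2.5, source_amplitude=0.5)
        segs, _ = synthgen.simulate_junction_ensemble(
            wt_chart, flow, params, n_junctions=2000, t_span=(0.0, 35.0), seed=6
        )
        obs = []
        for t in np.arange(10.0, 35.01, 1.0):
            f = junctions.anisotropy_field(
                segs[np.isclose(segs.t_min, t)],
                wt_chart,
                estimator="recentered",
            )
            f.time_min = float(t)
            obs.append(f)
        result = sourcemodel.fit_tau(
            obs, rr, tau_grid=np.arange(0.5, 10.01, 0.5), stride=3,
            smooth_radius_um=20.0,
        )
        assert result.identifiable
        assert 2.0 <= result.tau_hat <= 3.0


class TestAngularDistributions:
    def test_no_rotation_reproduces_source(self):
        dist = simulate_angular_distribution(0.0, tau=5.0, source_width=15.0,
                                             n=4000, seed=2)
        assert dist.mean_deg == pytest.approx(0.0, abs=1.0)
        assert dist.std_deg == pytest.approx(15.0, abs=2.0)

    def test_rotation_shifts_and_widens(self):
        """ρ = 3°/min, τ = 5 min: mean matches the exponential-age oracle
        (≈ ρτ), the distribution widens and is right-skewed."""
        d0 = simulate_angular_distribution(0.0, tau=5.0, n=4000, seed=3)
        d3 = simulate_angular_distribution(3.0, tau=5.0, n=4000, seed=3)
        theta, dens = exponential_age_oracle(3.0, 5.0, 15.0)
        assert d3.mean_deg == pytest.approx(oracle_circular_mean(theta, dens), abs=1.0)
        assert d3.std_deg > d0.std_deg
        assert d3.mean_deg > d3.median_deg  # exponential tail skews right

    @pytest.mark.parametrize("rho,tau", [(1.0, 2.0), (2.0, 5.0), (3.0, 5.0),
                                          (1.0, 8.0), (3.0, 8.0)])
    def test_steady_state_mean_deflection_law(self, rho, tau):
        """Steady-state intensity-weighted mean deflection equals the
        exponential-age integral, which itself equals ρτ up to the
        analytically bounded wrap loss."""
        dist = simulate_angular_distribution(
            rho, tau=tau, n=5000, duration=8.0 * tau, seed=int(10 * rho + tau),
            bins=180,
        )
        theta, dens = exponential_age_oracle(rho, tau, 15.0)
        # same arithmetic estimator on simulation histogram and oracle
        sim_mean = float(
            np.average(dist.bin_centers, weights=np.maximum(dist.counts, 0))
        )
        oracle_mean = oracle_arithmetic_mean(theta, dens)
        assert sim_mean == pytest.approx(oracle_mean, abs=1.0)
        # the oracle mean is ρτ minus the (small) wrapped tail
        wrap_bound = 180.0 * np.exp(-(90.0 - 15.0) / (rho * tau)) + 0.3
        assert abs(oracle_mean - rho * tau) <= wrap_bound

    def test_nonstationary_duration_warns(self):
        with pytest.warns(UserWarning):
            simulate_angular_distribution(1.0, tau=10.0, n=200, duration=5.0)


class TestLifetimeModulationModel:
    def test_uniform_lifetime_uniform_distribution(self):
        """Angle-independent lifetime: uniform recruitment gives a flat
        angular distribution, with or without rotation."""
        const = lambda th: np.full(np.shape(th), 5.0)
        for rho in (0.0, 3.0):
            dist = lifetime_modulation_model(rho, const, n=4000, duration=40.0,
                                             seed=5)
            counts = dist.counts / dist.counts.sum()
            assert counts.std() / counts.mean() < 0.12
            # no preferred orientation: tiny nematic order
            th2 = np.deg2rad(dist.bin_centers) * 2.0
            q = np.hypot(
                (counts * np.cos(th2)).sum(), (counts * np.sin(th2)).sum()
            )
            assert q < 0.05

    def test_dv_peaked_lifetime_differs_from_static_source(self):
        """DV-peaked lifetime under rotation: deflected, but not by the
        static-source prediction ρτ_max."""
        profile = lambda th: 0.5 + 4.5 * np.exp(
            -0.5 * (np.asarray(th) / 15.0) ** 2
        )
        dist = lifetime_modulation_model(3.0, profile, n=4000, duration=40.0, seed=9)
        assert np.isfinite(dist.mean_deg)
        assert dist.mean_deg > 0.0  # rotation does deflect the distribution
        assert abs(dist.mean_deg - 15.0) > 1.0  # but not by rho*tau_max

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            lifetime_modulation_model(1.0, lambda th: np.zeros(np.shape(th)), n=200)


class TestSourceMagnitudeInvariance:
    def test_deflection_independent_of_amplitude(self, wt_chart, wt_flow):
        """Rescaling the source amplitude rescales myosin linearly and
        leaves every intensity-weighted orientation statistic unchanged."""
        kwargs = dict(n_junctions=300, t_span=(0.0, 25.0), seed=13)
        a, _ = synthgen.simulate_junction_ensemble(
            wt_chart, wt_flow, ModelParams(tau=5.0, source_amplitude=1.0), **kwargs
        )
        b, _ = synthgen.simulate_junction_ensemble(
            wt_chart, wt_flow, ModelParams(tau=5.0, source_amplitude=10.0), **kwargs
        )
        assert np.allclose(a["angle_deg"], b["angle_deg"])
        assert np.allclose(10.0 * a["intensity"], b["intensity"], rtol=1e-9)
        last_a = a[np.isclose(a.t_min, 25.0)]
        last_b = b[np.isclose(b.t_min, 25.0)]
        mean_a = np.average(last_a["angle_deg"], weights=last_a["intensity"])
        mean_b = np.average(last_b["angle_deg"], weights=last_b["intensity"])
        assert mean_a == pytest.approx(mean_b, abs=1e-9)
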