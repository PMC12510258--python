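"""MSD analysis chain: Gaussian fits, MSD series, diffusion regression."""

import math

import numpy as np
import pytest

import anisophot as ap
from anisophot.optics import FiberGeometry
from anisophot.synth import SyntheticSpec, generate_gaussian_stack
from anisophot.transient import (MSDSeries, TransientStack,
                                 build_msd_series, fit_bivariate_gaussian,
                                 integrate_time_resolved, regress_diffusion)


def _render_gaussian(x, y, amp, cx, cy, v1, v2, theta_deg, off=0.0):
    X, Y = np.meshgrid(x, y, indexing="ij")
    th = math.radians(theta_deg)
    u = math.cos(th) * (X - cx) + math.sin(th) * (Y - cy)
    w = -math.sin(th) * (X - cx) + math.cos(th) * (Y - cy)
    return amp * np.exp(-0.5 * (u * u / v1 + w * w / v2)) + off


class TestBivariateGaussianFit:
    x = np.linspace(-2.65, 2.65, 107)

    def test_noiseless_recovery(self):
        frame = _render_gaussian(self.x, self.x, 10.0, 0.1, -0.2, 1.0, 2.0, 30.0,
                                 off=0.5)
        fit = fit_bivariate_gaussian(frame, self.x, self.x)
        # axis-1 is whichever the optimizer lists first; order by size
        v_lo, v_hi = sorted([fit.var1, fit.var2])
        assert v_lo == pytest.approx(1.0, rel=1e-6)
        assert v_hi == pytest.approx(2.0, rel=1e-6)
        assert fit.center[0] == pytest.approx(0.1, abs=1e-6)
        assert fit.offset == pytest.approx(0.5, rel=1e-6)
        # angle of the larger-variance axis (generated at 120 deg, axial)
        rot = fit.rotation + 90.0 if fit.var1 < fit.var2 else fit.rotation
        assert math.cos(2 * math.radians(rot - 120.0)) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_frame_flags_rotation(self):
        frame = _render_gaussian(self.x, self.x, 5.0, 0.0, 0.0, 1.5, 1.5, 0.0)
        fit = fit_bivariate_gaussian(frame, self.x, self.x)
        assert fit.var1 == pytest.approx(fit.var2, rel=1e-4)
        assert fit.rotation_indeterminate

    def test_isotropic_mc_frame_variance(self, iso_record):
        """Fitted variance of a simulated frame matches 2 v t / (3 mu_s')
        up to the pre-asymptotic offset (checked as slope over two frames)."""
        rec = iso_record
        x = rec.x_centers
        mask = None
        fits = []
        for k in (11, 14):  # t = 11.5, 14.5 ps
            fits.append(fit_bivariate_gaussian(rec.intensity[:, :, k], x, x, mask))
        d_est = (fits[1].var1 - fits[0].var1) / (2 * 3.0)
        d_th = rec.v / (3 * 4.4)
        assert d_est == pytest.approx(d_th, rel=0.25)  # single-pair, noisy

    def test_flat_frame_rejected(self):
        with pytest.raises(ValueError):
            fit_bivariate_gaussian(np.ones((107, 107)), self.x, self.x)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            fit_bivariate_gaussian(np.ones((5, 5)), self.x[:5], self.x[:5])


def _linear_stack(d_perp, d_par, rotation=0.0, alpha=0.0, s0=0.0025):
    spec = SyntheticSpec.analytic(
        d_perp=d_perp, d_par=d_par, rotation=rotation,
        geometry=FiberGeometry(elevation_alpha=alpha),
        photons_per_frame=None, sigma0_sq=s0)
    return generate_gaussian_stack(spec)


class TestBuildMSDSeries:
    def test_exact_linear_law(self):
        stack = _linear_stack(1.5e-2, 2.5e-2)
        series = build_msd_series(stack)
        t = series.times
        np.testing.assert_allclose(series.msd_par, 0.0025 + 2 * 2.5e-2 * t,
                                   rtol=1e-3)
        np.testing.assert_allclose(series.msd_perp, 0.0025 + 2 * 1.5e-2 * t,
                                   rtol=1e-3)

    def test_rotation_equivariance(self):
        s0 = build_msd_series(_linear_stack(1.5e-2, 2.5e-2))
        s40 = build_msd_series(_linear_stack(1.5e-2, 2.5e-2, rotation=40.0))
        # parallel axis at 90 + 40 deg from +x (axial, mod 180)
        d = (s40.rotation - (90.0 + 40.0)) % 180.0
        assert min(d, 180.0 - d) < 1.0
        np.testing.assert_allclose(s40.msd_par, s0.msd_par, rtol=1e-3)
        np.testing.assert_allclose(s40.msd_perp, s0.msd_perp, rtol=1e-3)

    def test_mc_stack_par_slope_exceeds_perp(self, aniso_stack):
        series = build_msd_series(aniso_stack)
        sel = series.times > 10.0
        sp = np.polyfit(series.times[sel], series.msd_par[sel], 1)[0]
        se = np.polyfit(series.times[sel], series.msd_perp[sel], 1)[0]
        assert sp > 1.2 * se

    def test_too_few_frames(self):
        stack = _linear_stack(1e-2, 2e-2)
        short = TransientStack(frames=stack.frames[:2],
                               time_stamps=stack.time_stamps[:2],
                               pixel_pitch=stack.pixel_pitch,
                               x0=stack.x0, y0=stack.y0)
        with pytest.raises(ValueError):
            build_msd_series(short)


class TestRegressDiffusion:
    @staticmethod
    def _series_from_lines(slope_perp, slope_par, times=None, err=1e-6):
        t = times if times is not None else np.arange(0.5, 15.6, 1.0)
        e = np.full_like(t, err)
        return MSDSeries(times=t, msd_par=slope_par * t, msd_perp=slope_perp * t,
                         err_par=e, err_perp=e, rotation=90.0)

    def test_white_matter_closed_form_chain(self):
        """Exact lines at the measured in-plane slopes + 31 deg elevation
        reproduce the retrieved tensor and OFA."""
        s = self._series_from_lines(2 * 1.69e-2, 2 * 2.117e-2)
        est = regress_diffusion(s, geometry=FiberGeometry(elevation_alpha=31.0))
        assert est.tensor.d_x == pytest.approx(1.69e-2, rel=1e-3)
        assert est.tensor.d_y == pytest.approx(2.47e-2, rel=1e-3)
        assert est.ofa == pytest.approx(0.227, abs=1e-3)

    def test_equal_slopes_zero_ofa(self):
        s = self._series_from_lines(2e-2, 2e-2)
        est = regress_diffusion(s)
        assert est.ofa == pytest.approx(0.0, abs=1e-9)

    def test_doubling_uncertainties_only_scales_errors(self):
        rng = np.random.default_rng(8)
        t = np.arange(0.5, 15.6, 1.0)
        noise = rng.normal(0, 1e-3, size=t.size)
        base = MSDSeries(times=t, msd_par=4e-2 * t + noise,
                         msd_perp=2e-2 * t + noise,
                         err_par=np.full_like(t, 1e-3),
                         err_perp=np.full_like(t, 1e-3), rotation=90.0)
        doubled = MSDSeries(times=t, msd_par=base.msd_par, msd_perp=base.msd_perp,
                            err_par=2 * base.err_par, err_perp=2 * base.err_perp,
                            rotation=90.0)
        e1 = regress_diffusion(base)
        e2 = regress_diffusion(doubled)
        assert e2.tensor.d_y == pytest.approx(e1.tensor.d_y, rel=1e-12)
        assert e2.se_par == pytest.approx(2 * e1.se_par, rel=1e-9)

    def test_needs_three_points(self):
        s = self._series_from_lines(2e-2, 3e-2, times=np.array([1.0, 11.0, 12.0]))
        with pytest.raises(ValueError):
            regress_diffusion(s, t_min=10.0)


class TestIntensityScaleInvariance:
    def test_msd_and_estimate_invariant(self):
        stack = _linear_stack(1.5e-2, 2.5e-2)
        scaled = TransientStack(frames=stack.frames * 137.0,
                                time_stamps=stack.time_stamps,
                                pixel_pitch=stack.pixel_pitch,
                                x0=stack.x0, y0=stack.y0)
        a = build_msd_series(stack)
        b = build_msd_series(scaled)
        np.testing.assert_allclose(b.msd_par, a.msd_par, rtol=1e-3)
        ea = regress_diffusion(a)
        eb = regress_diffusion(b)
        assert eb.tensor.d_y == pytest.approx(ea.tensor.d_y, rel=1e-3)


class TestIntegrateTimeResolved:
    def test_uniform_frames(self):
        n = 60
        frames = np.ones((4, n, n))
        stack = TransientStack(frames=frames, time_stamps=[1.0, 2, 3, 4],
                               pixel_pitch=0.1, x0=-3.0, y0=-3.0)
        curve = integrate_time_resolved(stack, use_fov=False)
        np.testing.assert_allclose(curve.intensity, n * n)

    def test_commutes_with_absorption_reweight(self, iso_record):
        mu_a = 0.05
        a = integrate_time_resolved(ap.absorption_reweight(iso_record, mu_a))
        b = integrate_time_resolved(iso_record)
        factors = np.exp(-mu_a * iso_record.v * iso_record.t_centers)
        np.testing.assert_allclose(a.intensity, b.intensity * factors, rtol=1e-9)

    def test_mu_a_zero_late_log_slope(self, iso_record):
        """Without absorption the asymptotic log-slope of R(t) vanishes;
        at desk scale we only check it is far smaller than an absorbing run."""
        c0 = integrate_time_resolved(iso_record)
        ca = integrate_time_resolved(ap.absorption_reweight(iso_record, 0.1))
        sel = c0.times > 8.0
        s0 = np.polyfit(c0.times[sel], np.log(c0.intensity[sel]), 1)[0]
        sa = np.polyfit(ca.times[sel], np.log(ca.intensity[sel]), 1)[0]
        assert s0 - sa == pytest.approx(0.1 * iso_record.v, rel=1e-6)

    def test_empty_mask_rejected(self):
        frames = np.ones((3, 60, 60))
        stack = TransientStack(frames=frames, time_stamps=[1.0, 2, 3],
                               pixel_pitch=0.1, x0=10.0, y0=10.0)
        with pytest.raises(ValueError):
            integrate_time_resolved(stack)


class TestModelResults:
    def test_summary_and_accessors(self):
        stack = _linear_stack(1.69e-2, 2.47e-2, alpha=31.0)
        model = ap.TransientDiffusionModel(
            stack, geometry=FiberGeometry(elevation_alpha=31.0))
        res = model.fit()
        assert res.d_perp == pytest.approx(1.69e-2, rel=5e-3)
        assert res.d_par == pytest.approx(2.47e-2, rel=5e-3)
        assert 0.0 <= res.ofa <= 1.0
        text = res.summary()
        assert "D_perp" in text and "OFA" in text
        d = res.to_dict()
        assert d["units"]["d"] == "mm^2/ps"
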