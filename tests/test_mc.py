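"""Monte Carlo transport: samplers, boundaries, conservation, diffusion limit."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import anisophot as ap
from anisophot.mc import (TENSOR_MODELS, absorption_reweight,
                          directional_scattering_coefficient,
                          fresnel_interface, fresnel_reflectance,
                          sample_free_path, sample_hg_deflection)


class TestDirectionalRate:
    props = ap.OpticalTensorProperties(2.0, 1.0, 1.0)

    @pytest.mark.parametrize("model", list(TENSOR_MODELS))
    def test_principal_axes(self, model):
        for axis, expect in ((np.eye(3)[0], 2.0), (np.eye(3)[1], 1.0),
                             (np.eye(3)[2], 1.0)):
            assert directional_scattering_coefficient(
                axis, self.props, model) == pytest.approx(expect)

    def test_norm_model_diagonal_direction(self):
        s = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
        assert directional_scattering_coefficient(
            s, self.props, "norm") == pytest.approx(math.sqrt(2.5), rel=1e-12)

    @pytest.mark.parametrize("model", list(TENSOR_MODELS))
    def test_isotropic_reduction_and_bounds(self, model):
        iso = ap.OpticalTensorProperties.isotropic(3.3)
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        np.testing.assert_allclose(
            directional_scattering_coefficient(dirs, iso, model), 3.3, rtol=1e-9)
        rates = directional_scattering_coefficient(dirs, self.props, model)
        assert np.all(rates >= 1.0 - 1e-9) and np.all(rates <= 2.0 + 1e-9)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            directional_scattering_coefficient(np.zeros(3), self.props)


class TestFreePath:
    def test_isotropic_mean(self):
        props = ap.OpticalTensorProperties.isotropic(4.0)
        rng = np.random.default_rng(1)
        s = sample_free_path([0, 0, 1.0], props, rng, size=200_000)
        assert s.mean() == pytest.approx(0.25, abs=3 * 0.25 / math.sqrt(200_000))

    def test_fixture_axis_mean(self):
        mu = 4.4 / 0.03  # white-matter perpendicular scattering coefficient
        props = ap.OpticalTensorProperties.uniaxial(mu, 2.6 / 0.03, "y")
        rng = np.random.default_rng(2)
        s = sample_free_path([1.0, 0, 0], props, rng, size=100_000)
        assert s.mean() == pytest.approx(1 / mu, rel=0.02)

    def test_seed_determinism(self):
        props = ap.OpticalTensorProperties.isotropic(2.0)
        a = sample_free_path([0, 0, 1.0], props, np.random.default_rng(3), size=10)
        b = sample_free_path([0, 0, 1.0], props, np.random.default_rng(3), size=10)
        np.testing.assert_array_equal(a, b)


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.97])
    def test_mean_cosine_is_g(self, g):
        rng = np.random.default_rng(4)
        c = sample_hg_deflection(g, rng, size=400_000)
        se = c.std() / math.sqrt(c.size)
        assert c.mean() == pytest.approx(g, abs=4 * se)
        assert np.all(np.abs(c) <= 1.0)

    def test_median_matches_numeric_cdf_inversion(self):
        # independent oracle: numerically invert the HG CDF at u = 0.5
        g = 0.8
        def hg_cdf(c):
            # integral of the HG phase function from -1 to c
            return ((1 - g**2) / (2 * g)) * (
                1 / math.sqrt(1 + g**2 - 2 * g * c) - 1 / (1 + g))
        median_oracle = brentq(lambda c: hg_cdf(c) - 0.5, -1, 1, xtol=1e-12)
        rng = np.random.default_rng(5)
        c = sample_hg_deflection(g, rng, size=400_000)
        assert np.median(c) == pytest.approx(median_oracle, abs=5e-3)


class TestFresnel:
    def test_normal_incidence_air_tissue(self):
        r = fresnel_reflectance(1.0, 1.39, 1.0)
        assert r == pytest.approx(((0.39 / 2.39) ** 2), rel=1e-9)

    def test_matched_media_transmit(self):
        rng = np.random.default_rng(6)
        d = np.array([0.3, 0.4, math.sqrt(1 - 0.25)])
        out = fresnel_interface(d, 1.39, 1.39, rng)
        np.testing.assert_allclose(out, d, atol=1e-12)

    def test_total_internal_reflection(self):
        # internal incidence beyond the critical angle asin(1/1.39) = 46 deg
        theta = math.radians(50.0)
        assert fresnel_reflectance(1.39, 1.0, math.cos(theta)) == 1.0
        d = np.array([math.sin(theta), 0.0, -math.cos(theta)])
        out = fresnel_interface(d, 1.39, 1.0, np.random.default_rng(7))
        np.testing.assert_allclose(out, [math.sin(theta), 0.0, math.cos(theta)],
                                   atol=1e-12)


class TestPropagate:
    def test_weight_conservation(self, iso_record):
        accounted, launched = iso_record.weight_balance()
        assert accounted == pytest.approx(launched, rel=1e-6)

    def test_seed_determinism(self, acquisition_grid):
        props = ap.OpticalTensorProperties.isotropic(3.0, g=0.9)
        med = ap.LayeredMedium.semi_infinite(props)
        a = ap.propagate(med, ap.SourceSpec(), acquisition_grid, 20_000, seed=11)
        b = ap.propagate(med, ap.SourceSpec(), acquisition_grid, 20_000, seed=11)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_isotropic_diffusion_slope(self):
        """Late-window variance slope approaches 2 v / (3 mu_s') (diffusion)."""
        props = ap.OpticalTensorProperties.isotropic(4.4, g=0.0, n_eff=1.39)
        med = ap.LayeredMedium.semi_infinite(props)
        grid = ap.DetectionGrid.centered(12.0, 0.15, np.arange(0.0, 60.01, 2.0))
        slopes = []
        for seed in (1, 2, 3):
            rec = ap.propagate(med, ap.SourceSpec(), grid, 250_000, seed=seed)
            tc, x = rec.t_centers, rec.x_centers
            sel = tc > 30.0
            var = []
            for k in np.where(sel)[0]:
                px = rec.intensity[:, :, k].sum(axis=1)
                m = (px * x).sum() / px.sum()
                var.append((px * (x - m) ** 2).sum() / px.sum())
            slopes.append(np.polyfit(tc[sel], var, 1)[0])
        expected = 2 * props.v / (3 * 4.4)
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(mean - expected) < 3 * max(se, 0.02 * expected)

    def test_msd_linearity_r2(self, aniso_record):
        """In the diffusive window the per-axis variance is linear in t."""
        rec = aniso_record
        tc, x = rec.t_centers, rec.x_centers
        sel = tc > 8.0
        var = []
        for k in np.where(sel)[0]:
            px = rec.intensity[:, :, k].sum(axis=1)
            m = (px * x).sum() / px.sum()
            var.append((px * (x - m) ** 2).sum() / px.sum())
        coef = np.polyfit(tc[sel], var, 1)
        fitted = np.polyval(coef, tc[sel])
        ss_res = np.sum((np.array(var) - fitted) ** 2)
        ss_tot = np.sum((np.array(var) - np.mean(var)) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_anisotropic_fast_axis(self, aniso_record):
        """Fibers along y: late-time y spread exceeds x spread."""
        rec = aniso_record
        k = len(rec.t_centers) - 1
        f = rec.intensity[:, :, k]
        x = rec.x_centers
        px, py = f.sum(axis=1), f.sum(axis=0)
        vx = (px * (x - (px * x).sum() / px.sum()) ** 2).sum() / px.sum()
        vy = (py * (x - (py * x).sum() / py.sum()) ** 2).sum() / py.sum()
        assert vy > 1.2 * vx

    def test_tensor_swap_transposes_intensity(self, acquisition_grid):
        """Swapping x/y tensor components transposes the (x, y) pattern."""
        a = ap.OpticalTensorProperties(80.0, 140.0, 140.0, g=0.95, n_eff=1.39)
        b = ap.OpticalTensorProperties(140.0, 80.0, 140.0, g=0.95, n_eff=1.39)
        src = ap.SourceSpec(incidence_angle=0.0)  # keep the source symmetric
        ra = ap.propagate(ap.LayeredMedium.semi_infinite(a), src,
                          acquisition_grid, 150_000, seed=13)
        rb = ap.propagate(ap.LayeredMedium.semi_infinite(b), src,
                          acquisition_grid, 150_000, seed=14)
        pa = ra.intensity.sum(axis=2)
        pb = rb.intensity.sum(axis=2).T
        # compare axis-marginal variances of the late-time patterns
        x = acquisition_grid.x_centers
        def axvar(p, axis):
            prof = p.sum(axis=1 - axis)
            m = (prof * x).sum() / prof.sum()
            return (prof * (x - m) ** 2).sum() / prof.sum()
        assert axvar(pa, 0) == pytest.approx(axvar(pb, 0), rel=0.05)
        assert axvar(pa, 1) == pytest.approx(axvar(pb, 1), rel=0.05)


class TestAbsorptionReweight:
    def test_identity_at_zero(self, iso_record):
        rec = absorption_reweight(iso_record, 0.0)
        np.testing.assert_array_equal(rec.intensity, iso_record.intensity)

    def test_exponential_factor(self, iso_record):
        mu_a = 0.043
        rec = absorption_reweight(iso_record, mu_a)
        k = 10  # t_center = 10.5 ps
        t = iso_record.t_centers[k]
        factor = math.exp(-mu_a * iso_record.v * t)
        np.testing.assert_allclose(rec.intensity[:, :, k],
                                   iso_record.intensity[:, :, k] * factor)
        # printed check: exp(-0.043 * v * 10 ps) = 0.9114
        assert math.exp(-0.043 * (0.299792458 / 1.39) * 10) == pytest.approx(
            0.9114, abs=1e-4)

    def test_profile_shape_invariant(self, iso_record):
        rec = absorption_reweight(iso_record, 0.1)
        for k in (3, 8, 14):
            a = iso_record.intensity[:, :, k]
            b = rec.intensity[:, :, k]
            if a.sum() > 0:
                np.testing.assert_allclose(b / b.sum(), a / a.sum(), rtol=1e-9)

    def test_double_application_rejected(self, iso_record):
        rec = absorption_reweight(iso_record, 0.01)
        with pytest.raises(ValueError):
            absorption_reweight(rec, 0.01)
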