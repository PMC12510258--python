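"""Two-stage inverse retrieval of tensor scattering, asymmetry and absorption.

Stage 1 fits the per-axis MSD curves with the tensor Monte Carlo forward
model, treating the two effective reduced scattering components and the
scalar asymmetry g as free parameters.  Because very different (mu_s, g)
pairs produce nearly identical diffusive behaviour (the similarity
degeneracy), g is handled on a grid: for each g the two effective reduced
components mu_s_eff' = mu_s (1 - g) are optimized, and the chi^2(g)
profile is reported; the early-time transient is what breaks the
degeneracy.  Common random numbers (one seed for every forward run) keep
chi^2 differences across the grid free of independent MC noise.

Stage 2 fixes the scattering parameters and retrieves the absorption
coefficient from the spatially integrated time-resolved curve.  A single
mu_a = 0 forward run per g suffices: homogeneous absorption only rescales
each time bin by exp(-mu_a v t) (microscopic Beer-Lambert), so the fit is
a two-parameter (amplitude, mu_a) weighted least squares, closed-form in
the amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .optics import OpticalTensorProperties, speed_in_medium
from .synth import SyntheticSpec, _mc_record, generate_mc_stack
from .transient import (DEFAULT_FOV_AREA, MSDSeries, TDRCurve,
                        build_msd_series, integrate_time_resolved)

__all__ = [
    "FitConfig",
    "ChiSquareSurface",
    "ScatteringInversion",
    "ScatteringResults",
    "AbsorptionInversion",
    "AbsorptionResults",
    "fit_scattering_stage1",
    "fit_absorption_stage2",
]


def default_g_grid() -> np.ndarray:
    return np.round(np.arange(0.80, 0.9901, 0.01), 4)


@dataclass
class FitConfig:
    """Settings shared by the two inversion stages.

    ``n_photons`` is the photon budget of each forward Monte Carlo run;
    ``seed`` is reused for every run on the grid (common random numbers).
    """

    g_grid: np.ndarray = field(default_factory=default_g_grid)
    n_photons: int = 300_000
    seed: int = 1234
    t_min: float = 10.0
    max_iter: int = 4
    slope_rtol: float = 0.01
    n_eff: float = 1.39
    tensor_model: str = "norm"
    incidence_angle: float = 13.0
    pixel_pitch: float = 0.05
    frame_size: float = 5.4
    fov_area: float = DEFAULT_FOV_AREA
    uncertainty_step: float = 0.05
    compute_uncertainties: bool = True

    def __post_init__(self) -> None:
        self.g_grid = np.asarray(self.g_grid, dtype=float)
        if self.g_grid.size == 0:
            raise ValueError("g grid must be non-empty")
        if np.any((self.g_grid < 0) | (self.g_grid >= 1)):
            raise ValueError("g grid values must lie in [0, 1)")
        if self.n_photons < 1:
            raise ValueError("photon budget must be positive")


@dataclass
class ChiSquareSurface:
    """chi^2 profile over one parameter axis (typically g)."""

    param: str
    values: np.ndarray
    chi2: np.ndarray
    payload: list = field(default_factory=list)

    @property
    def argmin(self) -> int:
        return int(np.nanargmin(self.chi2))

    @property
    def best(self) -> float:
        return float(self.values[self.argmin])

    @property
    def on_boundary(self) -> bool:
        return self.argmin in (0, len(self.values) - 1)


class _ForwardCache:
    """Memoized MSD forward model keyed by (g, mu_perp, mu_par, seed)."""

    def __init__(self, cfg: FitConfig, times: np.ndarray,
                 rotation: float = 90.0, par_is_axis1: bool = True):
        self.cfg = cfg
        self.times = times
        # analyse model stacks in the data's principal frame; forward runs
        # put the fiber (fast) axis along lab y, i.e. axis 1 at 90 deg
        self.rotation = rotation
        self.par_is_axis1 = par_is_axis1
        self._store: dict = {}

    def msd(self, mu_perp: float, mu_par: float, g: float) -> MSDSeries:
        key = (round(float(g), 6), round(float(mu_perp), 5),
               round(float(mu_par), 5), self.cfg.seed)
        if key not in self._store:
            props = OpticalTensorProperties.uniaxial(
                mu_s_perp=mu_perp / (1.0 - g), mu_s_par=mu_par / (1.0 - g),
                fiber_axis="y", g=g, mu_a=0.0, n_eff=self.cfg.n_eff)
            spec = SyntheticSpec.monte_carlo(
                props, n_photons=self.cfg.n_photons, seed=self.cfg.seed,
                tensor_model=self.cfg.tensor_model,
                incidence_angle=self.cfg.incidence_angle,
                frame_times=self.times, pixel_pitch=self.cfg.pixel_pitch,
                frame_size=self.cfg.frame_size, fov_area=self.cfg.fov_area,
                photons_per_frame=None, mu_a=0.0)
            stack = generate_mc_stack(spec)
            self._store[key] = build_msd_series(
                stack, t_min=self.cfg.t_min, rotation=self.rotation,
                par_is_axis1=self.par_is_axis1)
        return self._store[key]


def _late_slopes(series: MSDSeries, t_min: float) -> tuple[float, float]:
    sel = series.times > t_min
    t = series.times[sel]
    sp = np.polyfit(t, series.msd_par[sel], 1)[0]
    se = np.polyfit(t, series.msd_perp[sel], 1)[0]
    return se, sp


def _chi2_msd(model: MSDSeries, data: MSDSeries) -> float:
    if model.times.shape != data.times.shape or np.any(model.times != data.times):
        raise ValueError("model and data MSD time supports do not overlap")
    # combine the data uncertainty with the forward model's own MC error
    s_par = np.sqrt(data.err_par ** 2 + model.err_par ** 2)
    s_perp = np.sqrt(data.err_perp ** 2 + model.err_perp ** 2)
    r_par = (model.msd_par - data.msd_par) / s_par
    r_perp = (model.msd_perp - data.msd_perp) / s_perp
    return float(np.sum(r_par ** 2) + np.sum(r_perp ** 2))


class ScatteringInversion:
    """Stage-1 model: MSD curves vs the tensor-MC forward model.

    For each g on the grid the two effective reduced scattering components
    are found by matched-slope fixed-point iteration (each step one
    seeded forward run), starting from the isotropic-limit inversion
    mu' = v / (3 D) of the regressed slopes; chi^2 is then evaluated over
    both axes and all gate delays.
    """

    def __init__(self, series: MSDSeries, config: FitConfig | None = None):
        self.series = series
        self.config = config or FitConfig()

    def fit(self) -> "ScatteringResults":
        cfg = self.config
        data = self.series
        cache = _ForwardCache(cfg, data.times)  # model frame: fast axis on y
        v = speed_in_medium(cfg.n_eff)
        se_data, sp_data = _late_slopes(data, cfg.t_min)
        if se_data <= 0 or sp_data <= 0:
            raise ValueError("data MSD slopes must be positive")
        mu_perp0 = v / (3.0 * (se_data / 2.0))
        mu_par0 = v / (3.0 * (sp_data / 2.0))

        chi2s, params = [], []
        for g in cfg.g_grid:
            mu_perp, mu_par = mu_perp0, mu_par0
            for _ in range(cfg.max_iter):
                model = cache.msd(mu_perp, mu_par, g)
                se_m, sp_m = _late_slopes(model, cfg.t_min)
                r_perp = se_m / se_data
                r_par = sp_m / sp_data
                mu_perp *= r_perp
                mu_par *= r_par
                if abs(r_perp - 1) < cfg.slope_rtol and abs(r_par - 1) < cfg.slope_rtol:
                    break
            model = cache.msd(mu_perp, mu_par, g)
            chi2s.append(_chi2_msd(model, data))
            params.append((mu_perp, mu_par))

        surface = ChiSquareSurface("g", cfg.g_grid.copy(), np.array(chi2s),
                                   payload=params)
        i = surface.argmin
        mu_perp, mu_par = params[i]
        g_best = surface.best

        # delta-chi^2 = 1 curvature uncertainties (common random numbers)
        def curvature_se(idx):
            h = cfg.uncertainty_step
            base = surface.chi2[i]
            pts = []
            for f in (1.0 - h, 1.0 + h):
                mp = [mu_perp, mu_par]
                mp[idx] *= f
                pts.append(_chi2_msd(cache.msd(mp[0], mp[1], g_best), data))
            step = [mu_perp, mu_par][idx] * h
            d2 = (pts[0] - 2 * base + pts[1]) / step ** 2
            if d2 <= 0:
                return float("nan")
            return math.sqrt(2.0 / d2)

        # inflate by sqrt(reduced chi^2) when the residual scale is
        # underestimated (misfit beyond the stated uncertainties)
        if cfg.compute_uncertainties:
            dof = max(2 * len(data.times) - 3, 1)
            scale = math.sqrt(max(surface.chi2[i] / dof, 1.0))
            se_mu_perp = curvature_se(0) * scale
            se_mu_par = curvature_se(1) * scale
        else:
            se_mu_perp = se_mu_par = float("nan")
        return ScatteringResults(self, mu_perp, mu_par, g_best,
                                 se_mu_perp, se_mu_par, surface)


class ScatteringResults:
    """Stage-1 estimates: effective reduced tensor components and g."""

    def __init__(self, model, mu_s_eff_perp, mu_s_eff_par, g,
                 se_perp, se_par, chi2_surface: ChiSquareSurface):
        self.model = model
        self.mu_s_eff_perp = mu_s_eff_perp
        self.mu_s_eff_par = mu_s_eff_par
        self.g = g
        self.se_perp = se_perp
        self.se_par = se_par
        self.chi2_surface = chi2_surface

    def to_dict(self) -> dict:
        return {
            "mu_s_eff_prime_perp": self.mu_s_eff_perp,
            "mu_s_eff_prime_par": self.mu_s_eff_par,
            "se_mu_s_eff_prime_perp": self.se_perp,
            "se_mu_s_eff_prime_par": self.se_par,
            "g": self.g,
            "g_on_boundary": self.chi2_surface.on_boundary,
            "chi2_g": {"g": self.chi2_surface.values.tolist(),
                       "chi2": self.chi2_surface.chi2.tolist()},
            "units": {"mu_s_eff_prime": "mm^-1"},
        }

    def summary(self) -> str:
        s = self.chi2_surface
        return "\n".join([
            "Stage-1 tensor-scattering fit (MSD curves)",
            "==========================================",
            f"  mu_s_eff'_perp = ({self.mu_s_eff_perp:.2f} +/- {self.se_perp:.2f}) mm^-1",
            f"  mu_s_eff'_par  = ({self.mu_s_eff_par:.2f} +/- {self.se_par:.2f}) mm^-1",
            f"  g (grid argmin) = {self.g:.2f}"
            + ("  [boundary]" if s.on_boundary else ""),
            f"  chi2 at optimum = {s.chi2[s.argmin]:.1f}",
        ])


class AbsorptionInversion:
    """Stage-2 model: absorption from the integrated time-resolved curve.

    The forward TDR shape is one mu_a = 0 run at the stage-1 scattering
    parameters; the fit floats an amplitude (closed form) and mu_a through
    exp(-mu_a v t) reweighting.  A chi^2(g) profile over the grid serves
    as an independent cross-check of the asymmetry factor.
    """

    def __init__(self, curve: TDRCurve,
                 mu_s_eff_perp: float, mu_s_eff_par: float,
                 config: FitConfig | None = None):
        if len(curve.times) < 3:
            raise ValueError("TDR curve must have at least 3 bins")
        self.curve = curve
        self.mu_s_eff_perp = mu_s_eff_perp
        self.mu_s_eff_par = mu_s_eff_par
        self.config = config or FitConfig()

    @classmethod
    def from_stage1(cls, curve: TDRCurve, stage1: ScatteringResults,
                    config: FitConfig | None = None) -> "AbsorptionInversion":
        return cls(curve, stage1.mu_s_eff_perp, stage1.mu_s_eff_par, config)

    def _forward_tdr(self, g: float) -> np.ndarray:
        cfg = self.config
        props = OpticalTensorProperties.uniaxial(
            mu_s_perp=self.mu_s_eff_perp / (1.0 - g),
            mu_s_par=self.mu_s_eff_par / (1.0 - g),
            fiber_axis="y", g=g, mu_a=0.0, n_eff=cfg.n_eff)
        spec = SyntheticSpec.monte_carlo(
            props, n_photons=cfg.n_photons, seed=cfg.seed,
            tensor_model=cfg.tensor_model, incidence_angle=cfg.incidence_angle,
            frame_times=self.curve.times, pixel_pitch=cfg.pixel_pitch,
            frame_size=cfg.frame_size, fov_area=cfg.fov_area,
            photons_per_frame=None, mu_a=0.0)
        rec = _mc_record(spec)  # one zero-absorption run
        return integrate_time_resolved(rec).intensity

    def _fit_one(self, model0: np.ndarray):
        data = self.curve.intensity
        sig = self.curve.uncertainty
        ok = (model0 > 0) & (data >= 0) & (sig > 0)
        t = self.curve.times[ok]
        m0 = model0[ok]
        d = data[ok]
        v = speed_in_medium(self.config.n_eff)

        def make_chi2(w):
            def chi2_of(mu_a):
                m = m0 * np.exp(-mu_a * v * t)
                amp = np.sum(w * m * d) / np.sum(w * m * m)
                r = (amp * m - d)
                return float(np.sum(w * r * r)), amp
            return chi2_of

        # two passes: the second adds the forward model's own MC shot
        # noise (scaled by the fitted amplitude) to the weights
        chi2_of = make_chi2(1.0 / sig[ok] ** 2)
        mu_a, amp = 0.0, 1.0
        for _ in range(2):
            res = minimize_scalar(lambda mu: chi2_of(mu)[0], bounds=(0.0, 1.0),
                                  method="bounded", options={"xatol": 1e-6})
            mu_a = float(res.x)
            _, amp = chi2_of(mu_a)
            sig_eff2 = sig[ok] ** 2 + (amp ** 2) * m0
            chi2_of = make_chi2(1.0 / sig_eff2)
        chi2_min, amp = chi2_of(mu_a)
        # delta-chi2 = 1 uncertainty by parabola around the minimum
        h = max(0.1 * mu_a, 0.002)
        c_lo = chi2_of(max(mu_a - h, 0.0))[0]
        c_hi = chi2_of(mu_a + h)[0]
        d2 = (c_lo - 2 * chi2_min + c_hi) / h ** 2
        se = math.sqrt(2.0 / d2) if d2 > 0 else float("nan")
        return mu_a, se, amp, chi2_min

    def fit(self, g_profile: bool = True) -> "AbsorptionResults":
        cfg = self.config
        g_values = cfg.g_grid if g_profile else np.array([np.median(cfg.g_grid)])
        chi2s, fits = [], []
        for g in g_values:
            model0 = self._forward_tdr(float(g))
            mu_a, se, amp, chi2_min = self._fit_one(model0)
            chi2s.append(chi2_min)
            fits.append((mu_a, se, amp))
        surface = ChiSquareSurface("g", np.asarray(g_values, float),
                                   np.array(chi2s), payload=fits)
        i = surface.argmin
        mu_a, se, amp = fits[i]
        return AbsorptionResults(self, mu_a, se, amp, surface)


class AbsorptionResults:
    """Stage-2 estimate of the absorption coefficient."""

    def __init__(self, model, mu_a, se, amplitude, chi2_surface: ChiSquareSurface):
        self.model = model
        self.mu_a = mu_a
        self.se = se
        self.amplitude = amplitude
        self.chi2_surface = chi2_surface

    @property
    def g_best(self) -> float:
        return self.chi2_surface.best

    def to_dict(self) -> dict:
        return {
            "mu_a": self.mu_a, "se_mu_a": self.se,
            "amplitude": self.amplitude, "g_best": self.g_best,
            "chi2_g": {"g": self.chi2_surface.values.tolist(),
                       "chi2": self.chi2_surface.chi2.tolist()},
            "units": {"mu_a": "mm^-1"},
        }

    def summary(self) -> str:
        return "\n".join([
            "Stage-2 absorption fit (integrated time-resolved curve)",
            "=======================================================",
            f"  mu_a = ({self.mu_a:.3f} +/- {self.se:.3f}) mm^-1",
            f"  chi2(g) minimum at g = {self.g_best:.2f}",
        ])


def fit_scattering_stage1(series: MSDSeries,
                          config: FitConfig | None = None) -> ScatteringResults:
    """Functional wrapper over :class:`ScatteringInversion`."""
    return ScatteringInversion(series, config).fit()


def fit_absorption_stage2(curve: TDRCurve, mu_s_eff_perp: float,
                          mu_s_eff_par: float,
                          config: FitConfig | None = None,
                          g_profile: bool = True) -> AbsorptionResults:
    """Functional wrapper over :class:`AbsorptionInversion`."""
    return AbsorptionInversion(curve, mu_s_eff_perp, mu_s_eff_par, config).fit(
        g_profile=g_profile)
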