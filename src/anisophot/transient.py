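"""Transient-imaging analysis: frames -> MSD curves -> diffusion tensor -> OFA.

The measurement this module analyses is a stack of time-gated images of
the diffuse reflectance profile spreading over the sample surface after a
pulsed point-like injection.  Each frame is fitted with a bivariate
Gaussian; the growth of the fitted principal variances with gate delay is
the per-axis mean square displacement (MSD).  In the diffusive regime
MSD_i(t) = 2 D_i t (+ offset), so a weighted linear regression of the
late-time MSD yields the in-plane diffusion tensor components.  The
out-of-plane fiber elevation angle alpha projects the parallel rate onto
the surface (D_y,measured = D_par cos(alpha)), which is undone before the
Optical Fractional Anisotropy is computed under uniaxial symmetry.

The model/results pair :class:`TransientDiffusionModel` /
:class:`DiffusionResults` wraps the functional chain
(:func:`fit_bivariate_gaussian`, :func:`build_msd_series`,
:func:`regress_diffusion`) in the style of statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .optics import DiffusionTensor, FiberGeometry, compute_ofa, elevation_correct
from .mc import SpaceTimeRecord

__all__ = [
    "DEFAULT_FOV_AREA",
    "TransientStack",
    "GaussianProfileFit",
    "MSDSeries",
    "TDRCurve",
    "DiffusionEstimate",
    "fit_bivariate_gaussian",
    "build_msd_series",
    "regress_diffusion",
    "integrate_time_resolved",
    "TransientDiffusionModel",
    "DiffusionResults",
]

#: default circular field-of-view area, mm^2
DEFAULT_FOV_AREA = 13.2


@dataclass
class TransientStack:
    """A sequence of time-gated reflectance frames.

    ``frames`` is indexed [frame, ix, iy]; ``x0``/``y0`` give the mm
    coordinate of the lower pixel edges so that the beam entry point is at
    (0, 0).  The field of view is a circle of ``fov_area`` mm^2 centered on
    ``fov_center``.
    """

    frames: np.ndarray
    time_stamps: np.ndarray
    pixel_pitch: float
    x0: float
    y0: float
    fov_area: float = DEFAULT_FOV_AREA
    fov_center: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, nx, ny) array")
        if len(self.time_stamps) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.time_stamps)} time stamps")
        if np.any(np.diff(self.time_stamps) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.any(self.time_stamps < 0):
            raise ValueError("time stamps must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be > 0")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be >= 0 (subtract background first)")

    @classmethod
    def from_record(cls, record: SpaceTimeRecord,
                    fov_area: float = DEFAULT_FOV_AREA, **meta) -> "TransientStack":
        """Render a simulated :class:`SpaceTimeRecord` as a frame stack."""
        frames = np.moveaxis(record.intensity, -1, 0).copy()
        return cls(
            frames=frames,
            time_stamps=record.t_centers.copy(),
            pixel_pitch=record.grid.pixel_pitch,
            x0=record.grid.x0,
            y0=record.grid.y0,
            fov_area=fov_area,
            meta={"photons_launched": record.photons_launched, **record.meta, **meta},
        )

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.frames.shape[1]) + 0.5) * self.pixel_pitch

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.frames.shape[2]) + 0.5) * self.pixel_pitch

    @property
    def fov_mask(self) -> np.ndarray:
        X, Y = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        r2 = self.fov_area / math.pi
        cx, cy = self.fov_center
        return (X - cx) ** 2 + (Y - cy) ** 2 <= r2


@dataclass
class GaussianProfileFit:
    """Result of a bivariate Gaussian profile fit.

    ``var1``/``var2`` are the variances along the principal axes, with
    ``rotation`` the CCW angle (deg, normalized to (-90, 90]) of axis 1
    from +x.  ``rotation_indeterminate`` is set when the profile is
    rotationally symmetric within the fit uncertainty.
    """

    amplitude: float
    center: tuple[float, float]
    var1: float
    var2: float
    rotation: float
    offset: float
    cov: np.ndarray
    rotation_indeterminate: bool = False
    n_pixels: int = 0

    @property
    def var_errors(self) -> tuple[float, float]:
        return (math.sqrt(max(self.cov[3, 3], 0.0)),
                math.sqrt(max(self.cov[4, 4], 0.0)))


@dataclass
class MSDSeries:
    """Per-axis MSD curves in the rotated (principal-axis) frame.

    ``msd_par`` is the axis with the faster late-time expansion (or the
    axis chosen from a supplied fiber geometry); ``rotation`` is the
    in-plane angle of the parallel axis from +x, degrees.
    """

    times: np.ndarray
    msd_par: np.ndarray
    msd_perp: np.ndarray
    err_par: np.ndarray
    err_perp: np.ndarray
    rotation: float
    meta: dict = field(default_factory=dict)


@dataclass
class TDRCurve:
    """Spatially integrated time-domain reflectance."""

    times: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if np.any(self.uncertainty <= 0):
            raise ValueError("uncertainties must be positive")


@dataclass
class DiffusionEstimate:
    """Regressed diffusion tensor with uncertainties and the derived OFA."""

    tensor: DiffusionTensor
    se_perp: float
    se_par: float
    ofa: float
    ofa_se: float
    t_min: float
    rotation: float
    slopes: dict = field(default_factory=dict)


def _gauss_model(p, xs, ys, theta=None):
    a, cx, cy, s1, s2 = p[:5]
    if theta is None:
        th = math.radians(p[5])
        off = p[6]
    else:
        th = math.radians(theta)
        off = p[5]
    ct, st = math.cos(th), math.sin(th)
    dx = xs - cx
    dy = ys - cy
    u = ct * dx + st * dy
    w = -st * dx + ct * dy
    return a * np.exp(-0.5 * (u * u / s1 + w * w / s2)) + off


def fit_bivariate_gaussian(
    frame: np.ndarray,
    x_centers: np.ndarray,
    y_centers: np.ndarray,
    mask: np.ndarray | None = None,
    fixed_rotation: float | None = None,
    pixel_weighting: str = "uniform",
) -> GaussianProfileFit:
    """Weighted least-squares fit of a rotated bivariate Gaussian + offset.

    The fit runs on pixels inside ``mask`` (all pixels if None).  The
    background offset is constrained non-negative.  ``pixel_weighting``:
    ``"uniform"`` (default) or ``"poisson"`` (sigma = sqrt(I + 1); only
    appropriate when pixel values are counts with good statistics).
    """
    X, Y = np.meshgrid(x_centers, y_centers, indexing="ij")
    if mask is None:
        mask = np.ones_like(frame, dtype=bool)
    w = frame[mask].astype(float)
    xs = X[mask]
    ys = Y[mask]
    if w.size < 50:
        raise ValueError(f"need >= 50 unmasked pixels, got {w.size}")
    tot = w.sum()
    if tot <= 0 or np.ptp(w) == 0:
        raise ValueError("flat or empty frame: bivariate Gaussian fit is degenerate")

    # moment-based initialization (baseline-subtracted)
    base = np.percentile(w, 5)
    wpos = np.clip(w - base, 0.0, None)
    tpos = wpos.sum()
    if tpos <= 0:
        raise ValueError("frame has no intensity above baseline")
    mx = (wpos * xs).sum() / tpos
    my = (wpos * ys).sum() / tpos
    cxx = (wpos * (xs - mx) ** 2).sum() / tpos
    cyy = (wpos * (ys - my) ** 2).sum() / tpos
    cxy = (wpos * (xs - mx) * (ys - my)).sum() / tpos
    cov2 = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov2)
    s2_0, s1_0 = max(evals[0], 1e-6), max(evals[1], 1e-6)
    theta0 = math.degrees(math.atan2(evecs[1, 1], evecs[0, 1]))

    if pixel_weighting == "uniform":
        sig = np.ones_like(w)
    elif pixel_weighting == "poisson":
        sig = np.sqrt(w + 1.0)
    else:
        raise ValueError(f"unknown pixel weighting {pixel_weighting!r}")

    amp0 = max(w.max() - base, 1e-12)
    span = max(abs(xs).max(), abs(ys).max())
    if fixed_rotation is None:
        p0 = [amp0, mx, my, s1_0, s2_0, theta0, max(base, 0.0)]
        lb = [0.0, -span, -span, 1e-9, 1e-9, -180.0, 0.0]
        ub = [np.inf, span, span, np.inf, np.inf, 180.0, np.inf]
        theta_arg = None
    else:
        p0 = [amp0, mx, my, s1_0, s2_0, max(base, 0.0)]
        lb = [0.0, -span, -span, 1e-9, 1e-9, 0.0]
        ub = [np.inf, span, span, np.inf, np.inf, np.inf]
        theta_arg = fixed_rotation

    res = least_squares(
        lambda p: (_gauss_model(p, xs, ys, theta_arg) - w) / sig,
        p0, bounds=(lb, ub), max_nfev=50000,
    )
    if not res.success and res.status <= 0:
        raise ValueError(f"bivariate Gaussian fit failed: {res.message}")
    p = res.x

    # parameter covariance from the Jacobian
    dof = max(w.size - len(p), 1)
    s_res2 = 2.0 * res.cost / dof
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        cov_p = jtj_inv * s_res2
    except np.linalg.LinAlgError:
        cov_p = np.full((len(p), len(p)), np.nan)

    if fixed_rotation is None:
        a, cx, cy, s1, s2, th, off = p
        # normalize: axis-1 variance listed first, theta in (-90, 90]
        th = ((th + 90.0) % 180.0) - 90.0
        if th <= -90.0:
            th += 180.0
        cov7 = np.zeros((7, 7))
        cov7[:cov_p.shape[0], :cov_p.shape[1]] = cov_p
        indet = abs(s1 - s2) < 3.0 * math.sqrt(
            max(cov_p[3, 3] + cov_p[4, 4], 0.0)) or abs(s1 - s2) < 1e-9 * (s1 + s2)
        return GaussianProfileFit(
            amplitude=a, center=(cx, cy), var1=s1, var2=s2, rotation=th,
            offset=off, cov=cov7, rotation_indeterminate=bool(indet),
            n_pixels=w.size,
        )
    a, cx, cy, s1, s2, off = p
    cov7 = np.zeros((7, 7))
    cov7[:5, :5] = cov_p[:5, :5]
    cov7[6, 6] = cov_p[5, 5]
    return GaussianProfileFit(
        amplitude=a, center=(cx, cy), var1=s1, var2=s2,
        rotation=fixed_rotation, offset=off, cov=cov7,
        rotation_indeterminate=False, n_pixels=w.size,
    )


def _weighted_orientation_mean(angles_deg, weights) -> float:
    """Weighted circular mean of axial data (period 180 deg)."""
    a2 = np.radians(2.0 * np.asarray(angles_deg))
    w = np.asarray(weights)
    s = (w * np.sin(a2)).sum()
    c = (w * np.cos(a2)).sum()
    th = 0.5 * math.degrees(math.atan2(s, c))
    th = ((th + 90.0) % 180.0) - 90.0
    return th


def build_msd_series(
    stack: TransientStack,
    t_min: float = 10.0,
    geometry: FiberGeometry | None = None,
    assign_from_geometry: bool = False,
    msd_rel_floor: float = 0.01,
    rotation: float | None = None,
    par_is_axis1: bool | None = None,
) -> MSDSeries:
    """Fit every frame and assemble per-axis MSD curves.

    A single global in-plane rotation is estimated as the uncertainty-
    weighted circular mean of the late-time (t > ``t_min``) frame
    orientations, then every frame is re-fitted with that rotation fixed.
    The parallel axis is the one with the larger late-time expansion rate
    unless ``assign_from_geometry`` forces it from ``geometry``.
    ``msd_rel_floor`` adds a relative acquisition-noise term to the fit
    uncertainties in quadrature.  Passing ``rotation`` (deg) skips the
    free-rotation estimation pass and analyses the stack in that fixed
    frame (used when comparing forward-model stacks against data whose
    principal frame is already known).
    """
    if len(stack.frames) < 3:
        raise ValueError("need at least 3 frames")
    mask = stack.fov_mask
    x = stack.x_centers
    y = stack.y_centers
    times = stack.time_stamps
    late = times > t_min
    if not late.any():
        late = times >= np.median(times)

    if rotation is not None:
        theta = rotation
    else:
        free_fits: list[GaussianProfileFit] = []
        failures = []
        for k, frame in enumerate(stack.frames):
            try:
                free_fits.append(fit_bivariate_gaussian(frame, x, y, mask))
            except ValueError as err:
                failures.append((k, str(err)))
        if failures:
            raise ValueError(f"frame fits failed: {failures}")
        angles, weights = [], []
        for k in np.where(late)[0]:
            f = free_fits[k]
            if f.rotation_indeterminate:
                continue
            var_th = f.cov[5, 5]
            # canonical orientation: angle of the major axis (the fit may
            # list either principal axis first)
            th_major = f.rotation if f.var1 >= f.var2 else f.rotation + 90.0
            angles.append(th_major)
            weights.append(1.0 / max(var_th, 1e-4))
        if angles:
            theta = _weighted_orientation_mean(angles, weights)
        else:
            theta = 0.0  # rotationally symmetric stack

    fits = [fit_bivariate_gaussian(frame, x, y, mask, fixed_rotation=theta)
            for frame in stack.frames]
    v1 = np.array([f.var1 for f in fits])
    v2 = np.array([f.var2 for f in fits])
    e1 = np.array([f.var_errors[0] for f in fits])
    e2 = np.array([f.var_errors[1] for f in fits])
    e1 = np.sqrt(e1 ** 2 + (msd_rel_floor * v1) ** 2)
    e2 = np.sqrt(e2 ** 2 + (msd_rel_floor * v2) ** 2)

    # axis assignment: larger late-time growth = parallel
    if par_is_axis1 is not None:
        pass
    elif assign_from_geometry:
        if geometry is None:
            raise ValueError("assign_from_geometry requires a FiberGeometry")
        d = abs(((geometry.in_plane_angle - theta) + 90.0) % 180.0 - 90.0)
        par_is_axis1 = d < 45.0
    elif par_is_axis1 is None:
        g1 = np.polyfit(times[late], v1[late], 1)[0]
        g2 = np.polyfit(times[late], v2[late], 1)[0]
        par_is_axis1 = g1 >= g2
    if par_is_axis1:
        msd_par, msd_perp, err_par, err_perp = v1, v2, e1, e2
        rot_par = theta
    else:
        msd_par, msd_perp, err_par, err_perp = v2, v1, e2, e1
        rot_par = ((theta + 90.0 + 90.0) % 180.0) - 90.0

    return MSDSeries(
        times=times.copy(), msd_par=msd_par, msd_perp=msd_perp,
        err_par=err_par, err_perp=err_perp, rotation=rot_par,
        meta={"t_min": t_min, "global_rotation_axis1": theta,
              "par_is_axis1": bool(par_is_axis1)},
    )


def _wls_line(t, v, sig):
    """Weighted least-squares line fit; returns (slope, intercept, se_slope)."""
    w = 1.0 / np.asarray(sig) ** 2
    A = np.vstack([t, np.ones_like(t)]).T
    W = np.diag(w)
    cov = np.linalg.inv(A.T @ W @ A)
    beta = cov @ (A.T @ (w * v))
    return beta[0], beta[1], math.sqrt(max(cov[0, 0], 0.0))


def regress_diffusion(
    series: MSDSeries,
    t_min: float = 10.0,
    geometry: FiberGeometry | None = None,
) -> DiffusionEstimate:
    """Late-time weighted regression of the MSD curves.

    Per axis, MSD = slope * t + intercept for t > ``t_min`` and
    D = slope / 2.  The parallel component is corrected for the fiber
    elevation angle (D_par = D_y,measured / cos(alpha)); the tensor is
    completed uniaxially (perpendicular value on two axes) and the OFA
    computed with first-order error propagation.
    """
    sel = series.times > t_min
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 MSD points with t > {t_min}")
    t = series.times[sel]
    slope_perp, _, se_sl_perp = _wls_line(t, series.msd_perp[sel], series.err_perp[sel])
    slope_par, _, se_sl_par = _wls_line(t, series.msd_par[sel], series.err_par[sel])
    if slope_perp <= 0 or slope_par <= 0:
        raise ValueError("non-positive MSD slope: no diffusive expansion detected")

    d_perp_meas = slope_perp / 2.0
    d_par_meas = slope_par / 2.0
    alpha = geometry.elevation_alpha if geometry is not None else 0.0
    tensor = elevation_correct(d_perp_meas, d_par_meas, alpha)
    ca = math.cos(math.radians(alpha))
    se_perp = se_sl_perp / 2.0
    se_par = (se_sl_par / 2.0) / ca

    d_par = tensor.d_y
    d_perp = tensor.d_x
    ofa = compute_ofa(tensor)
    # first-order propagation through the OFA formula (uniaxial)
    eps = 1e-8
    dofa_dpar = (compute_ofa(DiffusionTensor(d_perp, d_par * (1 + eps), d_perp)) - ofa) / (d_par * eps)
    dofa_dperp = (compute_ofa(DiffusionTensor.uniaxial(d_par, d_perp * (1 + eps))) - ofa) / (d_perp * eps)
    ofa_se = math.sqrt((dofa_dpar * se_par) ** 2 + (dofa_dperp * se_perp) ** 2)

    return DiffusionEstimate(
        tensor=tensor, se_perp=se_perp, se_par=se_par,
        ofa=ofa, ofa_se=ofa_se, t_min=t_min, rotation=series.rotation,
        slopes={"slope_perp": slope_perp, "slope_par": slope_par,
                "elevation_alpha_deg": alpha},
    )


def integrate_time_resolved(source: TransientStack | SpaceTimeRecord,
                            use_fov: bool = True) -> TDRCurve:
    """Accumulate the intensity over the (masked) field of view per time bin.

    Uncertainties are Poisson-type: sqrt of the accumulated signal, with a
    floor of 1 where bins are empty.
    """
    if isinstance(source, SpaceTimeRecord):
        stack = TransientStack.from_record(source)
    else:
        stack = source
    mask = stack.fov_mask if use_fov else np.ones(stack.frames.shape[1:], bool)
    if not mask.any():
        raise ValueError("empty field-of-view mask")
    vals = np.array([frame[mask].sum() for frame in stack.frames])
    unc = np.sqrt(np.maximum(vals, 1.0))
    return TDRCurve(times=stack.time_stamps.copy(), intensity=vals, uncertainty=unc,
                    meta={"fov_area": stack.fov_area if use_fov else None})


class TransientDiffusionModel:
    """Diffusion-tensor model for a transient reflectance frame stack.

    Parameters
    ----------
    stack : TransientStack
        Time-gated frames with calibrated time stamps and pixel pitch.
    geometry : FiberGeometry, optional
        Fiber-bundle orientation; supplies the elevation angle used to
        de-project the parallel diffusion rate.
    t_min : float
        Lower edge (ps) of the diffusive regression window.

    Examples
    --------
    >>> model = TransientDiffusionModel(stack, geometry=FiberGeometry(elevation_alpha=31.0))
    >>> results = model.fit()
    >>> print(results.summary())      # doctest: +SKIP
    """

    def __init__(self, stack: TransientStack, geometry: FiberGeometry | None = None,
                 t_min: float = 10.0):
        self.stack = stack
        self.geometry = geometry
        self.t_min = t_min

    def fit(self, assign_from_geometry: bool = False) -> "DiffusionResults":
        series = build_msd_series(self.stack, t_min=self.t_min,
                                  geometry=self.geometry,
                                  assign_from_geometry=assign_from_geometry)
        est = regress_diffusion(series, t_min=self.t_min, geometry=self.geometry)
        return DiffusionResults(self, series, est)


class DiffusionResults:
    """Fitted diffusion tensor, uncertainties and OFA for a frame stack."""

    def __init__(self, model: TransientDiffusionModel, msd: MSDSeries,
                 estimate: DiffusionEstimate):
        self.model = model
        self.msd = msd
        self.estimate = estimate

    @property
    def d_perp(self) -> float:
        return self.estimate.tensor.d_x

    @property
    def d_par(self) -> float:
        return self.estimate.tensor.d_y

    @property
    def bse(self) -> dict:
        return {"d_perp": self.estimate.se_perp, "d_par": self.estimate.se_par}

    @property
    def ofa(self) -> float:
        return self.estimate.ofa

    @property
    def ofa_se(self) -> float:
        return self.estimate.ofa_se

    def to_dict(self) -> dict:
        e = self.estimate
        return {
            "d_perp": self.d_perp, "d_par": self.d_par,
            "se_d_perp": e.se_perp, "se_d_par": e.se_par,
            "ofa": e.ofa, "se_ofa": e.ofa_se,
            "rotation_deg": e.rotation, "t_min_ps": e.t_min,
            "elevation_alpha_deg": e.slopes.get("elevation_alpha_deg", 0.0),
            "units": {"d": "mm^2/ps", "t": "ps", "rotation": "deg"},
        }

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Transient diffusion-tensor fit",
            "==============================",
            f"frames: {len(self.model.stack.frames)}, "
            f"window: t > {e.t_min:g} ps, rotation: {e.rotation:+.1f} deg",
            f"elevation alpha: {e.slopes.get('elevation_alpha_deg', 0.0):.1f} deg",
            "",
            f"  D_perp = ({self.d_perp * 100:.3f} +/- {e.se_perp * 100:.3f}) x 1e-2 mm^2/ps",
            f"  D_par  = ({self.d_par * 100:.3f} +/- {e.se_par * 100:.3f}) x 1e-2 mm^2/ps",
            f"  OFA    = {e.ofa:.3f} +/- {e.ofa_se:.3f}",
        ]
        return "\n".join(lines)
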