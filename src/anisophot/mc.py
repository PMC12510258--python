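"""Anisotropic photon Monte Carlo in layered slab media.

The simulator launches photons into a stack of layers (z = 0 at the
surface, z growing into the tissue), alternating exponential free flights
with a direction-dependent tensor scattering rate, Henyey-Greenstein
deflections with the layer's scalar g, and unpolarized Fresnel events at
refractive-index boundaries.  Photons escaping through the top surface are
binned by exit position and elapsed time into a :class:`SpaceTimeRecord`.

Two tensor rate laws are available (``tensor_model``):

``"norm"`` (default)
    mu_s(s) = || diag(mu_s_x, mu_s_y, mu_s_z) . s ||_2
``"quadratic"``
    mu_s(s) = sum_i mu_s_i s_i^2

Both reduce exactly to the principal components along the tensor axes and
are bounded by [min_i mu_s_i, max_i mu_s_i] for unit directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .optics import OpticalTensorProperties, speed_in_medium

__all__ = [
    "Layer",
    "LayeredMedium",
    "SourceSpec",
    "DetectionGrid",
    "SpaceTimeRecord",
    "TENSOR_MODELS",
    "directional_scattering_coefficient",
    "sample_free_path",
    "sample_hg_deflection",
    "fresnel_reflectance",
    "fresnel_interface",
    "propagate",
    "absorption_reweight",
]

TENSOR_MODELS = {"norm": 0, "quadratic": 1}

DEFAULT_ROULETTE_WEIGHT = 1e-4
DEFAULT_ROULETTE_FACTOR = 10.0


def _rotation_about_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class Layer:
    """One slab layer.  ``thickness`` may be ``np.inf`` (semi-infinite).

    ``fiber_frame`` maps lab directions onto the layer's tensor principal
    axes; the convenience field ``in_plane_angle`` builds it as a rotation
    about z (fibers lying in the surface plane).
    """

    thickness: float
    properties: OpticalTensorProperties
    in_plane_angle: float = 0.0
    fiber_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")

    @property
    def rotation(self) -> np.ndarray:
        if self.fiber_frame is not None:
            return np.asarray(self.fiber_frame, dtype=float)
        return _rotation_about_z(self.in_plane_angle)


@dataclass(frozen=True)
class LayeredMedium:
    """Ordered stack of layers below z = 0 with ambient index on top.

    ``bottom_escape`` controls the deepest boundary when the last layer is
    finite: True (default) treats it as an absorbing escape, otherwise the
    last layer is extended to a semi-infinite half-space.
    """

    layers: tuple[Layer, ...]
    ambient_n: float = 1.0
    bottom_escape: bool = True

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("medium needs at least one layer")

    @classmethod
    def semi_infinite(cls, properties: OpticalTensorProperties,
                      in_plane_angle: float = 0.0, ambient_n: float = 1.0) -> "LayeredMedium":
        return cls(layers=(Layer(np.inf, properties, in_plane_angle),), ambient_n=ambient_n)

    @property
    def z_edges(self) -> np.ndarray:
        edges = [0.0]
        for i, layer in enumerate(self.layers):
            thick = layer.thickness
            if i == len(self.layers) - 1 and not (np.isfinite(thick) and self.bottom_escape):
                edges.append(np.inf)
            else:
                edges.append(edges[-1] + thick)
        return np.array(edges)

    @property
    def is_homogeneous(self) -> bool:
        return len(self.layers) == 1


@dataclass(frozen=True)
class SourceSpec:
    """Pencil-beam pulse entering at ``entry_point`` with ``incidence_angle``
    degrees off the surface normal (in the x-z plane), refracted at entry.
    A delta pulse at t = 0; ``gate_fwhm`` optionally records the temporal
    gate width (metadata; convolution is applied downstream if requested)."""

    incidence_angle: float = 13.0
    entry_point: tuple[float, float] = (0.0, 0.0)
    gate_fwhm: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence_angle < 90.0:
            raise ValueError("incidence angle must lie in [0, 90) degrees")

    def refracted_direction(self, n_ambient: float, n_medium: float) -> np.ndarray:
        """Initial direction inside the medium after Snell refraction."""
        sin_i = math.sin(math.radians(self.incidence_angle))
        sin_t = sin_i * n_ambient / n_medium
        cos_t = math.sqrt(1.0 - sin_t * sin_t)
        return np.array([sin_t, 0.0, cos_t])


@dataclass(frozen=True)
class DetectionGrid:
    """Top-surface detection raster and time binning.

    Pixels are squares of side ``pixel_pitch`` starting at (x0, y0);
    time bins are half-open [t, t+dt) with values reported at centers.
    """

    pixel_pitch: float
    nx: int
    ny: int
    x0: float
    y0: float
    time_bin_edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.time_bin_edges, dtype=float)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be > 0")
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("time bin edges must be strictly increasing, >= 2 values")
        object.__setattr__(self, "time_bin_edges", edges)

    @classmethod
    def centered(cls, half_extent: float, pixel_pitch: float,
                 time_bin_edges) -> "DetectionGrid":
        n = int(round(2.0 * half_extent / pixel_pitch))
        return cls(pixel_pitch=pixel_pitch, nx=n, ny=n,
                   x0=-half_extent, y0=-half_extent,
                   time_bin_edges=np.asarray(time_bin_edges, dtype=float))

    @classmethod
    def quadrant(cls, side: float, cells: int, time_bin_edges) -> "DetectionGrid":
        return cls(pixel_pitch=side / cells, nx=cells, ny=cells, x0=0.0, y0=0.0,
                   time_bin_edges=np.asarray(time_bin_edges, dtype=float))

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.pixel_pitch

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.pixel_pitch

    @property
    def t_centers(self) -> np.ndarray:
        e = self.time_bin_edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class SpaceTimeRecord:
    """Space- and time-resolved reflectance I(x, y, t).

    ``intensity`` is indexed [ix, iy, it] and holds escaped photon weight
    per surface pixel per time bin.  ``accounting`` tracks the fate of all
    launched weight (escaped in/out of grid, absorbed, transmitted through
    the bottom, terminated by the time gate, net roulette gain).
    """

    intensity: np.ndarray
    grid: DetectionGrid
    photons_launched: int
    accounting: dict
    v: float
    mu_a_applied: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def x_centers(self) -> np.ndarray:
        return self.grid.x_centers

    @property
    def y_centers(self) -> np.ndarray:
        return self.grid.y_centers

    @property
    def t_centers(self) -> np.ndarray:
        return self.grid.t_centers

    def frame(self, it: int) -> np.ndarray:
        return self.intensity[:, :, it]

    def weight_balance(self) -> tuple[float, float]:
        """(accounted weight, launched weight); equal up to float error."""
        a = self.accounting
        accounted = (a["escaped_grid"] + a["escaped_out"] + a["absorbed"]
                     + a["transmitted"] + a["terminated"] - a["roulette_gain"])
        return accounted, float(self.photons_launched)


def directional_scattering_coefficient(
    direction, props: OpticalTensorProperties, tensor_model: str = "norm"
) -> float | np.ndarray:
    """Scattering rate for propagation along ``direction`` (tensor frame).

    Accepts a single unit vector or an (N, 3) array of unit vectors.
    """
    s = np.asarray(direction, dtype=float)
    single = s.ndim == 1
    s2 = np.atleast_2d(s)
    norms = np.linalg.norm(s2, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("direction vector must be non-zero")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("direction must be a unit vector")
    mu = props.mu_s
    if tensor_model == "norm":
        out = np.sqrt(np.sum((s2 * mu) ** 2, axis=1))
    elif tensor_model == "quadratic":
        out = np.sum(mu * s2 ** 2, axis=1)
    else:
        raise ValueError(f"unknown tensor model {tensor_model!r}")
    return float(out[0]) if single else out


def sample_free_path(direction, props: OpticalTensorProperties, rng: np.random.Generator,
                     tensor_model: str = "norm", size=None):
    """Exponential free-path sample(s) with the direction-dependent rate
    held fixed over the flight segment."""
    rate = directional_scattering_coefficient(direction, props, tensor_model)
    return rng.exponential(scale=1.0 / rate, size=size)


def sample_hg_deflection(g: float, rng: np.random.Generator, size=None):
    """Cosine of the Henyey-Greenstein polar deflection angle.

    Inverse-CDF sampling; the sample mean converges to g."""
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must lie in [0, 1), got {g}")
    u = rng.random(size=size)
    if g < 1e-8:
        return 1.0 - 2.0 * u
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - frac * frac) / (2.0 * g), -1.0, 1.0)


def fresnel_reflectance(n_in: float, n_out: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_i``."""
    if not 0.0 < cos_i <= 1.0:
        raise ValueError("cos_i must lie in (0, 1]")
    return _kernel._fresnel_r.py_func(n_in, n_out, cos_i)


def fresnel_interface(direction, n_in: float, n_out: float,
                      rng: np.random.Generator, normal=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Stochastic Fresnel event at a planar boundary.

    Reflects with the unpolarized Fresnel probability (certain beyond the
    critical angle), otherwise returns the Snell-refracted direction.
    """
    u = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos_i = abs(float(u @ n))
    if cos_i < 1e-12:
        raise ValueError("grazing incidence is degenerate")
    refl = fresnel_reflectance(n_in, n_out, cos_i)
    if rng.random() < refl:
        return u - 2.0 * (u @ n) * n
    eta = n_in / n_out
    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
    tangential = u - (u @ n) * n
    sign = 1.0 if (u @ n) > 0 else -1.0
    out = eta * tangential + sign * cos_t * n
    return out / np.linalg.norm(out)


def propagate(
    medium: LayeredMedium,
    source: SourceSpec,
    grid: DetectionGrid,
    n_photons: int,
    seed: int,
    tensor_model: str = "norm",
    roulette_weight: float = DEFAULT_ROULETTE_WEIGHT,
    roulette_factor: float = DEFAULT_ROULETTE_FACTOR,
) -> SpaceTimeRecord:
    """Run the photon Monte Carlo and return the binned reflectance.

    Deterministic for fixed (seed, n_photons, configuration): every photon
    owns an RNG substream keyed by (seed, photon index).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if tensor_model not in TENSOR_MODELS:
        raise ValueError(f"unknown tensor model {tensor_model!r}")
    layers = medium.layers
    n_layers = len(layers)
    mu_s = np.array([lay.properties.mu_s for lay in layers])
    g_l = np.array([lay.properties.g for lay in layers])
    mu_a_l = np.array([lay.properties.mu_a for lay in layers])
    n_l = np.array([lay.properties.n_eff for lay in layers])
    v_l = np.array([speed_in_medium(n) for n in n_l])
    rot = np.array([lay.rotation for lay in layers])
    z_edges = medium.z_edges
    u0 = source.refracted_direction(medium.ambient_n, layers[0].properties.n_eff)

    intensity = np.zeros((grid.nx, grid.ny, len(grid.time_bin_edges) - 1))
    accounting = np.zeros(_kernel.ACC_N)
    _kernel.propagate_kernel(
        n_photons, seed,
        u0[0], u0[1], u0[2],
        z_edges, mu_s, g_l, mu_a_l, n_l, v_l, rot,
        TENSOR_MODELS[tensor_model], medium.ambient_n,
        grid.x0, grid.y0, grid.pixel_pitch, grid.nx, grid.ny,
        grid.time_bin_edges,
        intensity, accounting,
        roulette_weight, roulette_factor,
    )
    acc = {
        "escaped_grid": accounting[_kernel.ACC_ESCAPED_GRID],
        "escaped_out": accounting[_kernel.ACC_ESCAPED_OUT],
        "absorbed": accounting[_kernel.ACC_ABSORBED],
        "transmitted": accounting[_kernel.ACC_TRANSMITTED],
        "terminated": accounting[_kernel.ACC_TERMINATED],
        "roulette_gain": accounting[_kernel.ACC_ROULETTE_GAIN],
    }
    mu_a_applied = float(np.max(mu_a_l))
    return SpaceTimeRecord(
        intensity=intensity,
        grid=grid,
        photons_launched=n_photons,
        accounting=acc,
        v=float(v_l[0]),
        mu_a_applied=mu_a_applied,
        meta={
            "tensor_model": tensor_model,
            "seed": int(seed),
            "incidence_angle_deg": source.incidence_angle,
            "n_layers": n_layers,
        },
    )


def absorption_reweight(record: SpaceTimeRecord, mu_a: float) -> SpaceTimeRecord:
    """Apply homogeneous absorption to a mu_a = 0 record.

    With continuous Beer-Lambert weighting and a single medium, the photon
    path length at elapsed time t is exactly v t, so each time bin scales
    by exp(-mu_a v t_center) while spatial profile shapes are untouched.
    """
    if record.mu_a_applied != 0.0:
        raise ValueError("record already carries absorption; reweight only mu_a = 0 runs")
    if mu_a < 0:
        raise ValueError("mu_a must be >= 0")
    factors = np.exp(-mu_a * record.v * record.t_centers)
    new = SpaceTimeRecord(
        intensity=record.intensity * factors[None, None, :],
        grid=record.grid,
        photons_launched=record.photons_launched,
        accounting=dict(record.accounting),
        v=record.v,
        mu_a_applied=mu_a,
        meta={**record.meta, "absorption_reweighted": True},
    )
    return new
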