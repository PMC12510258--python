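"""Tensor optics of anisotropic turbid media.

Light transport in fibrous tissue (white matter, muscle, tendon) is
direction dependent: elongated scatterers make the scattering coefficient a
diagonal tensor in the frame of the fiber bundle while the single-scattering
asymmetry factor g is kept scalar.  The practical trade-off quantity is the
*effective reduced scattering coefficient* per axis,

    mu_s_eff_i' = mu_s_i * (1 - g),

which is NOT the true reduced scattering coefficient of the anisotropic
medium but is the robust parameter pair retrieved from transient data.

The degree of transport anisotropy is summarised by the Optical Fractional
Anisotropy (OFA), the fractional-anisotropy formula of DTI applied to the
light diffusion tensor.

Units are fixed package-wide: lengths in mm, times in ps, rates in mm^-1,
diffusion coefficients in mm^2/ps.  Angles cross interfaces in degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "C_MM_PER_PS",
    "OpticalTensorProperties",
    "DiffusionTensor",
    "FiberGeometry",
    "speed_in_medium",
    "effective_reduced_scattering",
    "scattering_from_reduced",
    "isotropic_diffusion_coefficient",
    "compute_ofa",
    "elevation_correct",
    "load_fixture",
]

#: speed of light in vacuum, mm / ps
C_MM_PER_PS = 0.299792458


def speed_in_medium(n_eff: float) -> float:
    """Energy transport speed v = c / n_eff in mm/ps."""
    if n_eff < 1.0:
        raise ValueError(f"n_eff must be >= 1, got {n_eff}")
    return C_MM_PER_PS / n_eff


@dataclass(frozen=True)
class OpticalTensorProperties:
    """Optical properties of one medium with a diagonal scattering tensor.

    Parameters
    ----------
    mu_s_x, mu_s_y, mu_s_z : float
        Principal scattering coefficients, mm^-1 (tensor frame).
    g : float
        Scalar Henyey-Greenstein asymmetry factor, 0 <= g < 1.
    mu_a : float
        Absorption coefficient, mm^-1.
    n_eff : float
        Effective refractive index (>= 1).
    """

    mu_s_x: float
    mu_s_y: float
    mu_s_z: float
    g: float = 0.0
    mu_a: float = 0.0
    n_eff: float = 1.39

    def __post_init__(self) -> None:
        if min(self.mu_s_x, self.mu_s_y, self.mu_s_z) <= 0:
            raise ValueError("all scattering tensor components must be > 0")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.n_eff < 1.0:
            raise ValueError("n_eff must be >= 1")

    @classmethod
    def uniaxial(
        cls,
        mu_s_perp: float,
        mu_s_par: float,
        fiber_axis: str = "y",
        g: float = 0.0,
        mu_a: float = 0.0,
        n_eff: float = 1.39,
    ) -> "OpticalTensorProperties":
        """Uniaxial medium: the parallel value sits on ``fiber_axis``, the
        perpendicular value on the remaining two axes."""
        if fiber_axis not in ("x", "y", "z"):
            raise ValueError("fiber_axis must be 'x', 'y' or 'z'")
        comps = {"x": mu_s_perp, "y": mu_s_perp, "z": mu_s_perp}
        comps[fiber_axis] = mu_s_par
        return cls(comps["x"], comps["y"], comps["z"], g=g, mu_a=mu_a, n_eff=n_eff)

    @classmethod
    def isotropic(
        cls, mu_s: float, g: float = 0.0, mu_a: float = 0.0, n_eff: float = 1.39
    ) -> "OpticalTensorProperties":
        return cls(mu_s, mu_s, mu_s, g=g, mu_a=mu_a, n_eff=n_eff)

    @property
    def mu_s(self) -> np.ndarray:
        return np.array([self.mu_s_x, self.mu_s_y, self.mu_s_z])

    @property
    def mu_s_eff_prime(self) -> np.ndarray:
        """Effective reduced scattering tensor components mu_s_i (1-g)."""
        return self.mu_s * (1.0 - self.g)

    @property
    def v(self) -> float:
        """Transport speed in the medium, mm/ps."""
        return speed_in_medium(self.n_eff)

    def to_dict(self) -> dict:
        return {
            "mu_s_x": self.mu_s_x,
            "mu_s_y": self.mu_s_y,
            "mu_s_z": self.mu_s_z,
            "g": self.g,
            "mu_a": self.mu_a,
            "n_eff": self.n_eff,
            "units": {"mu_s": "mm^-1", "mu_a": "mm^-1"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalTensorProperties":
        return cls(
            mu_s_x=d["mu_s_x"], mu_s_y=d["mu_s_y"], mu_s_z=d["mu_s_z"],
            g=d.get("g", 0.0), mu_a=d.get("mu_a", 0.0), n_eff=d.get("n_eff", 1.39),
        )


@dataclass(frozen=True)
class DiffusionTensor:
    """Diagonal light diffusion tensor, mm^2 / ps."""

    d_x: float
    d_y: float
    d_z: float

    def __post_init__(self) -> None:
        if min(self.d_x, self.d_y, self.d_z) <= 0:
            raise ValueError("all diffusion tensor components must be > 0")

    @classmethod
    def uniaxial(cls, d_par: float, d_perp: float, fiber_axis: str = "y") -> "DiffusionTensor":
        """Parallel value on ``fiber_axis``, perpendicular duplicated."""
        comps = {"x": d_perp, "y": d_perp, "z": d_perp}
        comps[fiber_axis] = d_par
        return cls(comps["x"], comps["y"], comps["z"])

    @property
    def diagonal(self) -> np.ndarray:
        return np.array([self.d_x, self.d_y, self.d_z])


@dataclass(frozen=True)
class FiberGeometry:
    """Orientation of the fiber bundle relative to the sample surface.

    ``in_plane_angle`` is the orientation of the fast (parallel) axis within
    the surface plane, degrees CCW from +x.  ``elevation_alpha`` is the tilt
    of the fibers out of the surface plane; it projects the parallel
    diffusion rate onto the measured in-plane rate by cos(alpha).
    ``elevation_sigma`` is the fiber-to-fiber spread of the elevation angle
    and is carried as metadata only.
    """

    in_plane_angle: float = 0.0
    elevation_alpha: float = 0.0
    elevation_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.elevation_alpha <= 90.0:
            raise ValueError("elevation_alpha must lie in [-90, 90] degrees")

    def to_dict(self) -> dict:
        return {
            "in_plane_angle": self.in_plane_angle,
            "elevation_alpha": self.elevation_alpha,
            "elevation_sigma": self.elevation_sigma,
            "units": {"angles": "deg"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberGeometry":
        return cls(
            in_plane_angle=d.get("in_plane_angle", 0.0),
            elevation_alpha=d.get("elevation_alpha", 0.0),
            elevation_sigma=d.get("elevation_sigma", 0.0),
        )


def effective_reduced_scattering(mu_s_component: float, g: float) -> float:
    """mu_s_i (1 - g): the effective reduced scattering component, mm^-1."""
    if mu_s_component <= 0:
        raise ValueError("mu_s_component must be > 0")
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must lie in [0, 1), got {g}")
    return mu_s_component * (1.0 - g)


def scattering_from_reduced(mu_s_prime: float, g: float) -> float:
    """Invert the similarity scaling: mu_s = mu_s' / (1 - g)."""
    if mu_s_prime <= 0:
        raise ValueError("mu_s_prime must be > 0")
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must lie in [0, 1), got {g}")
    return mu_s_prime / (1.0 - g)


def isotropic_diffusion_coefficient(mu_s_prime: float, n_eff: float = 1.39) -> float:
    """Isotropic-limit diffusion coefficient D = v / (3 mu_s'), mm^2/ps.

    Valid as the exact diffusion coefficient only for isotropic media; in
    anisotropic media each tensor component depends on all scattering
    components in a non-trivial way, so this serves as a consistency check
    and fit initialiser, never as the anisotropic map.
    """
    if mu_s_prime <= 0:
        raise ValueError("mu_s_prime must be > 0")
    return speed_in_medium(n_eff) / (3.0 * mu_s_prime)


def compute_ofa(d: DiffusionTensor | np.ndarray) -> float:
    """Optical Fractional Anisotropy of a diagonal diffusion tensor.

    OFA = sqrt(1/2) * sqrt((Dx-Dy)^2 + (Dy-Dz)^2 + (Dz-Dx)^2)
                    / sqrt(Dx^2 + Dy^2 + Dz^2)

    0 for isotropic diffusion, -> 1 for perfectly directional transport.
    """
    if isinstance(d, DiffusionTensor):
        dx, dy, dz = d.d_x, d.d_y, d.d_z
    else:
        dx, dy, dz = np.asarray(d, dtype=float)
    norm2 = dx * dx + dy * dy + dz * dz
    if norm2 <= 0:
        raise ValueError("OFA undefined for the zero tensor")
    spread = (dx - dy) ** 2 + (dy - dz) ** 2 + (dz - dx) ** 2
    return math.sqrt(0.5 * spread / norm2)


def elevation_correct(
    d_x_measured: float, d_y_measured: float, alpha: float
) -> DiffusionTensor:
    """Undo the out-of-plane projection of the fiber bundle.

    With fibers tilted by ``alpha`` degrees out of the surface plane the
    in-plane rates relate to the principal rates by D_x = D_perp and
    D_y = D_par * cos(alpha).  Returns the uniaxial tensor
    (D_perp, D_par, D_perp) with the parallel value on the y axis.
    """
    if not abs(alpha) < 90.0:
        raise ValueError("elevation angle must satisfy |alpha| < 90 degrees")
    d_perp = d_x_measured
    d_par = d_y_measured / math.cos(math.radians(alpha))
    return DiffusionTensor(d_x=d_perp, d_y=d_par, d_z=d_perp)


def load_fixture(name: str) -> dict:
    """Load one of the shipped JSON fixtures (e.g. ``white_matter``,
    ``table1_head``) from the package data directory."""
    fname = name if name.endswith(".json") else f"{name}.json"
    with resources.files("anisophot.data").joinpath(fname).open() as fh:
        return json.load(fh)
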