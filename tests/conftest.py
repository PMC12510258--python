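"""Shared fixtures: fixture media and reusable Monte Carlo runs."""

import numpy as np
import pytest

import anisophot as ap
from anisophot.synth import SyntheticSpec, generate_mc_stack


@pytest.fixture(scope="session")
def wm_fixture() -> dict:
    return ap.load_fixture("white_matter")


@pytest.fixture(scope="session")
def wm_props(wm_fixture) -> ap.OpticalTensorProperties:
    """White-matter optical properties (uniaxial, fibers along y, mu_a = 0)."""
    g = wm_fixture["g"]
    return ap.OpticalTensorProperties.uniaxial(
        mu_s_perp=wm_fixture["mu_s_eff_prime_perp"] / (1 - g),
        mu_s_par=wm_fixture["mu_s_eff_prime_par"] / (1 - g),
        fiber_axis="y", g=g, mu_a=0.0, n_eff=wm_fixture["n_eff"])


@pytest.fixture(scope="session")
def acquisition_grid() -> ap.DetectionGrid:
    """Transient-imaging raster: 5.4 x 5.4 mm^2, 0.05 mm pitch, 1 ps gates."""
    return ap.DetectionGrid.centered(2.7, 0.05, np.arange(0.0, 16.01, 1.0))


@pytest.fixture(scope="session")
def iso_record(acquisition_grid) -> ap.SpaceTimeRecord:
    """Isotropic semi-infinite reference run (mu_s' = 4.4, g = 0, mu_a = 0)."""
    props = ap.OpticalTensorProperties.isotropic(4.4, g=0.0, n_eff=1.39)
    medium = ap.LayeredMedium.semi_infinite(props)
    return ap.propagate(medium, ap.SourceSpec(), acquisition_grid,
                        n_photons=400_000, seed=20)


@pytest.fixture(scope="session")
def aniso_record(wm_props, acquisition_grid) -> ap.SpaceTimeRecord:
    """White-matter fixture run reused across analysis and acceptance tests."""
    medium = ap.LayeredMedium.semi_infinite(wm_props)
    return ap.propagate(medium, ap.SourceSpec(), acquisition_grid,
                        n_photons=2_000_000, seed=7)


@pytest.fixture(scope="session")
def aniso_stack(aniso_record) -> ap.TransientStack:
    return ap.TransientStack.from_record(aniso_record)


@pytest.fixture(scope="session")
def head_pair():
    """Four-layer head runs for both white-matter orientations, common
    random numbers (same seed), scaled photon budget."""
    from anisophot.head import HeadModelConfig, simulate_head
    n = 300_000
    rec_y = simulate_head(HeadModelConfig.from_fixture("y"), n_photons=n, seed=3)
    rec_x = simulate_head(HeadModelConfig.from_fixture("x"), n_photons=n, seed=3)
    return rec_y, rec_x


@pytest.fixture(scope="session")
def wm_mc_stack(wm_props) -> ap.TransientStack:
    """Synthetic camera-noise stack generated from the fixture medium."""
    spec = SyntheticSpec.monte_carlo(wm_props, n_photons=2_000_000, seed=9,
                                     photons_per_frame=500_000.0,
                                     read_noise=1.0)
    return generate_mc_stack(spec)
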