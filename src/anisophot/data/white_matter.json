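{
  "description": "Retrieved optical properties of human brain white matter at 820 nm: uniaxial scattering tensor (effective reduced components), scalar asymmetry, absorption, refractive index, and fiber-bundle geometry.",
  "units": {"mu_s_eff_prime": "mm^-1", "mu_a": "mm^-1", "angles": "deg"},
  "mu_s_eff_prime_perp": 4.4,
  "mu_s_eff_prime_par": 2.6,
  "g": 0.97,
  "mu_a": 0.043,
  "n_eff": 1.39,
  "fiber_axis": "y",
  "fiber_geometry": {
    "in_plane_angle": 0.0,
    "elevation_alpha": 31.0,
    "elevation_sigma": 14.0
  },
  "diffusion_tensor_1e2_mm2_per_ps": {"d_perp": 1.69, "d_par": 2.47},
  "ofa": 0.23
}
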