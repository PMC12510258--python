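{
  "description": "Four-layer human head model at 830 nm: scalp/skull, cerebrospinal fluid, gray matter (isotropic, literature values) and anisotropic white matter (measured values). mu_s_prime entries are reduced scattering coefficients; per-layer mu_s is mu_s_prime / (1 - g). The white matter layer lists the effective reduced tensor components (parallel / perpendicular).",
  "units": {"thickness": "mm", "mu_a": "mm^-1", "mu_s_prime": "mm^-1"},
  "ambient_n": 1.0,
  "layers": [
    {"name": "scalp_skull", "thickness": 10.0, "n": 1.39, "g": 0.89, "mu_a": 0.019, "mu_s_prime": 0.86},
    {"name": "csf", "thickness": 2.5, "n": 1.34, "g": 0.89, "mu_a": 0.0026, "mu_s_prime": 0.16},
    {"name": "gray_matter", "thickness": 3.0, "n": 1.39, "g": 0.9, "mu_a": 0.03, "mu_s_prime": 0.70},
    {"name": "white_matter", "thickness": 10.0, "n": 1.39, "g": 0.97, "mu_a": 0.043,
     "mu_s_eff_prime_par": 2.6, "mu_s_eff_prime_perp": 4.4, "anisotropic": true}
  ],
  "detection": {"grid_cells": 10, "quadrant_side_mm": 50.0},
  "time_windows_ns": [[0.5, 1.5], [1.5, 2.5], [2.5, 3.5], [3.5, 4.5]]
}
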