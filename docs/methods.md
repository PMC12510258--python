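# Methods

This note records the physical model, the estimation chain, the synthetic
data the tests rely on, and the numerical choices made where the design was
genuinely open. Units are fixed package-wide: millimetres, picoseconds,
rates in mm⁻¹, diffusion coefficients in mm²/ps, angles in degrees at every
interface; c = 0.299792458 mm/ps and v = c/n_eff.

## Transport model

A medium is a stack of plane-parallel layers below z = 0 (z positive into
the tissue), each carrying a diagonal scattering tensor
μs = diag(μs,x, μs,y, μs,z) in its own fiber frame (a rotation from the lab
frame, in-plane by default), a scalar Henyey–Greenstein asymmetry g, an
absorption coefficient μa and a refractive index n. Keeping g scalar while
the scattering coefficient is a tensor is a deliberate trade-off: a tensor
g would double the free parameters and make retrieval from data
impractical, and for near-unity asymmetry the pair (μs,i, g) collapses into
the effective reduced components μ̃′s,i = μs,i(1−g), which are the robust
quantities to report.

The photon random walk alternates:

- **Free flights** with exponential path lengths at the direction-dependent
  rate. Two interpolation laws between the principal components are
  implemented: `norm`, μs(ŝ) = ‖diag(μs)·ŝ‖₂ (default), and `quadratic`,
  μs(ŝ) = Σᵢ μs,i ŝᵢ². Both reduce exactly to μs,i along axis i and are
  bounded by the extreme components. The rate is held fixed over a flight
  segment and re-evaluated after every scattering or boundary event;
  boundary crossings truncate the flight and the remaining optical depth is
  re-spent at the new layer's rate (standard layered-MC handling). The
  `norm` law is the default because, at the white-matter operating point,
  its bulk diffusion tensor (measured by infinite-medium ensemble variance)
  reproduces the retrieved tensor ratio best; the choice is recorded in
  every record's provenance metadata.
- **Henyey–Greenstein deflections** about the incoming direction
  (inverse-CDF sampling, uniform azimuth), identical in every direction —
  the anisotropy lives entirely in the rate.
- **Boundary events** with unpolarised Fresnel reflection/refraction;
  total internal reflection beyond the critical angle. Photons leaving the
  top surface are detected; a finite bottom boundary is an absorbing escape
  by default (configurable to a semi-infinite continuation), since nothing
  is assumed about what lies below the deepest layer.
- **Absorption** as continuous microscopic Beer–Lambert weighting with the
  local layer's μa, never as discrete absorption events. Consequences: the
  spatial shape of every time gate is exactly independent of homogeneous
  absorption, and a single μa = 0 run of a homogeneous medium can be
  reweighted to any μa by exp(−μa v t) per time bin (path length = v t).
  The stage-2 absorption fit is built on this identity.

Photons launch at the origin, refracted from a 13°-off-normal pencil beam
(ambient n = 1) by default; a delta pulse at t = 0. Detection bins escaped
weight by exit pixel and time bin (half-open bins, values at centers), with
all top-surface escapes accepted: the off-axis injection / normal collection
geometry only excludes the specular reflection, which never enters the
medium. Russian roulette below weight 10⁻⁴ (survival factor 10) bounds the
walk length in absorbing media; weight accounting tracks escaped, absorbed,
transmitted, gate-terminated and roulette-adjusted weight so conservation
can be asserted to 10⁻⁶ relative. Each photon owns a counter-based
splitmix64 RNG stream keyed by (seed, photon index), so results are exactly
reproducible and independent of execution order. A photon deeper than it
could return within the remaining gate time is terminated early; this
pruning is exact for the reflectance observables.

## Transient analysis

The measured (or synthetic) observable is a stack of time-gated images of
the reflectance profile, 0.5–15.5 ps in 1 ps steps by default, on a
5.4×5.4 mm² raster of 0.05 mm pixels, analysed inside a circular field of
view of area 13.2 mm². Each frame is fitted with a rotated bivariate
Gaussian plus a constant background: unweighted pixel residuals inside the
FOV mask, background constrained non-negative, initialised from
baseline-subtracted moments. Principal variances and orientation come from
the fitted covariance. Choices worth noting:

- *Pixel weighting.* Unweighted residuals are the default. Weighting by
  observed counts is statistically biased low at Monte-Carlo photon budgets
  (downward-fluctuating pixels get the largest weights); weighting by the
  model chases the non-Gaussian tails of the pre-asymptotic profile. Both
  alternatives were evaluated on replicated simulations and rejected on
  those statistical grounds; `pixel_weighting="poisson"` remains available
  for genuinely high-count camera data.
- *Global rotation.* One in-plane principal frame is estimated for the
  whole stack as the uncertainty-weighted axial circular mean of the
  late-time frame orientations (canonicalised to the major-axis angle,
  since a per-frame fit may list either principal axis first), then every
  frame is re-fitted with the rotation fixed. Rotationally symmetric frames
  are flagged indeterminate and excluded from the mean.
- *MSD and regression.* The per-axis MSD is the fitted principal variance;
  its uncertainty combines the fit covariance with a 1 % relative
  acquisition-noise floor in quadrature. A weighted linear regression over
  t > 10 ps (configurable) gives D = slope/2 per axis. The parallel axis is
  the one with the larger regressed slope unless a supplied fiber geometry
  forces the assignment. The elevation correction divides the parallel
  in-plane rate by cos α; uncertainties propagate through the correction
  and through the OFA formula to first order.

A caveat the tests quantify: with μ̃′∥ = 2.6 mm⁻¹ the parallel axis has only
≈ 6–9 transport mean free times inside the 10.5–15.5 ps window, so the
regressed slope sits several percent above the asymptotic diffusion
coefficient (the walk is still thermalising); the perpendicular axis, with
≈ 10–15, is essentially converged. Estimates from this window are
window-averaged effective coefficients, not asymptotic ones.

## Two-stage inverse fit

Stage 1 fits the per-axis MSD curves with the Monte Carlo as forward model.
g is handled on a grid (default 0.80–0.99 in 0.01 steps) rather than as a
free optimiser variable, because near g → 1 a small change in g trades off
against a large change in μs — profiling over the grid sidesteps the
degeneracy and directly exposes the χ²(g) curve, whose minimum is carried
by the early-time transient (t ≲ 8 ps) where single-scattering properties
still matter. For each g, the two effective reduced components are found by
matched-slope fixed-point iteration: starting from the isotropic-limit
inversion μ̃′ = v/(3D) of the regressed slopes, each iteration runs one
seeded forward simulation, analyses it with exactly the same chain in the
data's principal frame, and rescales each component by the model/data slope
ratio (the map is nearly diagonal, so 2–4 iterations suffice). χ² sums both
axes over all gate delays with the data and forward-model MSD uncertainties
combined in quadrature. All forward runs share one seed (common random
numbers), which removes independent MC noise from χ² differences across the
grid and makes the optimisation landscape smooth; forward evaluations are
memoized. Uncertainties come from the Δχ² = 1 curvature around the optimum,
inflated by √(χ²/dof) when the residual scale exceeds the stated
uncertainties; they represent the fit geometry under common random numbers
and deliberately exclude the seed-to-seed MC floor (a seed bootstrap would
add it but costs a full refit per replicate).

Stage 2 fixes the stage-1 scattering parameters and retrieves μa from the
spatially integrated time-resolved curve. One μa = 0 forward run gives the
scattering-only shape R₀(t); the model A·R₀(t)·exp(−μa v t) is fitted with
the amplitude solved in closed form at each μa and μa found by bounded
scalar minimisation, making the estimate exactly invariant under rescaling
of the data. Weights combine the data uncertainties with the forward
model's own shot noise scaled by the fitted amplitude (two-pass). Repeating
the fit across the g grid yields an independent χ²(g) cross-check of the
asymmetry factor. The Δχ² = 1 parabola supplies the μa uncertainty.

## Four-layer head model

The head configuration (shipped as `table1_head.json`) stacks scalp/skull
(10 mm), cerebrospinal fluid (2.5 mm), gray matter (3 mm) and white matter
(10 mm); the three outer layers are isotropic with literature properties,
per-layer μs derived as μ′s/(1−g), and the white matter carries the
measured uniaxial tensor (μ̃′ = 2.6 / 4.4 mm⁻¹, g = 0.97) with its fast axis
along lab y or x. A normal-incidence delta pulse illuminates the origin;
reflectance is collected on a 10×10 grid covering a 50 mm quadrant over
nanosecond windows spanning 0.5–4.5 ns. The orientation contrast is the
normalised difference ΔI(x,y) = ⟨(I_y − I_x)/(½(I_y+I_x))⟩ over a window,
formed per time bin and averaged weighted by bin width, hence bounded in
[−2, 2]; cells with no signal in either run are masked (NaN), not
zero-filled. Running both orientations with the same seed makes photons
that never reach the white matter contribute identically, so their noise
cancels exactly in the numerator.

## Synthetic data

Two generators stand in for the experiment, both seeded and both emitting a
ground-truth sidecar so recovery tests never hard-code values:

- *Analytic-Gaussian mode*: frames are rotated bivariate Gaussians with
  per-axis variances σ₀² + 2 D_meas t (parallel axis projected by cos α),
  amplitudes decaying as exp(−μa v t), normalised per frame. This is the
  closed-form surrogate of the diffusive regime; round-trip recovery is
  exact to ≲ 0.1 %, so it isolates chain defects from transport physics.
- *Monte-Carlo mode*: frames rendered from a tensor-MC run (absorption by
  reweighting), carrying genuine transient physics and MC sampling noise.

Camera noise is Poisson shot noise at a configurable budget (the brightest
frame scaled to `photons_per_frame`, default 2×10⁵ counts) plus additive
Gaussian read noise (default σ = 2 counts), clipped at zero. The defaults
were chosen so that recovery uncertainties are commensurate with the
fixture's stated uncertainties. What the generators do **not** emulate:
speckle (assumed averaged out by the acquisition's spatial averaging), gate
upconversion efficiency and the ~150 fs instrument response (an optional
Gaussian gate width is carried as metadata only), laser drift, and
sample heterogeneity. Passing tests therefore validate the estimation chain
under the stated statistical model, not robustness to instrument
systematics.

## Problem sizes and reproducibility

The test suite and the acceptance script use seed-averaged, desk-scale
budgets chosen as the package's own operating points: forward-consistency
runs average five 2×10⁶-photon simulations (single-run estimator noise on a
D component is ≈ 6 %, larger than the uncertainty of the mean being
checked); stage-1 recovery averages two independent stack-plus-fit
replicates (2×10⁶-photon data stacks, 6×10⁵-photon forward evaluations,
coarse g grid {0.90, 0.97}); stage-2 uses a single 4×10⁵-photon curve; the
head-model property checks run 3×10⁵ photons per orientation with common
random numbers, far below the 10¹¹ trajectories of a production contrast
map, which is why they assert structural properties (exact null for
isotropic white matter, antisymmetry, growth of |ΔI| with distance and
delay) rather than contrast magnitudes. Every stochastic quantity is
reproducible from (configuration, seed); CLI runs write a manifest with the
configuration hash and seeds.

## Known limitations

- The interpolation law of the direction-dependent rate between the
  principal axes is not uniquely determined by on-axis calibration; the two
  implemented variants bracket reasonable smooth choices, and the parallel
  diffusion coefficient they produce through the windowed MSD chain runs a
  few percent above the value the fitted tensor would suggest (see the
  thermalisation caveat above).
- Scalar g: no direction-dependent phase function.
- Layered slabs only — no curved or mesh geometries, no polarisation, no
  frequency-domain output; GPU execution is out of scope (the numba kernel
  is single-threaded and processes ~2×10⁷ scattering events per second).
- The Δχ² = 1 uncertainties understate the seed-to-seed MC floor unless a
  seed bootstrap is run.
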