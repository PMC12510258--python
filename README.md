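# anisophot

Anisotropic photon transport in fibrous biological tissue: a tensor-scattering
photon Monte Carlo, a transient-imaging analysis that turns time-gated
reflectance images into a light diffusion tensor and an **Optical Fractional
Anisotropy (OFA)**, a two-stage inverse fit for scattering, asymmetry and
absorption, and a four-layer human-head simulation of the anisotropy contrast
seen by time-domain NIRS.

## Who this is for

Tissue-optics and neurophotonics researchers who need to model or analyse
direction-dependent light diffusion — most prominently in brain white matter,
where myelinated axon bundles make light diffuse faster along the local fiber
orientation than across it. Conventional diffuse-optics pipelines assume
isotropic scattering; this package provides the anisotropic forward model and
the estimation chain needed to quantify the effect.

## The model

Transport is described by a diagonal scattering-coefficient tensor
μ<sub>s</sub> = diag(μ<sub>s,x</sub>, μ<sub>s,y</sub>, μ<sub>s,z</sub>) with a
*scalar* Henyey–Greenstein asymmetry factor g. Because the isotropic
similarity relation breaks down in anisotropic media, the practical retrieved
quantities are the **effective reduced scattering components**

    μ̃′ₛ,ᵢ = μs,i (1 − g),   i ∈ {x, y, z}.

In the diffusive regime the reflectance profile spreads with per-axis mean
square displacement MSD<sub>i</sub>(t) = 2 D<sub>i</sub> t, giving a diagonal
diffusion tensor **D** (mm²/ps). Its normalised eigenvalue spread is the OFA:

    OFA = sqrt(1/2) · sqrt((Dx−Dy)² + (Dy−Dz)² + (Dz−Dx)²) / sqrt(Dx²+Dy²+Dz²)

which is 0 for isotropic diffusion and → 1 for perfectly directional
transport. Fiber bundles tilted out of the sample surface by an elevation
angle α project the parallel rate onto the measured in-plane rate as
D<sub>y,meas</sub> = D<sub>∥</sub> cos α; the analysis undoes this before the
OFA is evaluated under uniaxial symmetry (D<sub>⊥</sub> on two axes).

The Monte Carlo samples exponential free paths at the direction-dependent
rate μs(ŝ) = ‖diag(μs)·ŝ‖₂ (a quadratic-form variant is available), deflects
with the HG phase function, handles refractive-index boundaries with
unpolarised Fresnel coefficients, and applies absorption as continuous
Beer–Lambert weighting — so a μa = 0 run can be reweighted exactly by
exp(−μa v t), which the two-stage inverse fit exploits.

## Worked example

Generate a synthetic acquisition with the white-matter parameters (16 gated
frames, 0.5–15.5 ps, 5.4×5.4 mm² field) and recover the diffusion tensor:

```python
import anisophot as ap
from anisophot.synth import SyntheticSpec, generate_gaussian_stack

spec = SyntheticSpec.analytic(
    d_perp=1.69e-2, d_par=2.47e-2,                      # mm^2/ps
    geometry=ap.FiberGeometry(elevation_alpha=31.0),    # fiber tilt, deg
    photons_per_frame=None)                             # noiseless
stack = generate_gaussian_stack(spec)

model = ap.TransientDiffusionModel(stack,
                                   geometry=ap.FiberGeometry(elevation_alpha=31.0))
results = model.fit()
print(results.summary())
```

which prints

```
Transient diffusion-tensor fit
==============================
frames: 16, window: t > 10 ps, rotation: -90.0 deg
elevation alpha: 31.0 deg

  D_perp = (1.689 +/- 0.052) x 1e-2 mm^2/ps
  D_par  = (2.469 +/- 0.076) x 1e-2 mm^2/ps
  OFA    = 0.227 +/- 0.026
```

The generating tensor (1.69, 2.47)×10⁻² mm²/ps is recovered through the full
chain — per-frame bivariate Gaussian fits inside the circular 13.2 mm² field
of view, a global principal-frame rotation, weighted MSD regression for
t > 10 ps with D = slope/2, and the cos α elevation correction — and the OFA
of 0.227 quantifies the white-matter transport anisotropy (about 23 %).

The same objects drive the inverse problem on simulated data:
`ScatteringInversion` fits the two effective reduced components and g to MSD
curves with the Monte Carlo as forward model (χ² profiled over a g grid), and
`AbsorptionInversion` then retrieves μa from the spatially integrated
time-resolved curve by amplitude-free exponential reweighting of a single
μa = 0 run. `anisophot.head` builds the four-layer scalp/skull–CSF–gray–white
head model and the orientation-contrast map ΔI(x, y) between runs with the
white-matter fast axis along y versus x.

A command-line interface mirrors the stages:

```bash
anisophot synth    --spec spec.json --seed 1 --out stack.tif --truth truth.json
anisophot analyze  --stack stack.tif --meta stack.json --tmin 10 --alpha 31 --out est.json
anisophot fit-msd  --msd msd.csv --seed 7 --out stage1.json
anisophot fit-tdr  --curve tdr.csv --stage1 stage1.json --out stage2.json
anisophot headmodel --axis y --photons 1000000 --seed 3 --out head_y.h5
```

Every run writes a manifest (config hash, seeds, versions) next to its output.

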