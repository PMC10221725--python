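# confocyl

Simulation of reflectance confocal laser scanning microscope (CLSM) images
of multi-cylinder phantoms — the kind of 3D-printed calibration structures
used to validate confocal instruments: parallel dielectric cylinders
(radii 5–10 µm, printing-resin indices 1.5133/1.6285) randomly packed to
~10 % fill in a 200 × 200 µm² slab, imaged in air or immersion oil.

It is aimed at people building or validating confocal image-formation
models: it predicts where the characteristic reflexes of a cylindrical
scatterer appear (surface reflex, central maximum, underside reflexes,
deep multiple-reflection signals), how they move with numerical aperture,
pinhole size and refractive-index contrast, and how much light a cylinder
returns versus passes on to deeper structures.

## What it computes

**Cylinder scattering.** The exact series solution for a plane wave
normally incident on an infinite dielectric cylinder, for both
polarisations: amplitude function `T(θ) = c₀ + 2 Σ c_n cos nθ`, scattering
efficiency `Q_sca = (2/x)(|c₀|² + 2 Σ |c_n|²)` with size parameter
`x = 2π n_s r/λ₀`, and the forward/backward intensity ratio that controls
penetration depth.

**Maxwell confocal image.** The 2D confocal amplitude of a single cylinder
as an aperture-limited double integral over illumination and detection
plane-wave components,

    U(y,z) = ∬_{|ky|,|ky′|≤k·NA} S(ky,ky′) e^{i[z(kz′+kz) + y(ky′−ky)]} dky dky′,

with unpolarised intensity `I = (|U_p|² + |U_s|²)/2`, evaluated by a
midpoint Riemann sum, optionally averaged over the ±0.25 µm print
tolerance of the radius.

**Monte Carlo scan.** A ray-based photon transport through an arbitrary
cylinder phantom: launch from a thin lens sized to the NA
(`d_lens = 4f(NA/n_s)/√(1−(NA/n_s)²)`), analytic ray–cylinder
intersections, stochastic Fresnel reflection/refraction at each surface,
and detection through the thin-lens ABCD mapping
(`tan α₂ = −p₁/f + tan α₁`, `p₂ = p₁ + 2f tan α₂`) onto a pinhole. One
independent, seeded MC run per scan pixel.

**Phantoms and post-processing.** Reproducible rejection-sampled phantom
layouts with JSON round-trip, and the standard evaluation pipeline
(line-wise background subtraction, moving average, normalisation, cubic
upscaling, log view).

## Worked example

How strongly does a 10 µm cylinder reflect, and where do its reflexes lie?

```
$ confocyl scatter --radius 10 --n-cyl 1.6285 --n-surround 1.0
{
 "x": 113.82582078223888,
 "m": 1.6285,
 "Q_parallel": 2.2135895102397507,
 "Q_perp": 2.199391766870511,
 "Q_unpolarised": 2.206490638555131,
 "log10_fb_ratio": 2.634578385338985
}
```

The high-index resin in air scatters with efficiency ≈ 2.2 (more than
twice its geometric cross-section) and returns ~2.6 orders of magnitude
less light backward than forward. Repeating with `--n-surround 1.518
--n-cyl 1.5133` (the low-index resin in oil) gives `log10_fb_ratio ≈ 7.2`:
near-matched cylinders are almost transparent in reflection, which is why
deeper cylinders remain visible at low index contrast.

Axial reflex positions from the Monte Carlo (2D mode, NA 0.6 in air):

```python
import numpy as np
from confocyl import OpticalSystem, single_cylinder_phantom, axial_reflex_positions

optics = OpticalSystem(na=0.6, focal_length=2.0, pinhole_radius=1.68, n_surround=1.0)
phantom = single_cylinder_phantom(radius=10.0, n_cyl=1.6285, n_surround=1.0)
profile = axial_reflex_positions(
    optics, phantom, z_range=(-15, 15), n_positions=61,
    n_photons=50_000, seed=1, mode="2d",
)
for z, prom in profile.peaks:
    print(f"reflex at z = {z:+5.1f} um   (prominence {prom:.2e})")
```

```
reflex at z =  +0.5 um   (prominence 9.41e-02)
reflex at z =  +9.5 um   (prominence 2.67e-02)
```

The two located maxima are the central maximum (z ≈ 0, focus at the
cylinder centre: every ray enters along the surface normal and
retro-reflects off front or back surface) and the surface reflex
(z ≈ +10 µm, focus on the apex), each within one 0.5 µm grid step of its
geometric position. The Maxwell engine
(`confocyl.confocal_image`) puts the same two maxima at the same
positions.

Other entry points: `confocyl make-phantom`, `simulate-scan`,
`axial-profile`, `maxwell-image` and `postprocess` (YAML-driven; float32
TIFF output with JSON axis sidecars).

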