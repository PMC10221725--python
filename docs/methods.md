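# Methods

`confocyl` models image formation in a reflectance confocal laser scanning
microscope (CLSM) for phantoms made of parallel dielectric cylinders, with
two independent engines — an exact Maxwell-series calculation for a single
cylinder and a ray-based Monte Carlo for arbitrary multi-cylinder scenes —
plus the phantom generator and the post-processing pipeline used to
evaluate the scans.

## Physical model and assumptions

**Scene.** Cylinders are infinite along x, specified by centre (y, z),
radius and a real refractive index, embedded in a homogeneous surrounding
medium (air, n = 1.0, or immersion oil, n = 1.518). All media are
non-absorbing and free of volume scattering: the only light–matter
interaction is specular reflection/refraction at cylinder surfaces. The
phantom validates this explicitly (`mu_s = mu_a = 0` is enforced). Standard
configurations follow the printing resins IP-S (n = 1.5133) and IP-n162
(n = 1.6285) at λ₀ = 552 nm, giving index contrasts Δn from 0.6285 (high
resin in air) down to −0.0047 (low resin in oil; usually quoted rounded as
−0.0048).

**Cylinder scattering (`scattering`).** Plane-wave scattering by an
infinite cylinder at normal incidence is solved by the Bessel/Hankel series
with coefficients `b_n` (E ∥ axis, TM) and `a_n` (E ⊥ axis, TE), size
parameter x = 2π n_s r/λ₀ and relative index m = n_cyl/n_s. Truncation at
`ceil(x + 4 x^{1/3} + 2)` orders; the Hankel-function sign convention
(first kind, e^{−iωt}) is pinned by requiring the optical-theorem
extinction `(2/x) Re T(0)` to be positive and equal to Q_sca for these
lossless media — an identity the tests assert to 1e-10. The amplitude
function is the cosine series `T(θ) = c₀ + 2 Σ c_n cos nθ` (θ = 0 forward),
the unpolarised intensity `(|T_par|² + |T_perp|²)/2`, and
`Q_sca = (2/x)(|c₀|² + 2 Σ |c_n|²)` per polarisation (checked against the
independent angular quadrature `(1/(πx))∮|T|²dθ` to 0.1 %). m < 1 (cylinder
optically thinner than the medium) requires no special handling.

**Maxwell confocal image (`maxwell`).** The 2D confocal amplitude of a
single cylinder is a double integral of the scattering amplitude over the
illumination and detection transverse wavenumbers admitted by the aperture
(|ky|, |ky′| ≤ k·NA), with constant pupils and equal excitation/collection
paths:

    U(y,z) = ∬ S(ky,ky′) exp{i[z(kz′ + kz) + y(ky′ − ky)]} dky dky′.

The axial phase sign is a documented switch. With both axial roots positive
the physically consistent reflectance phase is the *sum* kz′ + kz
(illumination travels −z, detection +z); the alternative "difference"
reading makes the on-axis phase vanish and removes axial sectioning
entirely. The default was fixed by the physical criterion that the on-axis
surface reflex of a cylinder of radius R appears at focus depth z = +R,
which the sum convention satisfies and the difference convention cannot.
S is evaluated at the angle between the incident ray (ky, −kz) and the
detected ray (ky′, +kz′): `θ = arccos[(ky ky′ − kz kz′)/k²]`, which is π at
ky = ky′ = 0 (exact backscatter). The two polarisations are propagated as
independent scalar channels and mixed only in the intensity.

Numerics: midpoint Riemann sum with n_k = 256 nodes per axis by default
(midpoints avoid the kz → 0 endpoint); doubling n_k changes the normalised
axial response by < 1 % RMS at the standard configuration. Radius averaging
(default 11 radii over ±0.25 µm, the print tolerance) averages
*intensities*, not amplitudes: the samples represent nominally distinct
physical prints with no mutual phase coherence.

A note on the axial response: at the standard validation configuration
(r = 10 µm, n = 1.6285, air, NA 0.6) the central maximum at z = 0 is about
twice the surface maximum at z = +10 µm, in both engines. Geometric optics
explains this: with the focus at the centre every ray strikes the surface
along its normal, so both the direct front reflection (R) and the
back-surface retro-reflection (T²R ≈ R) return to the pinhole, versus R
alone at the apex. Images are therefore conventionally normalised *to the
surface maximum*, which can leave central values above 1. Absolute scales
are never meaningful; only normalised images are compared.

**Monte Carlo (`mc`).** The confocal optics follow a 4f layout: a thin lens
of focal length f (0.3–2 mm) sits 2f above the current focus, the detection
plane 2f behind the lens. The lens diameter matches the aperture,
`d_lens = 4f(NA/n_s)/√(1−(NA/n_s)²)`, i.e. the rim subtends arcsin(NA/n_s)
from the focus. Photons start uniformly over the lens *area*
(r₀ = r_lens·√ξ; a literal uniform-in-radius mode, density ∝ 1/r, is
selectable for replication studies) and aim exactly at the focal point —
Gaussian-beam launch models are deliberately omitted. Propagation
alternates straight free flight with surface events: ray–cylinder
intersection is solved analytically (quadratic in the y–z plane; hits
closer than 1e-6 µm are ignored as self-intersections, tangent rays with
discriminant < 1e-12 count as misses — both verified against a
surface-marching oracle), and each surface event draws reflect-vs-refract
stochastically with probability equal to the unpolarised Fresnel
reflectance (weight-1 branching, unbiased in expectation; total internal
reflection gives R = 1). The walk is scalar — polarisation enters only
through the Fresnel average. `max_events = 50` caps pathological
internal-reflection loops.

Detection: a photon crossing the lens plane upward inside the aperture
radius is mapped to the detection plane by the thin-lens ABCD step
`tan α₂ = −p₁/f + tan α₁`, `p₂ = p₁ + 2f tan α₂` per axis (coordinates
relative to the optical axis through the focus), and is detected iff it
lands inside the pinhole radius. Any ray emanating from the focal point
maps exactly to the pinhole centre, and a lateral source offset δ maps to
|p₂| = δ (magnification −1) — both asserted in tests. A "2d" mode confines
launch and detection to the y–z plane for comparison with the Maxwell
engine. No vignetting test beyond the aperture-radius check is applied.

Per-pixel random streams are spawned as `SeedSequence((base_seed, iy, iz))`,
so scans are bit-reproducible and independent of pixel evaluation order.
The production path is a vectorised batch engine; a scalar per-photon
implementation of identical physics backs the public `trace`/`launch_photon`
API and is statistically cross-checked against the batch engine.

**Subsurface reflexes.** Beneath a single r = 10 µm cylinder at Δn = 0.1105
(NA 1.4, pinhole 0.72 µm) the axial response shows discrete
refract–reflect–refract reflexes whose depths this package reproduces:
about 4.5 and 8 µm below the centre (ray paths running along the cylinder
axis; a paraxial flat-plate estimate places the latter at
z = R − 2R/m ≈ −8.6 µm), about 2 µm below the lower surface (an in-plane
annulus of rays near 53° that retro-reflects off the underside — verified
against a deterministic 2D ray-fan calculation), and, at reduced aperture
(NA 0.9), a focus-like signal from multiple internal reflections near
20 µm below the centre. In this analytic-geometry model the annular reflex
2 µm below the lower surface is the strongest of the group; the reflex
*positions* are the robust observable and are what the tests assert.

**Phantom generation (`phantom`).** Centres are rejection-sampled uniformly
over the admissible region (cylinder fully inside the 200 × 200 µm² slab),
discarding candidates that overlap accepted cylinders. Placement stops when
the achieved fill reaches the target, or when one more cylinder would
overshoot it by more than 1 % relative — the tolerance absorbs
whole-cylinder discreteness, so a 10 % target yields 12 cylinders at
r = 10 µm (9.42 %) and 51 at r = 5 µm (10.01 %). A cap of 10⁴ consecutive
rejections turns an infeasible target into a warned partial fill rather
than an exception (10 % is far below the ~55 % jamming density, so the cap
never triggers in normal use). `min_margin` defaults to 0 µm — printed
phantoms show near-touching cylinders — and is exposed for ray-tracing
robustness. Sample tilt is modelled as a rotation of the centres about the
slab centre. Two frozen layouts (12 × r10, 51 × r5, fixed seeds) ship with
the package for regenerable figures; they are not the (unpublished)
coordinates of any physical phantom.

**Post-processing (`postprocess`).** The pipeline order is fixed:
line-wise background subtraction (default row 5th percentile — the
estimator used on the measured data is not specified, and a percentile is
robust to sparse bright reflexes) → moving average (odd window, shrinking
at the edges) → normalisation (global max, or a region such as the first
cylinder surface) → display-only cubic upscaling (clipped at 0) and
logarithmic view. The log view accepts an empirical gain factor mirroring
the display compensation used when comparing against attenuated
measurements; it is never part of a quantitative result.

## Parameters that matter

| Parameter | Default | Notes |
|---|---|---|
| λ₀ | 552 nm | laser line; enters series size parameter and k |
| NA | 0.6 (air) / 1.4 (oil) | sets lens radius and ky integration limits |
| f | 2 mm (air) / 0.3 mm (oil) | thin-lens focal length |
| r_pin | 1.68 µm (air) / 0.72 µm (oil) | pinhole radius, object side |
| n_k | 256 | Maxwell quadrature nodes per axis |
| max_events | 50 | MC surface-event cap per photon |
| n_photons | 10⁴–10⁶/pixel | study sizes here; larger is config-reachable |
| fill_tol | 0.01 | relative fill overshoot allowance in the generator |

## Problem sizes used in tests and the acceptance script

Full-scale scans (201 × 201 pixels and up at 10⁷–10⁸ photons/pixel) are
reachable through the config but are not what the test suite runs. The
shipped studies use axial line scans of 41–61 positions at 2×10⁵–10⁶
photons per position and small 2D grids at 10³–10⁴ photons per pixel —
chosen so every reflex position quoted above is recovered reproducibly
across seeds (checked for several) while a complete run stays in the
minutes range on one CPU core.

## What the generator and tests do not show

The synthetic phantoms and the simulation model ideal geometry: no surface
roughness, no support-frame shadowing (a main cause of the effective-NA
reduction seen in measurements), no glass substrate (an optional planar
interface exists but is off by default), no volume heterogeneity of the
resin, no Gaussian beam profile, no diffraction inside the MC, and no
aberrations. Agreement of the two engines here therefore validates the
geometric-optics implementation, not the full instrument response; features
that depend on wave effects (PSF-scale widths, interference fringes,
caustic sharpness) differ systematically between the engines and from
measurements.

## Known limitations

* Normal-incidence scattering only; oblique incidence, absorbing/coated
  cylinders and spheres are out of scope.
* The ABCD detection step is paraxial in form (as specified by the model it
  implements) even though tangents of large angles are inserted at NA 1.4.
* Relative intensities of sharp geometric caustics (the annular underside
  reflex) are model-sensitive: exact analytic geometry makes them stronger
  than mesh-discretised or wave treatments would.
* The pinhole radius is taken verbatim from the configuration; no Airy-unit
  relation is enforced.
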