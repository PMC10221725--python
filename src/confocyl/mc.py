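"""Ray-based Monte Carlo photon transport through a cylinder phantom.

The confocal geometry: a thin lens of focal length ``f`` sits a distance
``2f`` above the current focal point and focuses the illumination to that
single point.  Photons are launched from random positions on the lens disc
toward the focus, propagated along straight rays through the phantom
(volume scattering and absorption are zero; the only events are specular
reflection/refraction at cylinder surfaces, decided stochastically from the
unpolarised Fresnel reflectance), and, if they return to the lens plane
travelling upward within the lens aperture, are mapped to the detection
plane at ``2f`` behind the lens with the thin-lens ABCD formalism.  A photon
is detected when its mapped position falls inside the pinhole radius.

All positions are micrometres; focal lengths are given in millimetres in
:class:`OpticalSystem` and converted internally.  The random walk is
scalar (no polarisation state); the pinhole/aperture test is purely
positional (no vignetting beyond the aperture-radius test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom

__all__ = [
    "OpticalSystem",
    "Photon",
    "DetectionRecord",
    "lens_diameter",
    "launch_photon",
    "intersect_ray_cylinder",
    "fresnel_reflectance",
    "fresnel_interact",
    "trace",
    "simulate_pixel",
]

_EPS_HIT = 1e-6  # um; self-intersection guard
_EPS_DISC = 1e-12  # tangent rays count as misses


def lens_diameter(na: float, focal_length_mm: float, n_surround: float) -> float:
    """Lens diameter (mm) matching a numerical aperture at distance 2f.

    ``d_lens = 4 f (NA/ns) / sqrt(1 - (NA/ns)^2)``: the lens rim then
    subtends the half-angle ``arcsin(NA/ns)`` seen from the focus.
    """
    if not 0 < na < n_surround:
        raise ValueError(f"need 0 < NA < n_surround, got NA={na}, ns={n_surround}")
    s = na / n_surround
    return 4.0 * focal_length_mm * s / np.sqrt(1.0 - s * s)


@dataclass(frozen=True)
class OpticalSystem:
    """Confocal geometry: NA, focal length, pinhole, medium, wavelength."""

    na: float
    focal_length: float  # mm
    pinhole_radius: float  # um
    n_surround: float = 1.0
    wavelength: float = 552.0  # nm, informational for the MC

    def __post_init__(self):
        lens_diameter(self.na, self.focal_length, self.n_surround)  # validates

    @property
    def lens_diameter_mm(self) -> float:
        return lens_diameter(self.na, self.focal_length, self.n_surround)

    @property
    def focal_length_um(self) -> float:
        return self.focal_length * 1e3

    @property
    def lens_radius_um(self) -> float:
        return self.lens_diameter_mm * 1e3 / 2.0


@dataclass
class Photon:
    """MC transport unit: position, unit direction, current medium, events."""

    position: np.ndarray
    direction: np.ndarray
    medium_index: float
    n_events: int = 0
    alive: bool = True


@dataclass
class DetectionRecord:
    """Outcome of tracing one photon through the detection optics."""

    lens_hit: tuple[float, float] | None
    pinhole_pos: tuple[float, float] | None
    detected: bool
    path: list[np.ndarray] | None = None


def launch_photon(
    optics: OpticalSystem,
    focal_point: np.ndarray,
    rng: np.random.Generator,
    sampling: str = "area",
) -> Photon:
    """Launch one photon from the lens disc toward the focal point.

    ``sampling="area"`` (default) draws the start radius as
    ``r_lens * sqrt(xi)`` so positions are uniform over the lens *area*;
    ``sampling="literal"`` uses ``r_lens * xi`` (uniform in radius, density
    ~1/r over the disc), retained for replication studies.
    """
    focal_point = np.asarray(focal_point, dtype=float)
    xi1, xi2 = rng.random(2)
    r_lens = optics.lens_radius_um
    r0 = r_lens * (np.sqrt(xi1) if sampling == "area" else xi1)
    phi0 = 2.0 * np.pi * xi2
    start = focal_point + np.array(
        [r0 * np.cos(phi0), r0 * np.sin(phi0), 2.0 * optics.focal_length_um]
    )
    direction = focal_point - start
    direction /= np.linalg.norm(direction)
    return Photon(
        position=start,
        direction=direction,
        medium_index=optics.n_surround,
    )


def intersect_ray_cylinder(
    position: np.ndarray,
    direction: np.ndarray,
    center_y: float,
    center_z: float,
    radius: float,
) -> tuple[float, np.ndarray] | None:
    """Nearest positive intersection of a ray with an infinite x-cylinder.

    Returns ``(distance, outward_normal)`` or ``None``.  Hits closer than
    1e-6 um are ignored (self-intersection guard); tangent rays
    (discriminant below 1e-12) count as misses.
    """
    dy, dz = direction[1], direction[2]
    py = position[1] - center_y
    pz = position[2] - center_z
    a = dy * dy + dz * dz
    if a < 1e-30:
        return None
    b = 2.0 * (py * dy + pz * dz)
    c = py * py + pz * pz - radius * radius
    disc = b * b - 4.0 * a * c
    if disc < _EPS_DISC:
        return None
    sq = np.sqrt(disc)
    t = (-b - sq) / (2.0 * a)
    if t <= _EPS_HIT:
        t = (-b + sq) / (2.0 * a)
    if t <= _EPS_HIT:
        return None
    hit = position + t * direction
    normal = np.array([0.0, hit[1] - center_y, hit[2] - center_z]) / radius
    return float(t), normal


def fresnel_reflectance(cos_i: float, n1: float, n2: float) -> float:
    """Unpolarised Fresnel reflectance (mean of s and p) for cos_i > 0."""
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def fresnel_interact(
    photon: Photon,
    normal: np.ndarray,
    n1: float,
    n2: float,
    rng: np.random.Generator,
) -> Photon:
    """Specular reflection or refraction at a dielectric interface.

    ``normal`` must be oriented against the incident ray.  The photon
    reflects with probability equal to the unpolarised Fresnel reflectance,
    otherwise refracts by Snell's law and updates its medium index
    (weight-1 stochastic branching; unbiased in expectation).
    """
    d = photon.direction
    cos_i = -float(np.dot(d, normal))
    if cos_i <= 0:
        raise ValueError("normal must be oriented against the incident ray")
    r = fresnel_reflectance(cos_i, n1, n2)
    if rng.random() < r:
        photon.direction = d + 2.0 * cos_i * normal
    else:
        eta = n1 / n2
        cos_t = np.sqrt(1.0 - eta * eta * (1.0 - cos_i * cos_i))
        photon.direction = eta * d + (eta * cos_i - cos_t) * normal
        photon.medium_index = n2
    photon.direction = photon.direction / np.linalg.norm(photon.direction)
    photon.n_events += 1
    return photon


def _nearest_hit(photon: Photon, phantom: Phantom):
    best = None
    for cyl in phantom.cylinders:
        hit = intersect_ray_cylinder(
            photon.position, photon.direction, cyl.center_y, cyl.center_z, cyl.radius
        )
        if hit is not None and (best is None or hit[0] < best[0]):
            best = (hit[0], hit[1], cyl)
    return best


def _detect(
    photon: Photon, optics: OpticalSystem, focal_point: np.ndarray, mode: str
) -> DetectionRecord:
    """Apply the lens-aperture test and the thin-lens ABCD pinhole mapping."""
    f = optics.focal_length_um
    z_lens = focal_point[2] + 2.0 * f
    dz = photon.direction[2]
    t = (z_lens - photon.position[2]) / dz
    p = photon.position + t * photon.direction
    x1 = p[0] - focal_point[0]
    y1 = p[1] - focal_point[1]
    if x1 * x1 + y1 * y1 > optics.lens_radius_um**2:
        return DetectionRecord(None, None, False)
    tan_x1 = photon.direction[0] / dz
    tan_y1 = photon.direction[1] / dz
    x2 = x1 + 2.0 * f * (-x1 / f + tan_x1)
    y2 = y1 + 2.0 * f * (-y1 / f + tan_y1)
    if mode == "2d":
        detected = abs(y2) < optics.pinhole_radius
    else:
        detected = x2 * x2 + y2 * y2 < optics.pinhole_radius**2
    return DetectionRecord((x1, y1), (x2, y2), bool(detected))


def trace(
    photon: Photon,
    phantom: Phantom,
    optics: OpticalSystem,
    focal_point: np.ndarray,
    max_events: int = 50,
    rng: np.random.Generator | None = None,
    record_path: bool = False,
    mode: str = "3d",
) -> DetectionRecord:
    """Propagate one photon to termination and apply the detection test.

    Alternates straight free flight with Fresnel surface events until the
    photon (a) travels upward with no surface in the way — then the lens
    aperture and pinhole tests are applied, (b) leaves the scene downward,
    or (c) exhausts ``max_events``.
    """
    if rng is None:
        rng = np.random.default_rng()
    focal_point = np.asarray(focal_point, dtype=float)
    path = [photon.position.copy()] if record_path else None
    while photon.n_events < max_events:
        hit = _nearest_hit(photon, phantom)
        if hit is None:
            if photon.direction[2] > 0:
                rec = _detect(photon, optics, focal_point, mode)
                rec.path = path
                return rec
            break  # leaves the scene downward/sideways
        t, normal, cyl = hit
        photon.position = photon.position + t * photon.direction
        if record_path:
            path.append(photon.position.copy())
        if float(np.dot(photon.direction, normal)) < 0:  # entering the cylinder
            n1, n2 = photon.medium_index, cyl.n_cyl
            fresnel_interact(photon, normal, n1, n2, rng)
        else:  # leaving: flip the outward normal against the ray
            n1, n2 = photon.medium_index, phantom.n_surround
            fresnel_interact(photon, -normal, n1, n2, rng)
    photon.alive = False
    return DetectionRecord(None, None, False, path)


# --------------------------------------------------------------------------
# Vectorised batch engine — same physics as trace(), run over photon arrays.
# --------------------------------------------------------------------------


def _launch_batch(optics, focal_point, n, rng, mode, sampling):
    f2 = 2.0 * optics.focal_length_um
    r_lens = optics.lens_radius_um
    if mode == "2d":
        y0 = r_lens * (2.0 * rng.random(n) - 1.0)
        x0 = np.zeros(n)
    else:
        xi1 = rng.random(n)
        r0 = r_lens * (np.sqrt(xi1) if sampling == "area" else xi1)
        phi = 2.0 * np.pi * rng.random(n)
        x0 = r0 * np.cos(phi)
        y0 = r0 * np.sin(phi)
    pos = np.empty((n, 3))
    pos[:, 0] = focal_point[0] + x0
    pos[:, 1] = focal_point[1] + y0
    pos[:, 2] = focal_point[2] + f2
    d = focal_point[None, :] - pos
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return pos, d


def _batch_nearest_hit(pos, d, cyls):
    """Nearest positive hit per ray over all cylinders; returns (t, icyl)."""
    n = pos.shape[0]
    t_best = np.full(n, np.inf)
    i_best = np.full(n, -1, dtype=np.int64)
    for i, (cy, cz, r) in enumerate(cyls):
        py = pos[:, 1] - cy
        pz = pos[:, 2] - cz
        a = d[:, 1] ** 2 + d[:, 2] ** 2
        b = 2.0 * (py * d[:, 1] + pz * d[:, 2])
        c = py * py + pz * pz - r * r
        disc = b * b - 4.0 * a * c
        valid = (disc >= _EPS_DISC) & (a > 1e-30)
        sq = np.sqrt(np.where(valid, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / (2.0 * a)
            t2 = (-b + sq) / (2.0 * a)
        t = np.where(t1 > _EPS_HIT, t1, t2)
        ok = valid & (t > _EPS_HIT) & (t < t_best)
        t_best[ok] = t[ok]
        i_best[ok] = i
    return t_best, i_best


def simulate_pixel(
    optics: OpticalSystem,
    phantom: Phantom,
    focal_point,
    n_photons: int,
    seed,
    mode: str = "3d",
    max_events: int = 50,
    sampling: str = "area",
    batch_size: int = 1 << 20,
) -> float:
    """Detected photon fraction for one focal position.

    Launches ``n_photons`` photons (weight 1 each) and returns
    ``n_detected / n_photons``.  In ``mode="2d"`` launch positions and
    directions are confined to the y-z plane and the pinhole test is
    one-dimensional, matching the two-dimensional Maxwell comparison.
    Deterministic for a fixed seed.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    focal_point = np.asarray(focal_point, dtype=float)
    rng = np.random.default_rng(seed)
    cyls = [(c.center_y, c.center_z, c.radius) for c in phantom.cylinders]
    n_idx = np.array([c.n_cyl for c in phantom.cylinders])
    ns = phantom.n_surround
    f = optics.focal_length_um
    r_lens2 = optics.lens_radius_um**2
    r_pin = optics.pinhole_radius
    z_lens_off = 2.0 * f  # lens plane relative to focus

    detected = 0
    remaining = n_photons
    while remaining > 0:
        n = min(remaining, batch_size)
        remaining -= n
        pos, d = _launch_batch(optics, focal_point, n, rng, mode, sampling)
        medium = np.full(n, ns)
        alive = np.ones(n, dtype=bool)
        for _ in range(max_events):
            if not alive.any() or not cyls:
                break
            idx = np.nonzero(alive)[0]
            t, icyl = _batch_nearest_hit(pos[idx], d[idx], cyls)
            miss = icyl < 0
            up = miss & (d[idx, 2] > 0)
            if up.any():
                detected += _batch_detect(
                    pos[idx[up]], d[idx[up]], focal_point, f, z_lens_off,
                    r_lens2, r_pin, mode,
                )
            alive[idx[miss]] = False
            hit = ~miss
            if not hit.any():
                break
            h = idx[hit]
            th = t[hit]
            ic = icyl[hit]
            pos[h] += th[:, None] * d[h]
            centers = np.array([[cyls[i][0], cyls[i][1]] for i in range(len(cyls))])
            radii = np.array([cyls[i][2] for i in range(len(cyls))])
            nrm = np.zeros((h.size, 3))
            nrm[:, 1] = (pos[h, 1] - centers[ic, 0]) / radii[ic]
            nrm[:, 2] = (pos[h, 2] - centers[ic, 1]) / radii[ic]
            cos_d = np.einsum("ij,ij->i", d[h], nrm)
            entering = cos_d < 0
            nrm[~entering] *= -1.0  # orient against the ray
            n1 = medium[h]
            n2 = np.where(entering, n_idx[ic], ns)
            cos_i = -np.einsum("ij,ij->i", d[h], nrm)
            cos_i = np.clip(cos_i, 1e-12, 1.0)
            eta = n1 / n2
            sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
            tir = sin_t2 >= 1.0
            cos_t = np.sqrt(np.where(tir, 0.0, 1.0 - sin_t2))
            rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
            rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
            refl_p = np.where(tir, 1.0, 0.5 * (rs * rs + rp * rp))
            reflect = rng.random(h.size) < refl_p
            dr = d[h]
            d_new = np.where(
                reflect[:, None],
                dr + 2.0 * cos_i[:, None] * nrm,
                eta[:, None] * dr + (eta * cos_i - cos_t)[:, None] * nrm,
            )
            d_new /= np.linalg.norm(d_new, axis=1, keepdims=True)
            d[h] = d_new
            medium[h] = np.where(reflect, n1, n2)
        # photons still alive after max_events are terminated undetected
    return detected / n_photons


def _batch_detect(pos, d, focal_point, f, z_lens_off, r_lens2, r_pin, mode):
    z_lens = focal_point[2] + z_lens_off
    t = (z_lens - pos[:, 2]) / d[:, 2]
    x1 = pos[:, 0] + t * d[:, 0] - focal_point[0]
    y1 = pos[:, 1] + t * d[:, 1] - focal_point[1]
    in_ap = x1 * x1 + y1 * y1 <= r_lens2
    tan_x1 = d[:, 0] / d[:, 2]
    tan_y1 = d[:, 1] / d[:, 2]
    x2 = x1 + 2.0 * f * (-x1 / f + tan_x1)
    y2 = y1 + 2.0 * f * (-y1 / f + tan_y1)
    if mode == "2d":
        det = np.abs(y2) < r_pin
    else:
        det = x2 * x2 + y2 * y2 < r_pin * r_pin
    return int(np.count_nonzero(in_ap & det))
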