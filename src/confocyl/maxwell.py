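"""Confocal image of a single cylinder from the Maxwell scattering series.

The reflectance confocal image amplitude of an infinite cylinder (axis along
x) is computed as a double integral over the transverse wavenumbers of the
illumination (ky) and detection (ky') plane-wave components admitted by the
numerical aperture,

    U(y, z) = int int S(ky, ky') exp{i [z (kz' + kz) + y (ky' - ky)]} dky dky',

with ``kz = sqrt(k^2 - ky^2)`` and ``kz' = sqrt(k^2 - ky'^2)`` both taken as
positive roots, ``k = 2 pi n_s / lambda_0`` and integration limits
``|ky|, |ky'| <= ky_max = k * NA``.  Illumination propagates toward -z and
detected light toward +z, so the axial phase is the *sum* ``kz' + kz`` under
this sign convention; ``axial_phase="difference"`` selects the alternative
``kz' - kz`` reading (which removes axial sectioning and is provided for
comparison only).  The default is fixed by the physical requirement that the
on-axis surface reflex of a cylinder of radius R appears at focus depth
z = +R.

``S(ky, ky')`` is the far-field amplitude of the cylinder at the scattering
angle between the incident direction (ky, -kz) and the detected direction
(ky', +kz'); for exact backscatter (ky = ky' = 0) this angle is pi.  The two
linear polarisations never couple in this two-dimensional geometry: each is
propagated as a scalar field and the unpolarised intensity is the average of
the two squared moduli.  Pupil functions are constant inside the aperture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scattering import CylinderScatteringSolution, amplitude, solve_cylinder

__all__ = [
    "ConfocalField",
    "confocal_amplitude",
    "unpolarised_intensity",
    "confocal_image",
    "radius_averaged_image",
]


@dataclass
class ConfocalField:
    """Complex confocal field of a single cylinder on a (y, z) focus grid."""

    grid_y: np.ndarray
    grid_z: np.ndarray
    U_parallel: np.ndarray  # shape (n_y, n_z)
    U_perp: np.ndarray
    wavenumber: float  # rad/um, in the surrounding medium
    ky_max: float

    @property
    def intensity(self) -> np.ndarray:
        return unpolarised_intensity(self.U_parallel, self.U_perp)


def _scattering_matrix(
    solution: CylinderScatteringSolution,
    ky: np.ndarray,
    kyp: np.ndarray,
    k: float,
    polarisation: str,
    chunk: int = 64,
) -> np.ndarray:
    """S(ky, ky') evaluated at the angle between incident and detected rays."""
    kz = np.sqrt(k**2 - ky**2)
    kzp = np.sqrt(k**2 - kyp**2)
    cos_theta = (np.outer(ky, kyp) - np.outer(kz, kzp)) / k**2
    theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    out = np.empty(theta.shape, dtype=complex)
    for i in range(0, theta.shape[0], chunk):  # chunked: cos(n*theta) is large
        out[i : i + chunk] = amplitude(solution, theta[i : i + chunk], polarisation)
    return out


def confocal_amplitude(
    solution: CylinderScatteringSolution,
    na: float,
    grid_y: np.ndarray,
    grid_z: np.ndarray,
    n_surround: float,
    wavelength_vacuum: float,
    n_k: int = 256,
    axial_phase: str = "sum",
) -> ConfocalField:
    """Evaluate the confocal field on a focus grid by a midpoint Riemann sum.

    Parameters
    ----------
    solution
        Scattering series of the imaged cylinder.
    na
        Numerical aperture; must not exceed ``n_surround``.
    grid_y, grid_z
        Focus coordinates in micrometres, relative to the cylinder axis.
    n_k
        Number of midpoint quadrature nodes per wavenumber axis (>= 16).
    axial_phase
        ``"sum"`` (default, physical reflectance convention) or
        ``"difference"``.

    The midpoint rule avoids the endpoint singularities at |ky| = ky_max
    where kz becomes small.
    """
    if not 0 < na <= n_surround:
        raise ValueError(f"need 0 < NA <= n_surround, got NA={na}, ns={n_surround}")
    if n_k < 16:
        raise ValueError("n_k must be at least 16")
    if axial_phase not in ("sum", "difference"):
        raise ValueError("axial_phase must be 'sum' or 'difference'")
    grid_y = np.asarray(grid_y, dtype=float)
    grid_z = np.asarray(grid_z, dtype=float)
    if not (np.all(np.isfinite(grid_y)) and np.all(np.isfinite(grid_z))):
        raise ValueError("grid must be finite")

    wavelength_um = wavelength_vacuum * 1e-3
    k = 2.0 * np.pi * n_surround / wavelength_um
    ky_max = k * na
    dk = 2.0 * ky_max / n_k
    nodes = -ky_max + dk * (np.arange(n_k) + 0.5)  # midpoint nodes
    kz = np.sqrt(k**2 - nodes**2)
    sign = 1.0 if axial_phase == "sum" else -1.0

    fields = {}
    for pol in ("parallel", "perp"):
        S = _scattering_matrix(solution, nodes, nodes, k, pol) * dk * dk
        U = np.empty((grid_y.size, grid_z.size), dtype=complex)
        # U(y,z) = a(y,z)^T S b(y,z) with a_j = exp{i(-y ky_j + sign*z kz_j)},
        # b_l = exp{i(y ky_l + z kz_l)}; evaluated one z-plane at a time.
        for iz, z in enumerate(grid_z):
            a = np.exp(1j * (np.outer(-grid_y, nodes) + sign * z * kz))  # (n_y, n_k)
            b = np.exp(1j * (np.outer(grid_y, nodes) + z * kz))
            U[:, iz] = np.einsum("yj,jl,yl->y", a, S, b, optimize=True)
        fields[pol] = U

    return ConfocalField(
        grid_y=grid_y,
        grid_z=grid_z,
        U_parallel=fields["parallel"],
        U_perp=fields["perp"],
        wavenumber=k,
        ky_max=ky_max,
    )


def unpolarised_intensity(U_parallel: np.ndarray, U_perp: np.ndarray) -> np.ndarray:
    """Pixelwise unpolarised intensity (|U_p|^2 + |U_s|^2) / 2."""
    U_parallel = np.asarray(U_parallel)
    U_perp = np.asarray(U_perp)
    if U_parallel.shape != U_perp.shape:
        raise ValueError(
            f"field grids differ: {U_parallel.shape} vs {U_perp.shape}"
        )
    return 0.5 * (np.abs(U_parallel) ** 2 + np.abs(U_perp) ** 2)


def confocal_image(
    radius: float,
    wavelength_vacuum: float,
    n_cyl: float,
    n_surround: float,
    na: float,
    grid_y: np.ndarray,
    grid_z: np.ndarray,
    n_k: int = 256,
    axial_phase: str = "sum",
) -> np.ndarray:
    """Unpolarised confocal intensity image of a single cylinder."""
    sol = solve_cylinder(radius, wavelength_vacuum, n_cyl, n_surround)
    fld = confocal_amplitude(
        sol, na, grid_y, grid_z, n_surround, wavelength_vacuum, n_k, axial_phase
    )
    return fld.intensity


def radius_averaged_image(
    base_radius: float,
    half_range: float,
    n_samples: int,
    wavelength_vacuum: float,
    n_cyl: float,
    n_surround: float,
    na: float,
    grid_y: np.ndarray,
    grid_z: np.ndarray,
    n_k: int = 256,
    axial_phase: str = "sum",
) -> np.ndarray:
    """Mean intensity image over evenly spaced radii in ``base +- half_range``.

    Averaging is incoherent (after squaring): the samples stand for nominally
    distinct physical cylinders within the fabrication tolerance, so their
    fields carry no mutual phase relation.  Damps the radius-sensitive
    interference fringes while leaving the surface and central maxima.
    """
    if n_samples < 1 or n_samples % 2 == 0:
        raise ValueError("n_samples must be odd and >= 1")
    if n_samples == 1:
        radii = np.array([base_radius])
    else:
        radii = np.linspace(
            base_radius - half_range, base_radius + half_range, n_samples
        )
    images = [
        confocal_image(
            r, wavelength_vacuum, n_cyl, n_surround, na, grid_y, grid_z, n_k,
            axial_phase,
        )
        for r in radii
    ]
    return np.mean(images, axis=0)
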