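"""Plane-wave scattering by an infinite dielectric cylinder at normal incidence.

The series solution (Bessel/Hankel expansion) for a non-absorbing circular
cylinder illuminated perpendicular to its axis, for both linear polarisations:

* ``parallel`` — electric field parallel to the cylinder axis (TM),
  coefficients ``b_n``;
* ``perp`` — electric field perpendicular to the axis (TE),
  coefficients ``a_n``.

The far-field amplitude function is the cosine series

    T(theta) = c_0 + 2 * sum_{n>=1} c_n cos(n*theta),

with ``theta = 0`` the forward direction and ``theta = pi`` exact
backscatter.  The unpolarised intensity is ``(|T_par|^2 + |T_perp|^2)/2``.
Time convention ``exp(-i omega t)``; Hankel functions of the first kind.

All media are non-absorbing (real refractive indices), so the scattering
efficiency equals the extinction efficiency and

    Q_sca = (2/x) * (|c_0|^2 + 2 * sum_{n>=1} |c_n|^2)

per polarisation, with size parameter ``x = 2 pi n_s r / lambda_0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import h1vp, hankel1, jv, jvp

__all__ = [
    "CylinderScatteringSolution",
    "solve_cylinder",
    "amplitude",
    "unpolarised_intensity",
    "scattering_efficiency",
    "forward_backward_orders",
    "truncation_order",
]

_POLARISATIONS = ("parallel", "perp")


def truncation_order(x: float) -> int:
    """Series truncation order for size parameter ``x`` (Wiscombe-style)."""
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


@dataclass(frozen=True)
class CylinderScatteringSolution:
    """Series coefficients for one (size parameter, relative index) pair.

    ``coeff_parallel`` holds ``b_n`` (E parallel to the axis) and
    ``coeff_perp`` holds ``a_n`` (E perpendicular), n = 0..max_order.
    """

    size_param: float
    rel_index: float
    max_order: int
    coeff_parallel: np.ndarray = field(repr=False)
    coeff_perp: np.ndarray = field(repr=False)

    def coefficients(self, polarisation: str) -> np.ndarray:
        if polarisation == "parallel":
            return self.coeff_parallel
        if polarisation == "perp":
            return self.coeff_perp
        raise ValueError(
            f"polarisation must be one of {_POLARISATIONS}, got {polarisation!r}"
        )


def solve_cylinder(
    radius: float,
    wavelength_vacuum: float,
    n_cyl: float,
    n_surround: float,
    max_order: int | None = None,
) -> CylinderScatteringSolution:
    """Solve normal-incidence scattering by an infinite dielectric cylinder.

    Parameters
    ----------
    radius
        Cylinder radius in micrometres.
    wavelength_vacuum
        Vacuum wavelength in nanometres.
    n_cyl, n_surround
        Real refractive indices of the cylinder and the surrounding medium.
    max_order
        Series truncation order; chosen automatically from the size
        parameter when not given.

    Notes
    -----
    The size parameter uses the wavelength in the *surrounding* medium:
    ``x = 2 pi n_surround radius / lambda_0``.  Complex (absorbing) indices
    are rejected: the media modelled here are lossless.
    """
    for name, val in (
        ("radius", radius),
        ("wavelength_vacuum", wavelength_vacuum),
        ("n_cyl", n_cyl),
        ("n_surround", n_surround),
    ):
        if isinstance(val, complex):
            raise ValueError(f"{name} must be real (non-absorbing media only)")
        if not val > 0:
            raise ValueError(f"{name} must be positive, got {val}")

    wavelength_um = wavelength_vacuum * 1e-3
    x = 2.0 * np.pi * n_surround * radius / wavelength_um
    m = n_cyl / n_surround
    if max_order is None:
        max_order = truncation_order(x)

    n = np.arange(max_order + 1)
    mx = m * x
    jn_x = jv(n, x)
    jnp_x = jvp(n, x)
    jn_mx = jv(n, mx)
    jnp_mx = jvp(n, mx)
    hn_x = hankel1(n, x)
    hnp_x = h1vp(n, x)

    # TM (E parallel to axis): continuity of E_z and H_phi at the surface.
    b_n = (jn_mx * jnp_x - m * jnp_mx * jn_x) / (jn_mx * hnp_x - m * jnp_mx * hn_x)
    # TE (E perpendicular): continuity of H_z and E_phi.
    a_n = (m * jn_mx * jnp_x - jnp_mx * jn_x) / (m * jn_mx * hnp_x - jnp_mx * hn_x)

    return CylinderScatteringSolution(
        size_param=float(x),
        rel_index=float(m),
        max_order=int(max_order),
        coeff_parallel=np.asarray(b_n, dtype=complex),
        coeff_perp=np.asarray(a_n, dtype=complex),
    )


def amplitude(
    solution: CylinderScatteringSolution,
    theta: float | np.ndarray,
    polarisation: str,
) -> complex | np.ndarray:
    """Far-field amplitude function T(theta) for one polarisation.

    ``theta`` is the scattering angle in radians (0 = forward, pi = exact
    backscatter); T is even in theta.
    """
    c = solution.coefficients(polarisation)
    theta = np.asarray(theta, dtype=float)
    n = np.arange(1, solution.max_order + 1)
    # T(theta) = c0 + 2 sum_n c_n cos(n theta); broadcast over theta.
    series = c[0] + 2.0 * np.tensordot(
        np.cos(np.multiply.outer(theta, n)), c[1:], axes=([-1], [0])
    )
    if series.ndim == 0:
        return complex(series)
    return series


def unpolarised_intensity(
    solution: CylinderScatteringSolution, theta: float | np.ndarray
) -> float | np.ndarray:
    """Unpolarised scattered intensity (|T_par|^2 + |T_perp|^2)/2."""
    t_par = amplitude(solution, theta, "parallel")
    t_perp = amplitude(solution, theta, "perp")
    out = 0.5 * (np.abs(t_par) ** 2 + np.abs(t_perp) ** 2)
    if np.ndim(out) == 0:
        return float(out)
    return out


def scattering_efficiency(
    solution: CylinderScatteringSolution, polarisation: str = "unpolarised"
) -> float:
    """Scattering efficiency Q_sca per unit length of the cylinder.

    ``Q = (2/x) (|c_0|^2 + 2 sum |c_n|^2)`` for a single polarisation;
    ``unpolarised`` averages the two.
    """
    if polarisation == "unpolarised":
        return 0.5 * (
            scattering_efficiency(solution, "parallel")
            + scattering_efficiency(solution, "perp")
        )
    c = solution.coefficients(polarisation)
    return float(
        (2.0 / solution.size_param)
        * (np.abs(c[0]) ** 2 + 2.0 * np.sum(np.abs(c[1:]) ** 2))
    )


def forward_backward_orders(
    radius: float,
    wavelength_vacuum: float,
    n_cyl: float,
    n_surround: float,
) -> float:
    """log10 of the unpolarised forward-to-backward scattered intensity ratio.

    Forward is theta = 0, backward theta = pi.  The ratio controls how much
    light a cylinder returns toward a reflectance detector versus passing on
    to deeper structures; it is undefined without index contrast.
    """
    if n_cyl == n_surround:
        raise ValueError("forward/backward ratio undefined for n_cyl == n_surround")
    sol = solve_cylinder(radius, wavelength_vacuum, n_cyl, n_surround)
    i_fwd = unpolarised_intensity(sol, 0.0)
    i_back = unpolarised_intensity(sol, np.pi)
    return float(np.log10(i_fwd / i_back))
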