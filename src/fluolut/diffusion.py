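"""Steady-state diffusion-theory dipole model of spatially resolved
reflectance (Farrell model).

Serves as a deterministic closed-form cross-check for the Monte-Carlo
engine in the diffusive regime (mu_s' >> mu_a, r beyond a transport
length or two) and as a fast generator of realistic radial profiles for
fixtures.  An isotropic point source is placed one transport mean free
path z0 = 1/mu_t' below the surface, with a negative image source
mirrored about the extrapolated boundary at z = -2*zb, where
zb = 2*A*D, D = 1/(3*mu_t'), and A encodes the internal reflection at
the refractive-index mismatch (Groenhuis polynomial approximation).
"""

from __future__ import annotations

import numpy as np

from .media import OpticalMedium


def internal_reflection_parameter(n: float) -> float:
    """Boundary mismatch parameter A = (1 + r_id) / (1 - r_id), with the
    internal diffuse reflectance r_id from the Groenhuis polynomial fit
    in the relative refractive index."""
    r_id = -1.440 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_id) / (1.0 - r_id)


def farrell_reflectance(medium: OpticalMedium, r) -> np.ndarray:
    """Diffuse reflectance per unit area R(r) (mm^-2) at radius r (mm)
    from a pencil source on a semi-infinite medium.

    Raises on non-positive radii (the dipole solution is singular at the
    source axis).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("farrell_reflectance requires r > 0")
    mu_t_prime = medium.mu_t_prime
    mu_eff = medium.mu_eff
    z0 = 1.0 / mu_t_prime
    D = 1.0 / (3.0 * mu_t_prime)
    zb = 2.0 * internal_reflection_parameter(medium.n) * D
    a_prime = medium.mu_s_prime / mu_t_prime
    r1 = np.hypot(z0, r)
    r2 = np.hypot(z0 + 2.0 * zb, r)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
    term2 = (
        (z0 + 2.0 * zb)
        * (mu_eff + 1.0 / r2)
        * np.exp(-mu_eff * r2)
        / r2**2
    )
    out = (a_prime / (4.0 * np.pi)) * (term1 + term2)
    return out if out.shape else float(out)


def farrell_profile(
    medium: OpticalMedium, r_max: float = 10.0, n_bins: int = 400
):
    """Farrell model sampled at the bin centers of the standard Monte-
    Carlo radial grid; returns (r_centers, values)."""
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, farrell_reflectance(medium, centers)
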