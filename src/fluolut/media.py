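"""Optical medium description for turbid, tissue-like samples.

All lengths are millimetres and all attenuation coefficients mm^-1
internally.  Literature values are commonly quoted in cm^-1; use
:func:`per_cm` (or the ``*_per_cm`` constructor arguments of the CLI) to
convert explicitly -- nothing in the package guesses units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


def per_cm(value_cm: float) -> float:
    """Convert an attenuation coefficient from cm^-1 to mm^-1."""
    return 0.1 * value_cm


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous turbid medium at a single wavelength.

    Parameters
    ----------
    mu_a:
        Absorption coefficient (mm^-1), > 0.
    mu_s_prime:
        Reduced scattering coefficient mu_s * (1 - g) (mm^-1), > 0.
    n:
        Refractive index relative to vacuum, >= 1.  The surrounding
        half-space is assumed to be air (n = 1).
    g:
        Scattering anisotropy (mean cosine of the single-scattering
        deflection).  The default 0 uses isotropic scattering with
        mu_s = mu_s_prime, which by the similarity relation leaves the
        diffuse observables beyond ~1 transport length unchanged.
    depth:
        Slab thickness in mm; ``math.inf`` means semi-infinite.  A finite
        bottom boundary absorbs all incident photon weight (black
        backing, as in a dark well).
    """

    mu_a: float
    mu_s_prime: float
    n: float = 1.37
    g: float = 0.0
    depth: float = math.inf

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_a) and self.mu_a > 0):
            raise ValueError(f"mu_a must be finite and > 0, got {self.mu_a}")
        if not (math.isfinite(self.mu_s_prime) and self.mu_s_prime > 0):
            raise ValueError(
                f"mu_s_prime must be finite and > 0, got {self.mu_s_prime}"
            )
        if not (math.isfinite(self.n) and self.n >= 1.0):
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")
        if not self.depth > 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s_prime / (1 - g) (mm^-1)."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def mu_t_prime(self) -> float:
        """Transport coefficient mu_a + mu_s_prime (mm^-1)."""
        return self.mu_a + self.mu_s_prime

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(3 mu_a mu_t') (mm^-1)."""
        return math.sqrt(3.0 * self.mu_a * self.mu_t_prime)

    @property
    def semi_infinite(self) -> bool:
        return math.isinf(self.depth)

    def with_depth(self, depth: float) -> "OpticalMedium":
        return replace(self, depth=depth)

    def specular_reflectance(self) -> float:
        """Fresnel specular reflectance at normal incidence from air."""
        return ((self.n - 1.0) / (self.n + 1.0)) ** 2
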