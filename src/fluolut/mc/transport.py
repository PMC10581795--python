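"""Monte-Carlo transport of excitation and fluorescence photons.

The public entry points are :func:`simulate_impulse`, which traces a
pencil-beam (impulse) response through a turbid slab, and
:func:`simulate_fluorescence_impulse`, which turns the absorbed-weight
map of an excitation run into an isotropic volume source at the emission
wavelength and traces the escaping fluorescence.  Disk or Gaussian beams
are obtained downstream by convolving the impulse response with the beam
irradiance profile (module :mod:`fluolut.reflectometry`); linearity of
transport guarantees equivalence with simulating the extended beam
directly.

The fluorescence model is perturbative: the fluorophore adds an
absorption contribution ``mu_a_fluo`` that is assumed small compared to
the background absorption, so the escaping fluorescence is exactly
linear in ``mu_a_fluo`` and in the quantum yield (re-absorption of
emitted light by the fluorophore itself is neglected).  This matches the
linear relation between corrected fluorescence intensity and fluorophore
concentration assumed by the look-up-table correction, which explicitly
excludes quenching.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from ..media import OpticalMedium
from . import kernels


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical parameters of a Monte-Carlo run.

    ``r_max``/``n_r_bins`` set the surface histogram (default 10 mm in
    400 bins, i.e. 25 um pitch, resolving the 1.1-2.1 mm slope-fit window
    with 40 points).  ``z_max``/``n_z_bins`` set the absorbed-weight
    record grid; absorption deeper than ``z_max`` is tallied but not
    resolved (and therefore not available as a fluorescence source).
    ``n_photons_emission`` defaults to ``n_photons`` when None.
    """

    n_photons: int = 200_000
    seed: int = 0
    r_max: float = 10.0
    n_r_bins: int = 400
    z_max: float = 20.0
    n_z_bins: int = 200
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    n_photons_emission: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.n_r_bins < 1 or self.n_z_bins < 1:
            raise ValueError("bin counts must be >= 1")
        if not (self.r_max > 0 and self.z_max > 0):
            raise ValueError("r_max and z_max must be > 0")
        if not (0 < self.roulette_survival <= 1):
            raise ValueError("roulette_survival must lie in (0, 1]")
        if self.n_photons < 100:
            warnings.warn(
                "n_photons < 100: Monte-Carlo statistics will be unreliable",
                stacklevel=3,
            )

    @property
    def emission_photons(self) -> int:
        return (
            self.n_photons
            if self.n_photons_emission is None
            else self.n_photons_emission
        )


@dataclass
class ImpulseResponse:
    """Binned pencil-beam response of a turbid slab.

    ``R_r`` is diffuse reflectance per unit area (mm^-2) in each annulus,
    as a fraction of the energy entering the medium; ``R_T_impulse`` the
    total diffusely reflected fraction (including radii beyond ``r_max``);
    ``A_rz`` the absorbed-weight density (mm^-3) on the (z, r) grid.
    ``absorbed_total``/``transmitted_total`` complete the energy budget:
    R_T_impulse + absorbed_total + transmitted_total = 1 up to roulette
    variance.
    """

    r_edges: np.ndarray
    R_r: np.ndarray
    R_T_impulse: float
    A_rz: np.ndarray
    z_edges: np.ndarray
    absorbed_total: float
    absorbed_outside_grid: float
    transmitted_total: float
    n_photons: int
    seed: int
    medium: OpticalMedium
    raw_refl_r: np.ndarray = field(repr=False, default=None)
    raw_a_rz: np.ndarray = field(repr=False, default=None)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def mc_standard_error(self) -> float:
        """Binomial standard error of the total-reflectance estimate."""
        p = min(max(self.R_T_impulse, 1e-12), 1.0 - 1e-12)
        return math.sqrt(p * (1.0 - p) / self.n_photons)


@dataclass
class RadialProfile:
    """A radially binned surface profile (values per unit area)."""

    r_centers: np.ndarray
    values: np.ndarray
    normalization_radius: float = math.nan

    def __post_init__(self) -> None:
        r = np.asarray(self.r_centers, dtype=float)
        if r.ndim != 1 or np.any(np.diff(r) <= 0):
            raise ValueError("r_centers must be strictly increasing 1-D")
        self.r_centers = r
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != r.shape:
            raise ValueError("values and r_centers must have equal length")


def _annulus_areas(r_edges: np.ndarray) -> np.ndarray:
    return np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)


def _validate_medium(medium: OpticalMedium) -> None:
    if not isinstance(medium, OpticalMedium):
        raise TypeError("medium must be an OpticalMedium")


def simulate_impulse(
    medium: OpticalMedium, cfg: SimulationConfig
) -> ImpulseResponse:
    """Trace a pencil beam at normal incidence into the medium.

    The specular Fresnel reflection at entry, ((n-1)/(n+1))^2, is removed
    before the photons enter (crossed polarizers suppress it in the
    measurement this emulates); all returned quantities are therefore
    fractions of the energy *entering* the medium, and diffuse
    reflectance excludes the specular component.
    """
    _validate_medium(medium)
    refl_r, a_rz, tallies = kernels.trace_pencil(
        cfg.n_photons,
        cfg.seed,
        medium.mu_a,
        medium.mu_s,
        medium.g,
        medium.n,
        medium.depth,
        cfg.r_max,
        cfg.n_r_bins,
        cfg.z_max,
        cfg.n_z_bins,
        cfg.roulette_threshold,
        cfg.roulette_survival,
    )
    r_edges = np.linspace(0.0, cfg.r_max, cfg.n_r_bins + 1)
    z_edges = np.linspace(0.0, cfg.z_max, cfg.n_z_bins + 1)
    areas = _annulus_areas(r_edges)
    dz = cfg.z_max / cfg.n_z_bins
    cell_vol = areas[None, :] * dz
    n = float(cfg.n_photons)
    return ImpulseResponse(
        r_edges=r_edges,
        R_r=refl_r / (areas * n),
        R_T_impulse=float(tallies[kernels.T_REFL] / n),
        A_rz=a_rz / (cell_vol * n),
        z_edges=z_edges,
        absorbed_total=float(tallies[kernels.T_ABS] / n),
        absorbed_outside_grid=float(tallies[kernels.T_ABS_OUT] / n),
        transmitted_total=float(tallies[kernels.T_TRANS] / n),
        n_photons=cfg.n_photons,
        seed=cfg.seed,
        medium=medium,
        raw_refl_r=refl_r,
        raw_a_rz=a_rz,
    )


def simulate_fluorescence_impulse(
    medium_ex: OpticalMedium,
    medium_em: OpticalMedium,
    mu_a_fluo: float,
    quantum_yield: float,
    cfg: SimulationConfig,
    excitation: Optional[ImpulseResponse] = None,
) -> RadialProfile:
    """Fluorescence escape profile for a pencil excitation beam.

    Two-stage scheme: (1) the absorbed-weight map of an excitation run at
    ``medium_ex`` defines isotropic emission sources of total strength
    ``quantum_yield * (mu_a_fluo / mu_a_ex) * absorbed_weight``; (2) the
    emitted photons propagate at ``medium_em`` and their surface escape
    is binned radially.  Pass a precomputed ``excitation`` response (from
    :func:`simulate_impulse` with ``medium_ex`` and ``cfg``) to reuse it.

    Returns escaping fluorescence per unit area per unit launched
    excitation energy.
    """
    _validate_medium(medium_ex)
    _validate_medium(medium_em)
    if not 0.0 <= quantum_yield <= 1.0:
        raise ValueError("quantum_yield must lie in [0, 1]")
    if mu_a_fluo < 0.0:
        raise ValueError("mu_a_fluo must be >= 0")
    r_edges = np.linspace(0.0, cfg.r_max, cfg.n_r_bins + 1)
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    if mu_a_fluo == 0.0:
        return RadialProfile(r_centers, np.zeros(cfg.n_r_bins))
    if excitation is None:
        excitation = simulate_impulse(medium_ex, cfg)
    raw = excitation.raw_a_rz
    total_weight = float(raw.sum())
    if total_weight <= 0.0:
        return RadialProfile(r_centers, np.zeros(cfg.n_r_bins))
    cdf = np.cumsum(raw.ravel())
    cdf /= cdf[-1]
    n_em = cfg.emission_photons
    refl_r, _, tallies = kernels.trace_volume_source(
        n_em,
        cfg.seed + 0x5EED,
        cdf,
        cfg.n_r_bins,
        cfg.r_max / cfg.n_r_bins,
        cfg.z_max / cfg.n_z_bins,
        medium_em.mu_a,
        medium_em.mu_s,
        medium_em.g,
        medium_em.n,
        medium_em.depth,
        cfg.r_max,
        cfg.n_r_bins,
        cfg.z_max,
        cfg.n_z_bins,
        cfg.roulette_threshold,
        cfg.roulette_survival,
    )
    # source energy per unit launched excitation energy
    source = (
        quantum_yield
        * (mu_a_fluo / medium_ex.mu_a)
        * (total_weight / excitation.n_photons)
    )
    areas = _annulus_areas(r_edges)
    values = refl_r * (source / (areas * n_em))
    return RadialProfile(r_centers, values)


def save_impulse(path, imp: ImpulseResponse) -> None:
    """Serialize an impulse response to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("r_edges", data=imp.r_edges)
        f.create_dataset("R_r", data=imp.R_r)
        f.create_dataset("A_rz", data=imp.A_rz)
        f.create_dataset("z_edges", data=imp.z_edges)
        f.attrs.update(
            {
                "R_T_impulse": imp.R_T_impulse,
                "absorbed_total": imp.absorbed_total,
                "absorbed_outside_grid": imp.absorbed_outside_grid,
                "transmitted_total": imp.transmitted_total,
                "n_photons": imp.n_photons,
                "seed": imp.seed,
                "mu_a": imp.medium.mu_a,
                "mu_s_prime": imp.medium.mu_s_prime,
                "n": imp.medium.n,
                "g": imp.medium.g,
                "depth": imp.medium.depth,
            }
        )


def load_impulse(path) -> ImpulseResponse:
    with h5py.File(path, "r") as f:
        a = f.attrs
        medium = OpticalMedium(
            mu_a=float(a["mu_a"]),
            mu_s_prime=float(a["mu_s_prime"]),
            n=float(a["n"]),
            g=float(a["g"]),
            depth=float(a["depth"]),
        )
        return ImpulseResponse(
            r_edges=f["r_edges"][:],
            R_r=f["R_r"][:],
            R_T_impulse=float(a["R_T_impulse"]),
            A_rz=f["A_rz"][:],
            z_edges=f["z_edges"][:],
            absorbed_total=float(a["absorbed_total"]),
            absorbed_outside_grid=float(a["absorbed_outside_grid"]),
            transmitted_total=float(a["transmitted_total"]),
            n_photons=int(a["n_photons"]),
            seed=int(a["seed"]),
            medium=medium,
        )
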