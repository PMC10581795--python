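"""Disk-illumination observables synthesized from impulse responses.

The measurement this emulates projects two disks on the sample: a large
one (4.16 mm) whose image yields the total diffuse reflectance R_T and
the fluorescence intensity F (both as the mean over a central 1.40 mm
area, normalized to a reflectance standard), and a small one (0.70 mm)
whose image yields the spatially resolved reflectance SRR, summarized by
the slope of log10(SRR) between 1.1 and 2.1 mm from the beam center.

Extended beams are synthesized by convolving the radially symmetric
pencil-beam impulse response with the beam irradiance profile (2D FFT on
a 25 um Cartesian grid); linearity of photon transport makes this exact
up to discretization.  Because beam and impulse are both radially
symmetric the radial profile of the result is read off along the grid
axes, avoiding angular-binning noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .mc.transport import ImpulseResponse, RadialProfile

#: default grid pitch for beam synthesis (mm)
DEFAULT_PITCH = 0.025
#: diffuse reflectance of the reference standard (Spectralon-like)
REFERENCE_REFLECTANCE = 0.99


class CoverageError(ValueError):
    """The impulse response does not extend far enough in radius for the
    requested beam synthesis or analysis."""


@dataclass(frozen=True)
class BeamSpec:
    """Illumination disk projected on the sample.

    ``diameter`` is the flat-top diameter, or the 1/e^2 intensity
    diameter for a Gaussian profile.  Defaults match the two projected
    disks of the measurement (large 4.16 mm, small 0.70 mm).
    """

    diameter: float
    profile: str = "flat-top"
    center: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("beam diameter must be > 0")
        if self.profile not in ("flat-top", "gaussian"):
            raise ValueError("profile must be 'flat-top' or 'gaussian'")

    @property
    def support_radius(self) -> float:
        """Radius beyond which the irradiance is (treated as) zero."""
        if self.profile == "flat-top":
            return 0.5 * self.diameter
        return self.diameter  # truncate the Gaussian at 2x its 1/e^2 radius

    def peak_irradiance(self, pitch: float = DEFAULT_PITCH) -> float:
        """Central irradiance (mm^-2) of the unit-energy beam kernel."""
        k = _beam_kernel(self, pitch)
        c = k.shape[0] // 2
        return float(k[c, c])


LARGE_DISK = BeamSpec(diameter=4.16)
SMALL_DISK = BeamSpec(diameter=0.70)


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of log10(SRR) vs radius over a fixed window."""

    slope: float  # mm^-1, slope of log10 SRR
    intercept: float
    r_squared: float
    fit_range: Tuple[float, float] = (1.1, 2.1)


@dataclass(frozen=True)
class ReflectometryTriplet:
    """The per-sample measurement vector feeding the correction LUT."""

    R_T: float
    slope_log_srr: float
    F: float


@dataclass
class SurfaceMap:
    """Square surface distribution on a Cartesian grid.

    ``pixels[iy, ix]`` holds intensity per unit area at
    ``(x, y) = ((ix - c) * pitch, (iy - c) * pitch)`` with ``c`` the
    central index (odd side length).  ``valid_radius`` bounds the region
    where the synthesis is free of truncation.
    """

    pixels: np.ndarray
    pitch: float
    valid_radius: float

    @property
    def center_index(self) -> int:
        return self.pixels.shape[0] // 2

    def radii(self) -> np.ndarray:
        n = self.pixels.shape[0]
        c = self.center_index
        ax = (np.arange(n) - c) * self.pitch
        return np.hypot(ax[None, :], ax[:, None])

    def radial_profile(self) -> RadialProfile:
        """Radial profile by exact symmetry: average of the four half-axis
        cuts through the center, sampled at multiples of the pitch."""
        c = self.center_index
        p = self.pixels
        n_half = c
        cuts = np.stack(
            [
                p[c, c + 1 : c + 1 + n_half],
                p[c, c - n_half : c][::-1],
                p[c + 1 : c + 1 + n_half, c],
                p[c - n_half : c, c][::-1],
            ]
        )
        values = cuts.mean(axis=0)
        r = self.pitch * np.arange(1, n_half + 1)
        keep = r <= self.valid_radius
        return RadialProfile(r[keep], values[keep])


def _beam_kernel(beam: BeamSpec, pitch: float) -> np.ndarray:
    """Unit-total-energy irradiance kernel on the synthesis grid."""
    rad = beam.support_radius
    n_half = max(0, int(math.ceil(rad / pitch)))
    ax = (np.arange(-n_half, n_half + 1)) * pitch
    rr = np.hypot(ax[None, :], ax[:, None])
    if beam.profile == "flat-top":
        k = (rr <= rad).astype(float)
    else:
        w = 0.5 * beam.diameter  # 1/e^2 radius
        k = np.exp(-2.0 * (rr / w) ** 2)
        k[rr > rad] = 0.0
    total = k.sum() * pitch * pitch
    return k / total


def _impulse_grid(
    r_centers: np.ndarray,
    values: np.ndarray,
    r_max: float,
    half_extent: float,
    pitch: float,
) -> np.ndarray:
    n_half = int(math.ceil(half_extent / pitch))
    ax = (np.arange(-n_half, n_half + 1)) * pitch
    rr = np.hypot(ax[None, :], ax[:, None])
    grid = np.interp(rr, r_centers, values, left=values[0], right=0.0)
    grid[rr > r_max] = 0.0
    return grid


def convolve_beam(
    impulse: Union[ImpulseResponse, RadialProfile],
    beam: BeamSpec,
    pitch: float = DEFAULT_PITCH,
    analysis_radius: float = 6.0,
) -> SurfaceMap:
    """Surface distribution under an extended beam of unit total energy.

    ``analysis_radius`` is the radius out to which the result must be
    valid; the impulse response must cover at least ``analysis_radius +
    beam.support_radius`` or a :class:`CoverageError` is raised (no
    silent truncation).
    """
    if isinstance(impulse, ImpulseResponse):
        r_centers = impulse.r_centers
        values = impulse.R_r
        r_max = impulse.r_edges[-1]
    else:
        r_centers = impulse.r_centers
        values = impulse.values
        r_max = r_centers[-1]
    needed = analysis_radius + beam.support_radius
    if r_max < needed - 1e-9:
        raise CoverageError(
            f"impulse response extends to r_max={r_max:g} mm but "
            f"analysis radius {analysis_radius:g} mm with beam support "
            f"{beam.support_radius:g} mm requires {needed:g} mm"
        )
    half_extent = analysis_radius + beam.support_radius
    grid = _impulse_grid(r_centers, values, r_max, half_extent, pitch)
    kernel = _beam_kernel(beam, pitch)
    out = fftconvolve(grid, kernel, mode="same") * pitch * pitch
    return SurfaceMap(pixels=out, pitch=pitch, valid_radius=analysis_radius)


def roi_mean_map(surface_map: SurfaceMap, diameter: float) -> float:
    """Mean over pixels whose centers lie within the central disk."""
    if 0.5 * diameter > surface_map.valid_radius + 1e-9:
        raise CoverageError(
            f"integration diameter {diameter:g} mm exceeds the valid "
            f"radius {surface_map.valid_radius:g} mm of the map"
        )
    mask = surface_map.radii() <= 0.5 * diameter
    return float(surface_map.pixels[mask].mean())


def compute_RT(
    surface_map: SurfaceMap,
    integration_diameter: float = 1.40,
    reference_scale: float = REFERENCE_REFLECTANCE,
) -> float:
    """Total diffuse reflectance: ROI mean of the large-disk map divided
    by the reference scale (the equivalent ROI mean of the reflectance
    standard under the same beam).

    The correction LUT shares this constant between training and query,
    so corrected fluorescence is invariant to its exact value.
    """
    if reference_scale <= 0:
        raise ValueError("reference_scale must be > 0")
    return roi_mean_map(surface_map, integration_diameter) / reference_scale


def compute_F(
    fluo_surface_map: SurfaceMap,
    integration_diameter: float = 1.40,
    reference_scale: float = REFERENCE_REFLECTANCE,
) -> float:
    """Fluorescence intensity: ROI mean of the fluorescence map under the
    large disk, reference-normalized exactly like R_T."""
    return compute_RT(fluo_surface_map, integration_diameter, reference_scale)


def compute_srr(
    surface_map: SurfaceMap, normalization_radius: float = 5.0
) -> RadialProfile:
    """Spatially resolved reflectance from the small-disk map.

    The angular average (here the exact radial cut) is normalized to the
    total intensity and area within ``normalization_radius``: values are
    divided by (sum of intensity within the disk) x (disk area), making
    the SRR independent of the overall intensity scale.
    """
    prof = surface_map.radial_profile()
    if normalization_radius > surface_map.valid_radius + 1e-9:
        raise CoverageError(
            f"normalization radius {normalization_radius:g} mm exceeds "
            f"valid radius {surface_map.valid_radius:g} mm"
        )
    edges = np.concatenate(
        [[0.0], 0.5 * (prof.r_centers[:-1] + prof.r_centers[1:]),
         [prof.r_centers[-1] + 0.5 * surface_map.pitch]]
    )
    areas = np.pi * np.diff(edges**2)
    inside = prof.r_centers <= normalization_radius
    total = float((prof.values[inside] * areas[inside]).sum())
    if total <= 0:
        raise ValueError("total intensity within normalization radius is 0")
    disk_area = np.pi * normalization_radius**2
    return RadialProfile(
        prof.r_centers,
        prof.values / (total * disk_area),
        normalization_radius=normalization_radius,
    )


def fit_slope_logsrr(
    profile: RadialProfile, fit_range: Tuple[float, float] = (1.1, 2.1)
) -> SlopeFit:
    """OLS fit of log10(SRR) against radius.

    A bin enters the fit iff its center lies in the closed interval
    ``fit_range``.  Non-positive values in the window are rejected (their
    logarithm is undefined) with the offending radius named.
    """
    lo, hi = fit_range
    sel = (profile.r_centers >= lo) & (profile.r_centers <= hi)
    r = profile.r_centers[sel]
    v = profile.values[sel]
    if r.size < 3:
        raise ValueError(
            f"need >= 3 bins with centers in [{lo}, {hi}] mm, got {r.size}"
        )
    bad = v <= 0
    if np.any(bad):
        raise ValueError(
            f"non-positive SRR at r = {r[bad][0]:.4g} mm: log10 undefined"
        )
    y = np.log10(v)
    slope, intercept = np.polyfit(r, y, 1)
    resid = y - (slope * r + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        fit_range=fit_range,
    )


def measure_triplet(
    excitation: ImpulseResponse,
    fluorescence: RadialProfile,
    large_beam: BeamSpec = LARGE_DISK,
    small_beam: BeamSpec = SMALL_DISK,
    integration_diameter: float = 1.40,
    srr_normalization_radius: float = 5.0,
    fit_range: Tuple[float, float] = (1.1, 2.1),
    pitch: float = DEFAULT_PITCH,
) -> Tuple[ReflectometryTriplet, SlopeFit]:
    """Full synthesis chain from impulse responses to (R_T, slope, F).

    The reference scale is the reflectance standard's ROI mean under the
    same large beam: REFERENCE_REFLECTANCE x peak irradiance.
    """
    ref_scale = REFERENCE_REFLECTANCE * large_beam.peak_irradiance(pitch)
    map_large = convolve_beam(
        excitation, large_beam, pitch,
        analysis_radius=max(2.0, 0.5 * integration_diameter + 0.5),
    )
    R_T = compute_RT(map_large, integration_diameter, ref_scale)
    map_small = convolve_beam(
        excitation, small_beam, pitch,
        analysis_radius=srr_normalization_radius + 0.3,
    )
    srr = compute_srr(map_small, srr_normalization_radius)
    fit = fit_slope_logsrr(srr, fit_range)
    map_fluo = convolve_beam(
        fluorescence, large_beam, pitch,
        analysis_radius=max(2.0, 0.5 * integration_diameter + 0.5),
    )
    F = compute_F(map_fluo, integration_diameter, ref_scale)
    return ReflectometryTriplet(R_T=R_T, slope_log_srr=fit.slope, F=F), fit


def profile_to_csv(profile: RadialProfile, path) -> None:
    pd.DataFrame({"r_mm": profile.r_centers, "srr": profile.values}).to_csv(
        path, index=False
    )


def triplets_to_csv(triplets, sample_ids, path) -> None:
    pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "R_T": [t.R_T for t in triplets],
            "slope_mm_inv": [t.slope_log_srr for t in triplets],
            "F": [t.F for t in triplets],
        }
    ).to_csv(path, index=False)


def triplets_from_csv(path):
    df = pd.read_csv(path)
    trips = [
        ReflectometryTriplet(
            R_T=float(row.R_T),
            slope_log_srr=float(row.slope_mm_inv),
            F=float(row.F),
        )
        for row in df.itertuples()
    ]
    return trips, df["sample_id"].tolist()
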