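"""Synthetic phantom generation: optical-property grids, emission-side
properties, training/test phantom sets, and rendered camera frames.

The generated sets emulate liquid phantoms of Intralipid (scatterer),
India ink (absorber) and a NIR fluorophore (Alexa Fluor 680-like,
excitation 670 nm / emission 716 nm) in black wells.  Default ranges are
mu_a in [0.05, 3] cm^-1 and mu_s' in [2.5, 100] cm^-1 at 670 nm,
logarithmically spaced; the training calibration concentration is
87 nM.  Emission-wavelength properties follow an Intralipid-like
scattering power law and a flat ink spectrum by default, both
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .media import OpticalMedium, per_cm
from .mc.transport import (
    ImpulseResponse,
    RadialProfile,
    SimulationConfig,
    simulate_fluorescence_impulse,
    simulate_impulse,
)
from .reflectometry import (
    LARGE_DISK,
    SMALL_DISK,
    BeamSpec,
    ReflectometryTriplet,
    SlopeFit,
    SurfaceMap,
    convolve_beam,
    measure_triplet,
)
from .lut import TrainingSet

# wavelengths (nm) of the emulated excitation/emission bands
LAMBDA_EX = 670.0
LAMBDA_EM = 716.0

#: calibration concentration shared by all training phantoms (nM)
C_CAL_NM = 87.0

#: fluorophore absorption per unit concentration, mm^-1 per nM
#: (ln(10) x molar extinction ~1.84e5 M^-1 cm^-1 of an Alexa-680-like dye)
MU_A_FLUO_PER_NM = math.log(10.0) * 1.84e5 * 1e-9 * 0.1

#: fluorescence quantum yield of the emulated dye
QUANTUM_YIELD = 0.36

#: default optical-property ranges at 670 nm (mm^-1)
MU_A_RANGE = (per_cm(0.05), per_cm(3.0))
MU_S_RANGE = (per_cm(2.5), per_cm(100.0))

#: training-phantom ranges (slightly inside the simulated ones)
TRAIN_MU_A_RANGE = (per_cm(0.08), per_cm(2.57))
TRAIN_MU_S_RANGE = (per_cm(3.02), per_cm(96.8))


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced optical-property grid (endpoints inclusive)."""

    N_a: int
    N_s: int
    mu_a_range: Tuple[float, float] = MU_A_RANGE
    mu_s_range: Tuple[float, float] = MU_S_RANGE

    def __post_init__(self) -> None:
        if self.N_a < 1 or self.N_s < 1:
            raise ValueError("N_a and N_s must be >= 1")
        for lo, hi in (self.mu_a_range, self.mu_s_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")


def _log_values(lo: float, hi: float, n: int) -> np.ndarray:
    if n == 1:
        # degenerate grid: the single value is the geometric mean
        return np.array([math.sqrt(lo * hi)])
    return np.geomspace(lo, hi, n)


def make_grid(spec: GridSpec) -> List[Tuple[float, float]]:
    """All (mu_a, mu_s') pairs of the grid, mu_a varying slowest."""
    mu_as = _log_values(*spec.mu_a_range, spec.N_a)
    mu_ss = _log_values(*spec.mu_s_range, spec.N_s)
    return [(float(a), float(s)) for a in mu_as for s in mu_ss]


def emission_properties(
    medium_ex: OpticalMedium,
    scatter_power: float = 2.4,
    ink_ratio: float = 1.0,
    lambda_ex: float = LAMBDA_EX,
    lambda_em: float = LAMBDA_EM,
) -> OpticalMedium:
    """Optical properties at the emission wavelength.

    Scattering follows the Intralipid-like power law
    mu_s'(lambda) ~ lambda**(-scatter_power); absorption scales by the
    ink spectral ratio (flat by default).
    """
    factor = (lambda_em / lambda_ex) ** (-scatter_power)
    return replace(
        medium_ex,
        mu_a=medium_ex.mu_a * ink_ratio,
        mu_s_prime=medium_ex.mu_s_prime * factor,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """One synthetic phantom: media at both wavelengths, fluorophore
    concentration (nM) and well depth (mm)."""

    medium_ex: OpticalMedium
    medium_em: OpticalMedium
    concentration: float = C_CAL_NM
    depth: float = math.inf
    label: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.depth > 0:
            raise ValueError("depth must be > 0")


def phantom_from_properties(
    mu_a: float,
    mu_s_prime: float,
    concentration: float = C_CAL_NM,
    depth: float = math.inf,
    n: float = 1.37,
    label: str = "",
    scatter_power: float = 2.4,
    ink_ratio: float = 1.0,
) -> PhantomSpec:
    ex = OpticalMedium(mu_a=mu_a, mu_s_prime=mu_s_prime, n=n, depth=depth)
    em = emission_properties(ex, scatter_power, ink_ratio)
    return PhantomSpec(
        medium_ex=ex,
        medium_em=em,
        concentration=concentration,
        depth=depth,
        label=label,
    )


def simulate_phantom(
    spec: PhantomSpec, cfg: SimulationConfig
) -> Tuple[ReflectometryTriplet, SlopeFit]:
    """Full chain for one phantom: excitation impulse -> fluorescence
    impulse -> disk synthesis -> (R_T, slope, F)."""
    excitation = simulate_impulse(spec.medium_ex, cfg)
    fluo = simulate_fluorescence_impulse(
        spec.medium_ex,
        spec.medium_em,
        MU_A_FLUO_PER_NM * spec.concentration,
        QUANTUM_YIELD,
        cfg,
        excitation=excitation,
    )
    return measure_triplet(excitation, fluo)


def build_training_set(
    grid: GridSpec | Sequence[Tuple[float, float]],
    cfg: SimulationConfig,
    c_cal: float = C_CAL_NM,
    depth: float = math.inf,
) -> TrainingSet:
    """Simulate the training phantoms of a grid and collect triplets."""
    pairs = make_grid(grid) if isinstance(grid, GridSpec) else list(grid)
    records = []
    for i, (mu_a, mu_sp) in enumerate(pairs):
        spec = phantom_from_properties(
            mu_a, mu_sp, concentration=c_cal, depth=depth, label=f"train_{i}"
        )
        trip, _ = simulate_phantom(spec, replace_seed(cfg, cfg.seed + i))
        records.append(trip)
    return TrainingSet(records=records, c_cal=c_cal)


def replace_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=int(seed))


def build_test_sets(
    cfg: SimulationConfig, seed: int = 0, n_concentration: int = 8
) -> Dict[str, List[PhantomSpec]]:
    """Synthetic test phantoms emulating the two experimental series.

    ``concentration_series``: phantoms with log-uniform optical
    properties inside the training ranges and varying concentration at
    the training depth (10 mm), plus two phantoms 10% outside the
    property ranges to exercise the extrapolation flag.
    ``depth_series``: four media x well depths {1, 3, 5, 10} mm at the
    calibration concentration (slab with absorbing bottom).
    """
    rng = np.random.default_rng(seed)
    specs_c: List[PhantomSpec] = []
    for i in range(n_concentration):
        mu_a = math.exp(rng.uniform(*np.log(TRAIN_MU_A_RANGE)))
        mu_sp = math.exp(rng.uniform(*np.log(TRAIN_MU_S_RANGE)))
        conc = float(rng.uniform(20.0, 180.0))
        specs_c.append(
            phantom_from_properties(
                mu_a, mu_sp, concentration=conc, depth=10.0,
                label=f"conc_{i}",
            )
        )
    for j, (mu_a, mu_sp) in enumerate(
        [
            (TRAIN_MU_A_RANGE[0] * 0.9, TRAIN_MU_S_RANGE[1] * 1.1),
            (TRAIN_MU_A_RANGE[1] * 1.1, TRAIN_MU_S_RANGE[0] * 0.9),
        ]
    ):
        specs_c.append(
            phantom_from_properties(
                mu_a, mu_sp, concentration=C_CAL_NM, depth=10.0,
                label=f"outside_{j}",
            )
        )
    media = [
        (TRAIN_MU_A_RANGE[0], TRAIN_MU_S_RANGE[0]),
        (TRAIN_MU_A_RANGE[0], TRAIN_MU_S_RANGE[1]),
        (TRAIN_MU_A_RANGE[1], TRAIN_MU_S_RANGE[0]),
        (TRAIN_MU_A_RANGE[1], TRAIN_MU_S_RANGE[1]),
    ]
    specs_d = [
        phantom_from_properties(
            mu_a, mu_sp, concentration=C_CAL_NM, depth=float(d),
            label=f"depth_{k}_{d}mm",
        )
        for k, (mu_a, mu_sp) in enumerate(media)
        for d in (1, 3, 5, 10)
    ]
    return {"concentration_series": specs_c, "depth_series": specs_d}


def phantoms_to_csv(specs: Sequence[PhantomSpec], path) -> None:
    pd.DataFrame(
        {
            "label": [s.label for s in specs],
            "mu_a_ex": [s.medium_ex.mu_a for s in specs],
            "mu_sp_ex": [s.medium_ex.mu_s_prime for s in specs],
            "mu_a_em": [s.medium_em.mu_a for s in specs],
            "mu_sp_em": [s.medium_em.mu_s_prime for s in specs],
            "c_nM": [s.concentration for s in specs],
            "depth_mm": [s.depth for s in specs],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------
# camera-frame rendering for the image pipeline
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Idealized 16-bit camera: linear response, constant background
    offset, optional Poisson shot noise and Gaussian read noise.  The
    default pixel pitch makes the 0.46 mm analysis strip 10 pixels
    wide."""

    pixel_pitch: float = 0.046     # mm / pixel
    n_pixels: int = 261            # square frame side
    gain: float = 3.0e5            # counts per (map unit x second)
    read_noise_sd: float = 0.0     # counts RMS
    background_offset: float = 100.0
    shot_noise: bool = False
    full_well: int = 65535


def _sample_map(
    surface_map: SurfaceMap,
    camera: CameraModel,
    center_shift: Tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Sample a radially symmetric surface map at camera pixel centers,
    optionally shifting the pattern center (oblique-incidence
    emulation)."""
    prof = surface_map.radial_profile()
    c = (camera.n_pixels - 1) / 2.0
    ax = (np.arange(camera.n_pixels) - c) * camera.pixel_pitch
    xx = ax[None, :] - center_shift[0]
    yy = ax[:, None] - center_shift[1]
    rr = np.hypot(xx, yy)
    center_value = float(surface_map.pixels[surface_map.center_index,
                                            surface_map.center_index])
    r_nodes = np.concatenate([[0.0], prof.r_centers])
    v_nodes = np.concatenate([[center_value], prof.values])
    return np.interp(rr, r_nodes, v_nodes, right=0.0)


def render_frames(
    reflect_map: SurfaceMap,
    fluo_map: SurfaceMap,
    dot_map: SurfaceMap,
    camera: CameraModel = CameraModel(),
    exposure_reflect: float = 0.5,
    exposure_fluo: float = 10.0,
    exposure_dot: float = 2.0,
    reference_level: Optional[float] = None,
    dot_shift: Tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
):
    """Render the five acquisition frames (reflectance, fluorescence,
    reference, background, spread dot) from truth surface maps.

    ``reference_level`` defaults to the reflectance of an ideal standard
    under the same (unit-energy) large beam: 0.99 x the beam peak
    irradiance; passing the value explicitly accommodates other beams.
    Returns a dict of :class:`fluolut.pipeline.CameraFrame`.
    """
    from .pipeline import CameraFrame  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    if reference_level is None:
        from .reflectometry import REFERENCE_REFLECTANCE

        reference_level = REFERENCE_REFLECTANCE * LARGE_DISK.peak_irradiance()

    def digitize(ideal_rate: np.ndarray, exposure: float) -> np.ndarray:
        counts = ideal_rate * camera.gain * exposure + camera.background_offset
        if camera.shot_noise:
            counts = rng.poisson(np.clip(counts, 0, None)).astype(float)
        if camera.read_noise_sd > 0:
            counts = counts + rng.normal(0, camera.read_noise_sd, counts.shape)
        return np.clip(np.round(counts), 0, camera.full_well)

    flat = np.full((camera.n_pixels, camera.n_pixels), reference_level)
    frames = {
        "reflectance": CameraFrame(
            pixels=digitize(_sample_map(reflect_map, camera), exposure_reflect),
            pixel_pitch=camera.pixel_pitch,
            exposure_time=exposure_reflect,
            kind="reflectance",
        ),
        "fluorescence": CameraFrame(
            pixels=digitize(_sample_map(fluo_map, camera), exposure_fluo),
            pixel_pitch=camera.pixel_pitch,
            exposure_time=exposure_fluo,
            kind="fluorescence",
        ),
        "reference": CameraFrame(
            pixels=digitize(flat, exposure_reflect),
            pixel_pitch=camera.pixel_pitch,
            exposure_time=exposure_reflect,
            kind="reference",
        ),
        "background": CameraFrame(
            pixels=np.full(
                (camera.n_pixels, camera.n_pixels),
                camera.background_offset,
            ),
            pixel_pitch=camera.pixel_pitch,
            exposure_time=exposure_reflect,
            kind="background",
        ),
        "spread_dot": CameraFrame(
            pixels=digitize(
                _sample_map(dot_map, camera, center_shift=dot_shift),
                exposure_dot,
            ),
            pixel_pitch=camera.pixel_pitch,
            exposure_time=exposure_dot,
            kind="spread_dot",
        ),
    }
    return frames


def render_phantom_frames(
    excitation: ImpulseResponse,
    fluorescence: RadialProfile,
    camera: CameraModel = CameraModel(),
    large_beam: BeamSpec = LARGE_DISK,
    small_beam: BeamSpec = SMALL_DISK,
    seed: int = 0,
    **kwargs,
):
    """Convenience wrapper: synthesize the three surface maps from the
    impulse responses and render the acquisition frames."""
    reflect_map = convolve_beam(excitation, large_beam, analysis_radius=4.0)
    fluo_map = convolve_beam(fluorescence, large_beam, analysis_radius=4.0)
    dot_map = convolve_beam(excitation, small_beam, analysis_radius=5.3)
    return render_frames(
        reflect_map, fluo_map, dot_map, camera=camera, seed=seed, **kwargs
    )
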