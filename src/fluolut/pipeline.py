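"""Camera-frame processing chain.

Reproduces, on synthetic or real grayscale frames, the acquisition
processing that turns raw images into the three LUT quantities:
background subtraction, exposure-time normalization, normalization to a
reflectance reference, disk-ROI averaging (R_T, F), and for the spread
dot: intensity-and-area normalization around the peak, strip-based
radial profiling and the log10 slope fit.

The oblique incidence of the real instrument shifts the spread-dot peak
slightly along the incidence direction; the radial profile is therefore
taken within a narrow strip perpendicular to that direction, where the
shift matters least.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import tifffile
from scipy.ndimage import uniform_filter

from .mc.transport import RadialProfile
from .reflectometry import ReflectometryTriplet, SlopeFit, fit_slope_logsrr

FRAME_KINDS = (
    "fluorescence",
    "reflectance",
    "reference",
    "background",
    "spread_dot",
)


@dataclass
class CameraFrame:
    """One acquisition: nonnegative pixel intensities plus metadata."""

    pixels: np.ndarray
    pixel_pitch: float   # mm / pixel
    exposure_time: float  # s
    kind: str = "reflectance"
    incidence_direction: Tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not self.exposure_time > 0:
            raise ValueError("exposure_time must be > 0")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.kind not in FRAME_KINDS:
            raise ValueError(f"kind must be one of {FRAME_KINDS}")


@dataclass(frozen=True)
class StripSpec:
    """Analysis strip for the spread-dot radial profile: a band of the
    given width through the peak, running perpendicular to the
    incidence direction."""

    width: float = 0.46  # mm
    incidence_direction: Tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("strip width must be > 0")


def preprocess(
    frame: CameraFrame,
    background: CameraFrame,
    reference: Optional[CameraFrame] = None,
    background_ref: Optional[CameraFrame] = None,
) -> np.ndarray:
    """Background-subtract, exposure-normalize and (optionally)
    reference-normalize a frame.

    out = ((frame - bkg) / ET) / ((reference - bkg_ref) / ET_ref)

    Negative pixels after background subtraction are clipped to zero.
    Any reference pixel <= 0 after its own subtraction is an error (the
    division is undefined there).
    """
    if frame.pixels.shape != background.pixels.shape:
        raise ValueError("frame and background shapes differ")
    num = np.clip(frame.pixels - background.pixels, 0.0, None)
    num /= frame.exposure_time
    if reference is None:
        return num
    bkg_ref = background if background_ref is None else background_ref
    if reference.pixels.shape != frame.pixels.shape:
        raise ValueError("reference shape differs from frame")
    den = (reference.pixels - bkg_ref.pixels) / reference.exposure_time
    if np.any(den <= 0):
        raise ValueError(
            "reference has pixels <= 0 after background subtraction"
        )
    return num / den


def roi_mean(
    frame: np.ndarray,
    center: Tuple[float, float],
    diameter: float = 1.40,
    pixel_pitch: float = 0.046,
) -> float:
    """Mean over pixels whose centers lie within the circle (pixel
    center-in-circle rule, no area weighting).  ``center`` is (x, y) in
    pixel coordinates."""
    ny, nx = frame.shape
    cx, cy = center
    rad = 0.5 * diameter / pixel_pitch
    if cx - rad < -0.5 or cx + rad > nx - 0.5 or cy - rad < -0.5 or cy + rad > ny - 0.5:
        raise ValueError("ROI extends outside the frame")
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
    return float(frame[mask].mean())


def find_peak(frame: np.ndarray) -> Tuple[int, int]:
    """Peak position (x, y) after 3x3 mean smoothing.

    Bright cores often clip at the camera's full well, leaving a plateau
    of identical maximal values; the peak is taken as the (rounded)
    centroid of that plateau, which reduces to the single argmax pixel
    when there is no tie.  Rounding halves toward the lower index, so
    the result is deterministic."""
    smooth = uniform_filter(np.asarray(frame, float), size=3, mode="nearest")
    top = smooth >= smooth.max() * (1.0 - 1e-12)
    ys, xs = np.nonzero(top)
    return int(np.floor(xs.mean() + 0.5)), int(np.floor(ys.mean() + 0.5))


def ia_normalize(
    frame: np.ndarray,
    center: Tuple[float, float],
    radius: float = 3.7,
    pixel_pitch: float = 0.046,
) -> np.ndarray:
    """Normalize to both the total intensity and the area within
    ``radius`` of the peak: divide by (sum within radius x disk area).
    Downstream slope fitting is invariant to this constant."""
    ny, nx = frame.shape
    cx, cy = center
    rad = radius / pixel_pitch
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
    total = float(frame[mask].sum())
    if total <= 0:
        raise ValueError("total intensity within the radius is 0")
    return frame / (total * math.pi * radius**2)


def strip_radial_profile(
    frame: np.ndarray,
    peak: Tuple[float, float],
    strip: StripSpec = StripSpec(),
    pixel_pitch: float = 0.046,
) -> RadialProfile:
    """Radial profile from pixels inside the analysis strip.

    Pixels whose centers lie within ``strip.width`` of the line through
    the peak perpendicular to the incidence direction are binned by
    their distance to the peak at pixel-pitch resolution; each bin
    reports the mean intensity.  Empty bins are dropped.
    """
    ny, nx = frame.shape
    cx, cy = peak
    dx, dy = strip.incidence_direction
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("incidence_direction must be nonzero")
    ux, uy = dx / norm, dy / norm
    yy, xx = np.mgrid[0:ny, 0:nx]
    # distance along the incidence direction = across the strip
    along = (xx - cx) * ux + (yy - cy) * uy
    half_w = 0.5 * strip.width / pixel_pitch
    mask = np.abs(along) <= half_w
    if not np.any(mask):
        raise ValueError("strip lies outside the frame")
    rr = np.hypot(xx - cx, yy - cy)[mask] * pixel_pitch
    vv = frame[mask]
    nbin = int(np.ceil(rr.max() / pixel_pitch)) + 1
    idx = np.minimum((rr / pixel_pitch + 0.5).astype(int), nbin - 1)
    sums = np.bincount(idx, weights=vv, minlength=nbin)
    counts = np.bincount(idx, minlength=nbin)
    filled = counts > 0
    centers = np.arange(nbin)[filled] * pixel_pitch
    values = sums[filled] / counts[filled]
    if centers[0] == 0.0:  # RadialProfile wants strictly positive radii
        centers = centers[1:]
        values = values[1:]
    return RadialProfile(centers, values)


def process_acquisition(
    frames: Dict[str, CameraFrame],
    integration_diameter: float = 1.40,
    ia_radius: float = 3.7,
    fit_range: Tuple[float, float] = (1.1, 2.1),
    strip: Optional[StripSpec] = None,
    roi_center: Optional[Tuple[float, float]] = None,
) -> Tuple[ReflectometryTriplet, SlopeFit]:
    """Full processing chain from the five raw frames to the triplet.

    ``frames`` must contain 'reflectance', 'fluorescence', 'reference',
    'background' and 'spread_dot'.  The ROI for R_T and F defaults to
    the frame center; the spread-dot peak is located automatically.
    """
    missing = [k for k in FRAME_KINDS if k not in frames]
    if missing:
        raise KeyError(f"missing frames: {missing}")
    bkg = frames["background"]
    ref = frames["reference"]
    pitch = frames["reflectance"].pixel_pitch

    refl = preprocess(frames["reflectance"], bkg, ref)
    fluo = preprocess(frames["fluorescence"], bkg, ref)
    if roi_center is None:
        ny, nx = refl.shape
        roi_center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    R_T = roi_mean(refl, roi_center, integration_diameter, pitch)
    F = roi_mean(fluo, roi_center, integration_diameter, pitch)

    dot = preprocess(frames["spread_dot"], bkg)  # background only
    peak = find_peak(dot)
    dot = ia_normalize(dot, peak, ia_radius, pitch)
    if strip is None:
        strip = StripSpec(
            incidence_direction=frames["spread_dot"].incidence_direction
        )
    prof = strip_radial_profile(dot, peak, strip, pitch)
    fit = fit_slope_logsrr(prof, fit_range)
    return (
        ReflectometryTriplet(R_T=R_T, slope_log_srr=fit.slope, F=F),
        fit,
    )


# ---------------------------------------------------------------------
# TIFF + JSON-sidecar round trip
# ---------------------------------------------------------------------

def save_frame(path, frame: CameraFrame, as_uint16: bool = True) -> None:
    path = Path(path)
    data = frame.pixels
    if as_uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_pitch": frame.pixel_pitch,
        "exposure_time": frame.exposure_time,
        "kind": frame.kind,
        "incidence_direction": list(frame.incidence_direction),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_frame(path) -> CameraFrame:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return CameraFrame(
        pixels=tifffile.imread(path),
        pixel_pitch=float(meta["pixel_pitch"]),
        exposure_time=float(meta["exposure_time"]),
        kind=meta["kind"],
        incidence_direction=tuple(meta.get("incidence_direction", (1.0, 0.0))),
    )


def load_acquisition(directory) -> Dict[str, CameraFrame]:
    """Load the five frames of one acquisition from a directory holding
    '<kind>.tif' plus '<kind>.json' sidecars."""
    directory = Path(directory)
    frames = {}
    for kind in FRAME_KINDS:
        for suffix in (".tif", ".tiff"):
            p = directory / f"{kind}{suffix}"
            if p.exists():
                frames[kind] = load_frame(p)
                break
    return frames
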