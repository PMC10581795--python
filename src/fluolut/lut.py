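"""Look-up-table correction of fluorescence intensity.

Training phantoms share geometry and fluorophore concentration c_cal but
span the optical-property range of interest.  Each contributes a record
(R_T, slopelogSRR, F); its correcting value is cvF = log10(1/F).  A
scattered-data interpolant over the (R_T, slope) plane then yields cvF
for any query, and the corrected intensity is

    F_corrected = F * 10**cvF(R_T, slopelogSRR),

which equals 1 exactly at every training phantom.  The fluorophore
concentration follows as c = c_cal * F_corrected (linear in F; quenching
excluded).  The log/power-of-10 pair keeps the interpolated surface
well-behaved where F is strongly attenuated.

Two interpolants are provided, both exact at the nodes: piecewise-linear
barycentric interpolation on a Delaunay triangulation, and a thin-plate
spline (r^2 log r kernel plus affine part).  TPS inputs are standardized
to zero mean / unit variance of the training set, since the kernel is
not scale-invariant and R_T and the slope carry different units.
Queries outside the training convex hull are evaluated (TPS extrapolates
naturally; the linear method continues the affine function of the
nearest simplex) and flagged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay

from .reflectometry import ReflectometryTriplet


@dataclass
class TrainingSet:
    """Measured (R_T, slopelogSRR, F) records of the training phantoms,
    all at the shared calibration concentration ``c_cal`` (nM)."""

    records: List[ReflectometryTriplet]
    c_cal: float

    def __post_init__(self) -> None:
        if self.c_cal <= 0:
            raise ValueError("c_cal must be > 0")
        if any(rec.F <= 0 for rec in self.records):
            raise ValueError("all training F must be > 0 (log10(1/F) must exist)")

    @property
    def inputs(self) -> np.ndarray:
        return np.array(
            [[rec.R_T, rec.slope_log_srr] for rec in self.records], float
        )

    @property
    def cvf(self) -> np.ndarray:
        return np.log10(
            1.0 / np.array([rec.F for rec in self.records], float)
        )


@dataclass
class CorrectionResult:
    F_corrected: float
    c_estimate: float
    extrapolated: bool


@dataclass
class CorrectionLUT:
    """Fitted interpolator from (R_T, slopelogSRR) to cvF."""

    method: str
    nodes: np.ndarray          # (n, 2) raw training inputs
    cvf: np.ndarray            # (n,) training outputs
    c_cal: float
    scale_mean: np.ndarray
    scale_std: np.ndarray
    ridge: float = 0.0
    _tps: Optional[RBFInterpolator] = field(default=None, repr=False)
    _tri: Optional[Delaunay] = field(default=None, repr=False)
    _plane_coefs: Optional[np.ndarray] = field(default=None, repr=False)

    # -- evaluation ---------------------------------------------------
    def _standardize(self, xy: np.ndarray) -> np.ndarray:
        return (xy - self.scale_mean) / self.scale_std

    def evaluate(self, R_T: float, slope: float) -> Tuple[float, bool]:
        """cvF at a query point, plus an outside-the-hull flag."""
        q = np.array([[float(R_T), float(slope)]])
        if not np.all(np.isfinite(q)):
            raise ValueError("R_T and slope must be finite")
        inside = bool(self._tri.find_simplex(self._standardize(q))[0] >= 0)
        if self.method == "tps":
            val = float(self._tps(self._standardize(q))[0])
        else:
            val = float(self._linear_eval(self._standardize(q)[0]))
        return val, not inside

    def _linear_eval(self, q: np.ndarray) -> float:
        tri = self._tri
        isimp = int(tri.find_simplex(q[None, :])[0])
        if isimp < 0:
            # outside the hull: evaluate the nearest-simplex affine
            # function at the projection of the query onto the hull.
            # Boundary simplices can be slivers with steep planes, so the
            # plane is not extended beyond the hull itself -- the value
            # continues constant along the outward normal.  Ties resolve
            # to the lowest simplex index (jitter-free).
            proj = self._project_to_hull(q)
            inward = proj + 1e-9 * (tri.points.mean(axis=0) - proj)
            isimp = int(tri.find_simplex(inward[None, :])[0])
            if isimp < 0:
                isimp = int(
                    np.argmin(
                        ((tri.points[tri.simplices].mean(axis=1) - q) ** 2)
                        .sum(axis=1)
                    )
                )
            q = proj
        a, b, c0 = self._plane_coefs[isimp]
        return a * q[0] + b * q[1] + c0

    def _project_to_hull(self, q: np.ndarray) -> np.ndarray:
        pts = self._tri.points
        best = None
        best_d = math.inf
        for i0, i1 in self._tri.convex_hull:
            p0, p1 = pts[i0], pts[i1]
            d = p1 - p0
            t = float(np.dot(q - p0, d) / max(np.dot(d, d), 1e-300))
            t = min(max(t, 0.0), 1.0)
            cand = p0 + t * d
            dist = float(np.dot(q - cand, q - cand))
            if dist < best_d:
                best_d = dist
                best = cand
        return best

    # -- application --------------------------------------------------
    def correct(self, F: float, R_T: float, slope: float) -> CorrectionResult:
        if F < 0:
            raise ValueError("F must be >= 0")
        cvf, extrapolated = self.evaluate(R_T, slope)
        F_corr = F * 10.0**cvf
        return CorrectionResult(
            F_corrected=F_corr,
            c_estimate=self.c_cal * F_corr,
            extrapolated=extrapolated,
        )

    # -- serialization ------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "c_cal": self.c_cal,
            "ridge": self.ridge,
            "nodes": self.nodes.tolist(),
            "cvf": self.cvf.tolist(),
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "CorrectionLUT":
        with open(path) as f:
            payload = json.load(f)
        lut = cls(
            method=payload["method"],
            nodes=np.array(payload["nodes"], float),
            cvf=np.array(payload["cvf"], float),
            c_cal=float(payload["c_cal"]),
            scale_mean=np.array(payload["scale_mean"], float),
            scale_std=np.array(payload["scale_std"], float),
            ridge=float(payload.get("ridge", 0.0)),
        )
        _fit(lut)
        return lut


def _fit(lut: CorrectionLUT) -> None:
    xy = (lut.nodes - lut.scale_mean) / lut.scale_std
    try:
        lut._tri = Delaunay(xy)
    except Exception as exc:  # qhull degenerate-input errors
        raise ValueError(
            "training inputs are degenerate (collinear?) — cannot "
            f"triangulate: {exc}"
        ) from exc
    if lut._tri.nsimplex == 0:
        raise ValueError("training inputs are collinear: no 2-D simplex")
    # per-simplex affine coefficients for linear evaluation/extrapolation
    coefs = np.empty((lut._tri.nsimplex, 3))
    for i, simp in enumerate(lut._tri.simplices):
        p = xy[simp]
        A = np.column_stack([p, np.ones(3)])
        coefs[i] = np.linalg.solve(A, lut.cvf[simp])
    lut._plane_coefs = coefs
    if lut.method == "tps":
        try:
            lut._tps = RBFInterpolator(
                xy,
                lut.cvf,
                kernel="thin_plate_spline",
                degree=1,
                smoothing=lut.ridge,
            )
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(np.column_stack([xy, np.ones(len(xy))]))
            raise ValueError(
                "thin-plate spline system is singular "
                f"(input design condition number {cond:.3g})"
            ) from exc


def build_lut(
    train: TrainingSet, method: str = "tps", ridge: float = 0.0
) -> CorrectionLUT:
    """Fit the correcting LUT.

    ``method='linear'`` interpolates cvF barycentrically on the Delaunay
    triangulation of the (standardized) training inputs;
    ``method='tps'`` fits an exact thin-plate spline (``ridge > 0``
    relaxes exactness for noisy experimental tables).
    """
    if method not in ("linear", "tps"):
        raise ValueError("method must be 'linear' or 'tps'")
    nodes = train.inputs
    if len(nodes) < 3:
        raise ValueError("need >= 3 training records")
    mean = nodes.mean(axis=0)
    std = nodes.std(axis=0)
    std[std == 0] = 1.0
    lut = CorrectionLUT(
        method=method,
        nodes=nodes,
        cvf=train.cvf,
        c_cal=train.c_cal,
        scale_mean=mean,
        scale_std=std,
        ridge=ridge,
    )
    _fit(lut)
    return lut


def correct(
    F: float, R_T: float, slope: float, lut: CorrectionLUT
) -> CorrectionResult:
    """Apply the LUT: F_corrected = F * 10**cvF(R_T, slope)."""
    return lut.correct(F, R_T, slope)


def estimate_concentration(result: CorrectionResult, c_cal: float) -> float:
    """Fluorophore concentration c = c_cal * F_corrected (nM)."""
    if c_cal <= 0:
        raise ValueError("c_cal must be > 0")
    return c_cal * result.F_corrected


def fr_correct(F: float, R_T: float) -> float:
    """Baseline 'F/R' correction: raw fluorescence over the diffuse
    reflectance at the excitation wavelength."""
    if R_T <= 0:
        raise ValueError("R_T must be > 0 for the F/R baseline")
    return F / R_T


def correct_many(
    triplets: Sequence[ReflectometryTriplet], lut: CorrectionLUT
) -> List[CorrectionResult]:
    return [lut.correct(t.F, t.R_T, t.slope_log_srr) for t in triplets]
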