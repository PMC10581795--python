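"""Numba kernels for photon transport in a homogeneous turbid slab.

Geometry: the medium occupies 0 <= z <= depth (depth may be inf), with
the source at the origin of the top surface and z pointing into the
medium.  The surrounding half-space is air (n = 1).

Transport scheme: exponential step sampling; partial Fresnel
transmission at the top boundary, including total internal reflection;
Henyey-Greenstein or isotropic scattering; Russian roulette below a
weight threshold; a finite bottom boundary absorbs all incident weight
(black backing).

Absorption uses one of two unbiased schemes chosen per medium by cost:
the MCML-style continuous deposition (a fraction mu_a/mu_t of the weight
is deposited at every interaction), which keeps many low-weight photons
alive and so gives low-variance reflectance tails, but costs
~ln(1/W_th)*mu_t/mu_a steps per non-escaping photon; and analog survival
sampling (the photon terminates with probability mu_a/mu_t, depositing
its full weight), which bounds the cost by the absorption time.  The
continuous scheme is used whenever its step bound is moderate
(mu_a/mu_t >= ANALOG_SWITCH_LOSS); for the extreme-albedo media beyond
that, photons are almost never absorbed and the two schemes have
near-identical variance, so the cheaper analog scheme is used.

All kernels consume an explicit 64-bit RNG state (splitmix64) so that
runs are bit-reproducible for a fixed seed.

All kernels consume an explicit 64-bit RNG state (splitmix64) so that
runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the scalar tally array
T_REFL = 0      # diffusely reflected weight (all radii)
T_TRANS = 1     # weight absorbed by the bottom backing
T_ABS = 2       # weight absorbed in the medium (all positions)
T_ABS_OUT = 3   # part of T_ABS deposited outside the (r, z) record grid
N_TALLY = 4

#: below this single-interaction loss fraction mu_a/mu_t, absorption is
#: sampled analog instead of by continuous weight deposition (the
#: continuous scheme would need > ~1150 steps per non-escaping photon;
#: at such albedos the statistics are escape-dominated and the two
#: schemes have near-identical variance)
ANALOG_SWITCH_LOSS = 8e-3

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _rand(state):
    """splitmix64 -> float64 uniform in [0, 1)."""
    state[0] = state[0] + _SM_GAMMA
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    z = z ^ (z >> np.uint64(31))
    return float(z >> np.uint64(11)) * _INV_2_53


@njit(cache=True, inline="always", fastmath=True)
def _fresnel_internal(cos_i, n_rel):
    """Unpolarized internal Fresnel reflectance for incidence from the
    medium (index n_rel) onto air; cos_i = |uz| > 0."""
    if n_rel == 1.0:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    # n1 = n_rel (medium), n2 = 1 (air)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _propagate(state, x, y, z, ux, uy, uz, w,
               mu_a, mu_s, g, n_rel, depth,
               dr, refl_r,
               dr_abs, dz_abs, a_rz,
               roulette_threshold, roulette_survival,
               tallies, max_steps):
    """Trace one photon from its current state to termination, updating
    the surface-reflectance histogram, the absorbed-weight map and the
    scalar tallies in place."""
    mu_t = mu_a + mu_s
    p_abs = mu_a / mu_t
    analog = p_abs < ANALOG_SWITCH_LOSS
    n_r = refl_r.shape[0]
    n_z_abs, n_r_abs = a_rz.shape
    for _ in range(max_steps):
        s_left = -math.log(1.0 - _rand(state))  # dimensionless step
        # advance, handling boundary crossings within this step
        while True:
            step = s_left / mu_t
            if uz < 0.0 and z + step * uz < 0.0:
                db = -z / uz
                x += db * ux
                y += db * uy
                z = 0.0
                s_left -= db * mu_t
                refl = _fresnel_internal(-uz, n_rel)
                esc = w * (1.0 - refl)
                if esc > 0.0:
                    tallies[T_REFL] += esc
                    ir = int(math.sqrt(x * x + y * y) / dr)
                    if ir < n_r:
                        refl_r[ir] += esc
                w *= refl
                if w <= 0.0:
                    return
                uz = -uz
            elif uz > 0.0 and z + step * uz > depth:
                db = (depth - z) / uz
                x += db * ux
                y += db * uy
                tallies[T_TRANS] += w
                return
            else:
                x += step * ux
                y += step * uy
                z += step * uz
                break
        # interaction: deposit absorbed weight (analog or continuous)
        if analog:
            if _rand(state) < p_abs:
                tallies[T_ABS] += w
                ir = int(math.sqrt(x * x + y * y) / dr_abs)
                iz = int(z / dz_abs)
                if ir < n_r_abs and iz < n_z_abs:
                    a_rz[iz, ir] += w
                else:
                    tallies[T_ABS_OUT] += w
                return
        else:
            dw = w * p_abs
            tallies[T_ABS] += dw
            ir = int(math.sqrt(x * x + y * y) / dr_abs)
            iz = int(z / dz_abs)
            if ir < n_r_abs and iz < n_z_abs:
                a_rz[iz, ir] += dw
            else:
                tallies[T_ABS_OUT] += dw
            w -= dw
        # scatter: HG phase function (g = 0 reduces to isotropic)
        if g == 0.0:
            cos_t = 2.0 * _rand(state) - 1.0
        else:
            tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * _rand(state))
            cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            if cos_t > 1.0:
                cos_t = 1.0
            elif cos_t < -1.0:
                cos_t = -1.0
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
        phi = 2.0 * math.pi * _rand(state)
        cos_p = math.cos(phi)
        sin_p = math.sin(phi)
        if abs(uz) > 0.99999:
            ux = sin_t * cos_p
            uy = sin_t * sin_p
            uz = cos_t if uz >= 0.0 else -cos_t
        else:
            den = math.sqrt(1.0 - uz * uz)
            nux = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
            nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
            uz = -sin_t * cos_p * den + uz * cos_t
            ux = nux
            uy = nuy
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
        if w < roulette_threshold:
            if _rand(state) < roulette_survival:
                w /= roulette_survival
            else:
                return
    # safety net: deposit any residual weight as absorbed
    tallies[T_ABS] += w
    tallies[T_ABS_OUT] += w


@njit(cache=True)
def trace_pencil(n_photons, seed,
                 mu_a, mu_s, g, n_rel, depth,
                 r_max, n_r, z_max, n_z,
                 roulette_threshold, roulette_survival):
    """Pencil-beam impulse: photons enter at the origin along +z with unit
    weight (the specular fraction is handled by the caller).

    Returns (refl_r, a_rz, tallies): raw weight sums, not yet normalized.
    """
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed) * np.uint64(0x2545F4914F6CDD1D) + np.uint64(1)
    refl_r = np.zeros(n_r, dtype=np.float64)
    a_rz = np.zeros((n_z, n_r), dtype=np.float64)
    tallies = np.zeros(N_TALLY, dtype=np.float64)
    dr = r_max / n_r
    dz = z_max / n_z
    for _ in range(n_photons):
        _propagate(state, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0,
                   mu_a, mu_s, g, n_rel, depth,
                   dr, refl_r,
                   dr, dz, a_rz,
                   roulette_threshold, roulette_survival,
                   tallies, 10_000_000)
    return refl_r, a_rz, tallies


@njit(cache=True)
def trace_volume_source(n_photons, seed, cdf, n_r_src, src_dr, src_dz,
                        mu_a, mu_s, g, n_rel, depth,
                        r_max, n_r, z_max, n_z,
                        roulette_threshold, roulette_survival):
    """Isotropic volume source distributed according to ``cdf``, the
    flattened (row-major, z outer) cumulative weight over an
    (n_z_src, n_r_src) cell grid with pitches (src_dz, src_dr).
    Positions are jittered uniformly within the sampled cell (uniform per
    annulus area in r, uniform in z); the azimuth is random.  Photons are
    launched with unit weight and an isotropic direction.

    Returns (refl_r, a_rz, tallies) raw weight sums.
    """
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed) * np.uint64(0x9E6C63D0876A6A4F) + np.uint64(3)
    refl_r = np.zeros(n_r, dtype=np.float64)
    a_rz = np.zeros((n_z, n_r), dtype=np.float64)
    tallies = np.zeros(N_TALLY, dtype=np.float64)
    dr = r_max / n_r
    dz = z_max / n_z
    n_cells = cdf.shape[0]
    for _ in range(n_photons):
        u = _rand(state)
        idx = np.searchsorted(cdf, u, side="right")
        if idx >= n_cells:
            idx = n_cells - 1
        iz = idx // n_r_src
        ir = idx - iz * n_r_src
        r_lo = ir * src_dr
        r_hi = r_lo + src_dr
        r0 = math.sqrt(r_lo * r_lo + _rand(state) * (r_hi * r_hi - r_lo * r_lo))
        phi = 2.0 * math.pi * _rand(state)
        x = r0 * math.cos(phi)
        y = r0 * math.sin(phi)
        z = (iz + _rand(state)) * src_dz
        if z > depth:
            z = depth
        cos_t = 2.0 * _rand(state) - 1.0
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
        psi = 2.0 * math.pi * _rand(state)
        _propagate(state, x, y, z,
                   sin_t * math.cos(psi), sin_t * math.sin(psi), cos_t, 1.0,
                   mu_a, mu_s, g, n_rel, depth,
                   dr, refl_r,
                   dr, dz, a_rz,
                   roulette_threshold, roulette_survival,
                   tallies, 10_000_000)
    return refl_r, a_rz, tallies
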