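"""Numba photon-transport kernel for layered slab media.

Sequential, single-stream-per-photon weighted-packet Monte Carlo:

* exponential free paths at the layer-local total interaction coefficient,
  truncated at slab interfaces and domain walls with resampling of the
  remaining optical path (memoryless, hence exact for layered media);
* survival-weighting at every scattering event (weight times the single
  scattering albedo, absorbed fraction deposited to the energy ledger);
* Henyey-Greenstein polar scattering, uniform azimuth;
* unpolarized Fresnel reflection / Snell refraction at every interface with
  a refractive-index step, including total internal reflection;
* per-voxel fluence tally of weight x path length along every sub-step
  (Amanatides-Woo traversal when a sub-step crosses voxel boundaries);
* Russian roulette below a weight threshold, compensated so the expectation
  is unbiased; the ledger records the (zero-mean) roulette residual.

Every photon owns a counter-seeded xorshift128+ substream, so results are
bit-reproducible for a given root seed independent of batching.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

_MASK = uint64(0xFFFFFFFFFFFFFFFF)
_EPS = 1e-9  # mm nudge across interfaces
_MAX_EVENTS = 5_000_000


@njit(cache=True, fastmath=True, inline="always")
def _splitmix64(state):
    state = (state + uint64(0x9E3779B97F4A7C15)) & _MASK
    z = state
    z = ((z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)) & _MASK
    return state, z ^ (z >> uint64(31))


@njit(cache=True, fastmath=True, inline="always")
def _rng_init(seed, photon_index):
    state = (uint64(seed) * uint64(0x2545F4914F6CDD1D) + uint64(photon_index)) & _MASK
    state, s0 = _splitmix64(state)
    state, s1 = _splitmix64(state)
    if s0 == uint64(0) and s1 == uint64(0):
        s1 = uint64(1)
    return s0, s1


@njit(cache=True, fastmath=True, inline="always")
def _rng_next(s0, s1):
    # xorshift128+; returns a double in (0, 1]
    x = s0
    y = s1
    s0 = y
    x ^= (x << uint64(23)) & _MASK
    x ^= x >> uint64(17)
    x ^= y ^ (y >> uint64(26))
    s1 = x
    r = (x + y) & _MASK
    u = (np.float64(r >> uint64(11)) + 1.0) * (1.0 / 9007199254740992.0)
    return u, s0, s1


@njit(cache=True, fastmath=True, inline="always")
def _tally_segment(fluence, voxel_inv, nx, ny, nz, x0, y0, z0, x1, y1, z1, amount, seglen):
    """Accumulate ``amount`` x path length into voxels along the segment."""
    i0 = int(x0 * voxel_inv)
    j0 = int(y0 * voxel_inv)
    k0 = int(z0 * voxel_inv)
    i1 = int(x1 * voxel_inv)
    j1 = int(y1 * voxel_inv)
    k1 = int(z1 * voxel_inv)
    if i0 == i1 and j0 == j1 and k0 == k1:
        if 0 <= i0 < nx and 0 <= j0 < ny and 0 <= k0 < nz:
            fluence[i0, j0, k0] += amount * seglen
        return
    # Amanatides-Woo traversal, parameter t in [0, 1] along the segment
    dx = x1 - x0
    dy = y1 - y0
    dz = z1 - z0
    voxel = 1.0 / voxel_inv
    if dx > 0.0:
        step_i, t_delta_x = 1, voxel / dx
        t_max_x = ((i0 + 1) * voxel - x0) / dx
    elif dx < 0.0:
        step_i, t_delta_x = -1, -voxel / dx
        t_max_x = (i0 * voxel - x0) / dx
    else:
        step_i, t_delta_x, t_max_x = 0, 1e30, 1e30
    if dy > 0.0:
        step_j, t_delta_y = 1, voxel / dy
        t_max_y = ((j0 + 1) * voxel - y0) / dy
    elif dy < 0.0:
        step_j, t_delta_y = -1, -voxel / dy
        t_max_y = (j0 * voxel - y0) / dy
    else:
        step_j, t_delta_y, t_max_y = 0, 1e30, 1e30
    if dz > 0.0:
        step_k, t_delta_z = 1, voxel / dz
        t_max_z = ((k0 + 1) * voxel - z0) / dz
    elif dz < 0.0:
        step_k, t_delta_z = -1, -voxel / dz
        t_max_z = (k0 * voxel - z0) / dz
    else:
        step_k, t_delta_z, t_max_z = 0, 1e30, 1e30

    i, j, k = i0, j0, k0
    t_prev = 0.0
    while t_prev < 1.0:
        if t_max_x <= t_max_y and t_max_x <= t_max_z:
            t_next = t_max_x
            axis = 0
        elif t_max_y <= t_max_z:
            t_next = t_max_y
            axis = 1
        else:
            t_next = t_max_z
            axis = 2
        if t_next > 1.0:
            t_next = 1.0
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
            fluence[i, j, k] += amount * (t_next - t_prev) * seglen
        t_prev = t_next
        if t_prev >= 1.0:
            break
        if axis == 0:
            i += step_i
            t_max_x += t_delta_x
        elif axis == 1:
            j += step_j
            t_max_y += t_delta_y
        else:
            k += step_k
            t_max_z += t_delta_z


@njit(cache=True, fastmath=True, inline="always")
def _fresnel_r(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance; returns (R, cos_transmitted)."""
    if n1 == n2:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n1 / n2
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, fastmath=True)
def transport(
    n_photons,
    seed,
    z_bounds,  # (n_layers + 1,) interface depths, z_bounds[0] = 0
    mu_a,
    mu_s,
    g_arr,
    n_arr,
    n_outside,
    src_x,
    src_y,
    cos_cap,  # cosine of the source cone half-angle
    det_x,
    det_y,
    det_r2,
    voxel,
    r_thresh,
    r_surv,
    refract_launch,  # cone sampled in the exterior medium, refracted at entry
    fluence,  # (nx, ny, nz) float64, zero-initialised
    det_weight,
    det_path,
    det_exit_x,
    det_exit_y,
):
    nx, ny, nz = fluence.shape
    xmax = nx * voxel
    ymax = ny * voxel
    zmax = nz * voxel
    voxel_inv = 1.0 / voxel
    n_layers = mu_a.shape[0]

    absorbed = 0.0
    escaped = 0.0
    detected = 0.0
    roulette_res = 0.0
    n_det = 0

    for ip in range(n_photons):
        s0, s1 = _rng_init(seed, ip)

        # --- launch: cone about +z, uniform over the spherical cap
        u, s0, s1 = _rng_next(s0, s1)
        uz = 1.0 - u * (1.0 - cos_cap)
        sin_t = np.sqrt(max(0.0, 1.0 - uz * uz))
        # uniform azimuth via the rejection double-angle trick (no trig calls)
        while True:
            ua, s0, s1 = _rng_next(s0, s1)
            ub, s0, s1 = _rng_next(s0, s1)
            a = 2.0 * ua - 1.0
            b = 2.0 * ub - 1.0
            r2 = a * a + b * b
            if 0.0 < r2 <= 1.0:
                break
        cos_p = (a * a - b * b) / r2
        sin_p = 2.0 * a * b / r2

        if refract_launch:
            # cone angle is in the exterior medium; Fresnel + Snell at entry
            R, cos_t = _fresnel_r(n_outside, n_arr[0], uz)
            u, s0, s1 = _rng_next(s0, s1)
            if u < R:
                escaped += 1.0
                continue
            sin_t2 = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            ux = sin_t2 * cos_p
            uy = sin_t2 * sin_p
            uz = cos_t
        else:
            ux = sin_t * cos_p
            uy = sin_t * sin_p

        x = src_x
        y = src_y
        z = _EPS
        w = 1.0
        path = 0.0
        layer = 0
        alive = True
        events = 0

        while alive:
            events += 1
            if events > _MAX_EVENTS:
                roulette_res += w
                break
            mt = mu_a[layer] + mu_s[layer]
            if mt > 0.0:
                u, s0, s1 = _rng_next(s0, s1)
                step = -np.log(u) / mt
            else:
                step = 1e30

            # distance to the slab interface along the flight direction
            if uz > 0.0:
                d_if = (z_bounds[layer + 1] - z) / uz
            elif uz < 0.0:
                d_if = (z_bounds[layer] - z) / uz
            else:
                d_if = 1e30
            if d_if < 0.0:
                d_if = 0.0
            # distance to the lateral domain walls (axis 0 = x, 1 = y)
            d_wall = 1e30
            wall_axis = 0
            if ux > 0.0:
                d_wall = (xmax - x) / ux
            elif ux < 0.0:
                d_wall = -x / ux
            if uy > 0.0:
                d = (ymax - y) / uy
            elif uy < 0.0:
                d = -y / uy
            else:
                d = 1e30
            if d < d_wall:
                d_wall = d
                wall_axis = 1
            if d_wall < 0.0:
                d_wall = 0.0

            cause = 0  # 0 scatter, 1 interface, 2 wall
            t = step
            if d_if < t:
                t = d_if
                cause = 1
            if d_wall < t:
                t = d_wall
                cause = 2

            x1 = x + ux * t
            y1 = y + uy * t
            z1 = z + uz * t
            if t > 0.0:
                _tally_segment(fluence, voxel_inv, nx, ny, nz, x, y, z, x1, y1, z1, w, t)
            path += t
            x = x1
            y = y1
            z = z1

            if cause == 2:
                # lateral face: Fresnel against the exterior medium
                if wall_axis == 0:
                    cos_i = ux if ux > 0.0 else -ux
                else:
                    cos_i = uy if uy > 0.0 else -uy
                R, _ = _fresnel_r(n_arr[layer], n_outside, cos_i)
                u, s0, s1 = _rng_next(s0, s1)
                if u < R:
                    if wall_axis == 0:
                        ux = -ux
                        x = _EPS if x <= 0.0 + _EPS else xmax - _EPS
                    else:
                        uy = -uy
                        y = _EPS if y <= 0.0 + _EPS else ymax - _EPS
                    continue
                escaped += w
                break

            if cause == 1:
                going_up = uz < 0.0
                if going_up and layer == 0:
                    # top surface: Fresnel into the exterior medium
                    R, cos_t = _fresnel_r(n_arr[0], n_outside, -uz)
                    u, s0, s1 = _rng_next(s0, s1)
                    if u < R:
                        uz = -uz
                        z = _EPS
                    else:
                        escaped += w
                        ddx = x - det_x
                        ddy = y - det_y
                        if ddx * ddx + ddy * ddy <= det_r2:
                            detected += w
                            det_weight[n_det] = w
                            det_path[n_det] = path
                            det_exit_x[n_det] = x
                            det_exit_y[n_det] = y
                            n_det += 1
                        break
                elif (not going_up) and layer == n_layers - 1:
                    # bottom face: Fresnel against the exterior medium
                    R, _ = _fresnel_r(n_arr[layer], n_outside, uz)
                    u, s0, s1 = _rng_next(s0, s1)
                    if u < R:
                        uz = -uz
                        z = zmax - _EPS
                    else:
                        escaped += w
                        break
                else:
                    nxt = layer - 1 if going_up else layer + 1
                    n1 = n_arr[layer]
                    n2 = n_arr[nxt]
                    if n1 == n2:
                        layer = nxt
                        z = z - _EPS if going_up else z + _EPS
                    else:
                        cos_i = -uz if going_up else uz
                        R, cos_t = _fresnel_r(n1, n2, cos_i)
                        u, s0, s1 = _rng_next(s0, s1)
                        if u < R:
                            uz = -uz
                            z = z + _EPS if going_up else z - _EPS
                        else:
                            ratio = n1 / n2
                            ux *= ratio
                            uy *= ratio
                            uz = -cos_t if going_up else cos_t
                            layer = nxt
                            z = z - _EPS if going_up else z + _EPS
                continue

            # --- scattering event
            absorbed += w * (mu_a[layer] / mt)
            w *= mu_s[layer] / mt
            if w <= 0.0:
                break

            g = g_arr[layer]
            u, s0, s1 = _rng_next(s0, s1)
            if g == 0.0:
                cos_s = 2.0 * u - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cos_s = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cos_s > 1.0:
                    cos_s = 1.0
                elif cos_s < -1.0:
                    cos_s = -1.0
            sin_s = np.sqrt(max(0.0, 1.0 - cos_s * cos_s))
            while True:
                ua, s0, s1 = _rng_next(s0, s1)
                ub, s0, s1 = _rng_next(s0, s1)
                a = 2.0 * ua - 1.0
                b = 2.0 * ub - 1.0
                r2 = a * a + b * b
                if 0.0 < r2 <= 1.0:
                    break
            cos_p = (a * a - b * b) / r2
            sin_p = 2.0 * a * b / r2

            if uz > 0.99999999 or uz < -0.99999999:
                ux = sin_s * cos_p
                uy = sin_s * sin_p
                uz = cos_s if uz > 0.0 else -cos_s
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_n = sin_s * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_s
                uy_n = sin_s * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_s
                uz_n = -den * sin_s * cos_p + uz * cos_s
                ux = ux_n
                uy = uy_n
                uz = uz_n

            if w < r_thresh:
                u, s0, s1 = _rng_next(s0, s1)
                if u < r_surv:
                    w_new = w / r_surv
                    roulette_res -= w_new - w
                    w = w_new
                else:
                    roulette_res += w
                    break

    return absorbed, escaped, detected, roulette_res, n_det
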