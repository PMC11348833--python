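"""Numba photon-packet transport kernel.

All geometry inside the kernel is in centimetres.  Each photon owns an
independent counter-seeded xorshift64* stream, so results are bitwise
reproducible for a given (seed, photon count) regardless of execution
order.  Variance reduction is implicit capture (a weight fraction
mu_a/mu_t is deposited at every interaction) plus Russian roulette below a
weight threshold.  Fluence uses the track-length estimator (valid also for
mu_a = 0 voxels); the absorption tally feeds the energy audit:

    launched + roulette_gain == absorbed + escaped + roulette_loss

exactly, up to float summation.  Refractive-index mismatches between
adjacent voxels trigger unpolarized Fresnel reflection/refraction at the
shared face; this is what makes an implanted high-index probe behave as a
waveguide.  Crossing the outer grid boundary is a plain escape.
"""

import math

import numpy as np
from numba import njit

_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_GOLD = np.uint64(0x9E3779B97F4A7C15)
_MULT = np.uint64(2685821657736338717)
_INV53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _photon_state(seed, ip):
    z = (np.uint64(seed) + np.uint64(1)) * _GOLD + (np.uint64(ip) + np.uint64(1)) * _MIX1
    z ^= z >> np.uint64(30)
    z *= _MIX1
    z ^= z >> np.uint64(27)
    z *= _MIX2
    z ^= z >> np.uint64(31)
    if z == np.uint64(0):
        z = _GOLD
    return z


@njit(cache=True, inline="always")
def _next_u(state):
    """xorshift64*; returns (new_state, uniform in (0, 1])."""
    s = state
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    r = s * _MULT
    u = (np.float64(r >> np.uint64(11)) + 1.0) * _INV53
    return s, u


@njit(cache=True, inline="always")
def _fresnel(n1, n2, ci):
    """Unpolarized Fresnel reflectance at a planar interface.

    Returns (R, cos_theta_t, tir).  ci is the incidence cosine in [0, 1].
    """
    if n1 == n2:
        return 0.0, ci, False
    st2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0, 0.0, True
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct, False


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if abs(g) < 1e-12:
        return 1.0 - 2.0 * u
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def mc_transport(
    labels,
    mua_l,
    mus_l,
    g_l,
    n_l,
    extra_mua,
    dx,
    dy,
    dz,
    src_kind,
    sx,
    sy,
    sz,
    vx,
    vy,
    vz,
    e1x,
    e1y,
    e1z,
    e2x,
    e2y,
    e2z,
    radius,
    cos_half,
    n_photons,
    seed,
    w_thresh,
    p_surv,
    max_path,
    fluence,
    absorbed,
    class_abs,
):
    """Trace n_photons packets; tallies accumulate in-place.

    Returns (launched, escaped, roulette_gain, roulette_loss) weights.
    ``fluence`` accumulates sum(w * path) per voxel [cm]; ``absorbed``
    accumulates deposited weight per voxel; ``class_abs`` per label.
    """
    nx, ny, nz = labels.shape
    Lx = nx * dx
    Ly = ny * dy
    Lz = nz * dz
    launched = 0.0
    escaped = 0.0
    r_gain = 0.0
    r_loss = 0.0

    for ip in range(n_photons):
        state = _photon_state(seed, ip)
        x = sx
        y = sy
        z = sz
        ux = vx
        uy = vy
        uz = vz

        if src_kind == 1:  # isotropic point
            state, u1 = _next_u(state)
            state, u2 = _next_u(state)
            ct = 1.0 - 2.0 * u1
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * u2
            ux = st * math.cos(phi)
            uy = st * math.sin(phi)
            uz = ct
        elif src_kind >= 2:  # disk sources
            state, u1 = _next_u(state)
            state, u2 = _next_u(state)
            r = radius * math.sqrt(u1)
            psi = 2.0 * math.pi * u2
            cpsi = math.cos(psi)
            spsi = math.sin(psi)
            x += r * (cpsi * e1x + spsi * e2x)
            y += r * (cpsi * e1y + spsi * e2y)
            z += r * (cpsi * e1z + spsi * e2z)
            state, u3 = _next_u(state)
            state, u4 = _next_u(state)
            if src_kind == 2:  # Lambertian
                ct = math.sqrt(u3)
            else:  # uniform within cone
                ct = 1.0 - u3 * (1.0 - cos_half)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * u4
            cp = math.cos(phi)
            sp = math.sin(phi)
            ux = st * (cp * e1x + sp * e2x) + ct * vx
            uy = st * (cp * e1y + sp * e2y) + ct * vy
            uz = st * (cp * e1z + sp * e2z) + ct * vz

        w = 1.0
        launched += 1.0

        # enter the grid if launched outside it
        if x < 0.0 or x >= Lx or y < 0.0 or y >= Ly or z < 0.0 or z >= Lz:
            tmin = 0.0
            tmax = 1.0e30
            ok = True
            for axis in range(3):
                if axis == 0:
                    p, u, L = x, ux, Lx
                elif axis == 1:
                    p, u, L = y, uy, Ly
                else:
                    p, u, L = z, uz, Lz
                if abs(u) < 1e-14:
                    if p < 0.0 or p >= L:
                        ok = False
                        break
                else:
                    t1 = (0.0 - p) / u
                    t2 = (L - p) / u
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tmin:
                        tmin = t1
                    if t2 < tmax:
                        tmax = t2
            if (not ok) or tmin > tmax or tmax <= 0.0:
                escaped += w
                continue
            t_entry = tmin + 1e-9
            x += t_entry * ux
            y += t_entry * uy
            z += t_entry * uz
            if x < 0.0 or x >= Lx or y < 0.0 or y >= Ly or z < 0.0 or z >= Lz:
                escaped += w
                continue

        ix = int(x / dx)
        iy = int(y / dy)
        iz = int(z / dz)
        if ix > nx - 1:
            ix = nx - 1
        if iy > ny - 1:
            iy = ny - 1
        if iz > nz - 1:
            iz = nz - 1

        alive = True
        path = 0.0
        stuck = 0
        while alive:
            state, u = _next_u(state)
            tau = -math.log(u)
            while True:
                lab = labels[ix, iy, iz]
                mua_v = mua_l[lab] + extra_mua[ix, iy, iz]
                mus_v = mus_l[lab]
                mut = mua_v + mus_v

                if ux > 0.0:
                    tx = ((ix + 1) * dx - x) / ux
                elif ux < 0.0:
                    tx = (ix * dx - x) / ux
                else:
                    tx = 1.0e30
                if uy > 0.0:
                    ty = ((iy + 1) * dy - y) / uy
                elif uy < 0.0:
                    ty = (iy * dy - y) / uy
                else:
                    ty = 1.0e30
                if uz > 0.0:
                    tz = ((iz + 1) * dz - z) / uz
                elif uz < 0.0:
                    tz = (iz * dz - z) / uz
                else:
                    tz = 1.0e30
                tb = tx
                if ty < tb:
                    tb = ty
                if tz < tb:
                    tb = tz
                if tb < 0.0:
                    tb = 0.0

                if mut > 0.0 and tau <= mut * tb:
                    # interaction inside this voxel
                    s = tau / mut
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    fluence[ix, iy, iz] += w * s
                    path += s
                    if path >= max_path:
                        escaped += w
                        alive = False
                        break
                    a = w * mua_v / mut
                    absorbed[ix, iy, iz] += a
                    class_abs[lab] += a
                    w -= a
                    if w <= 0.0:
                        alive = False
                        break
                    gv = g_l[lab]
                    state, u1 = _next_u(state)
                    state, u2 = _next_u(state)
                    ct = _hg_cos(gv, u1)
                    st = math.sqrt(max(0.0, 1.0 - ct * ct))
                    phi = 2.0 * math.pi * u2
                    cp = math.cos(phi)
                    sp = math.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = st * cp
                        uy = st * sp
                        uz = ct if uz >= 0.0 else -ct
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        uxn = st * (ux * uz * cp - uy * sp) / den + ux * ct
                        uyn = st * (uy * uz * cp + ux * sp) / den + uy * ct
                        uzn = -st * cp * den + uz * ct
                        norm = math.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                        ux = uxn / norm
                        uy = uyn / norm
                        uz = uzn / norm
                    if w < w_thresh:
                        state, ur = _next_u(state)
                        if ur <= p_surv:
                            r_gain += w * (1.0 / p_surv - 1.0)
                            w /= p_surv
                        else:
                            r_loss += w
                            alive = False
                    break  # resample optical depth
                else:
                    # propagate to the voxel boundary
                    s = tb
                    fluence[ix, iy, iz] += w * s
                    tau -= mut * s
                    path += s
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    if path >= max_path:
                        escaped += w
                        alive = False
                        break
                    if s <= 0.0:
                        stuck += 1
                        if stuck > 1000:
                            escaped += w
                            alive = False
                            break
                    else:
                        stuck = 0

                    if tx <= ty and tx <= tz:
                        axis = 0
                    elif ty <= tz:
                        axis = 1
                    else:
                        axis = 2
                    jx, jy, jz = ix, iy, iz
                    if axis == 0:
                        jx += 1 if ux > 0.0 else -1
                    elif axis == 1:
                        jy += 1 if uy > 0.0 else -1
                    else:
                        jz += 1 if uz > 0.0 else -1
                    if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                        escaped += w
                        alive = False
                        break
                    n1 = n_l[lab]
                    n2 = n_l[labels[jx, jy, jz]]
                    if n1 != n2:
                        if axis == 0:
                            ci = abs(ux)
                        elif axis == 1:
                            ci = abs(uy)
                        else:
                            ci = abs(uz)
                        R, ct_t, tir = _fresnel(n1, n2, ci)
                        state, ur = _next_u(state)
                        if tir or ur <= R:
                            if axis == 0:
                                ux = -ux
                            elif axis == 1:
                                uy = -uy
                            else:
                                uz = -uz
                            # stay in the current voxel
                        else:
                            eta = n1 / n2
                            if axis == 0:
                                sgn = 1.0 if ux > 0.0 else -1.0
                                uy *= eta
                                uz *= eta
                                ux = sgn * ct_t
                            elif axis == 1:
                                sgn = 1.0 if uy > 0.0 else -1.0
                                ux *= eta
                                uz *= eta
                                uy = sgn * ct_t
                            else:
                                sgn = 1.0 if uz > 0.0 else -1.0
                                ux *= eta
                                uy *= eta
                                uz = sgn * ct_t
                            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                            ux /= norm
                            uy /= norm
                            uz /= norm
                            ix, iy, iz = jx, jy, jz
                    else:
                        ix, iy, iz = jx, jy, jz
                    # keep consuming the remaining optical depth

    return launched, escaped, r_gain, r_loss
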