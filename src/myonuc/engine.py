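"""Numerical core of the myotube simulation.

All per-step physics runs in numba-compiled kernels over flat arrays:
overdamped Langevin motion of bodies (nuclei, centrosome-like structures)
and of microtubule vertex chains, elliptical confinement, soft excluded
volume, Hookean connector springs with linear force–velocity motor walking,
microtubule dynamic instability (growth attenuated by antagonistic force
and by tubulin-pool depletion, growth-rate-dependent catastrophe, no
rescue), and first-order stochastic binding/unbinding/nucleation events.

Randomness is counter-based: every variate is a pure hash of
(seed, step, purpose, entity), so a replicate is a pure function of its
seed, replicates are independent, and two conditions run with the same
seed consume identical randomness per shared entity.

The inextensibility of fibers is enforced by projecting segment lengths
back to their stored values after each move (minus end outward), rather
than by stiff stretching springs; bending elasticity is the small-angle
harmonic discretization of the worm-like chain with rigidity κ.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------
# parameter-vector layout (all float64, units μm / s / pN)
DT = 0; KT = 1; VISC = 2; CONF_K = 3; STERIC_K = 4; SEG_L0 = 5; RIGID = 6
VGROW0 = 7; VSHRINK = 8; FG = 9; LMAX = 10; CAT_TF = 11; CAT_TS = 12
NUC_RATE = 13; ELL_A = 14; ELL_B = 15; CONN_D = 16; EPS_NUC = 17
NPAR = 18

# connector species ids
SP_DYNEIN = 0; SP_KIF5B = 1; SP_MAP4 = 2; SP_MAP7KIF5B = 3
# head kinds
HEAD_ANCHOR = 0; HEAD_PASSIVE = 1; HEAD_MOTOR = 2

# event-counter layout
EV_NUCLEATION = 0; EV_CATASTROPHE = 1; EV_REMOVAL = 2; EV_FIRST_NUC_STEP = 3
EV_ATTACH = 4; EV_DETACH = 5
NEV = 6

# RNG purposes
_P_BODY = 1; _P_VERT = 2; _P_CAT = 3; _P_NUC = 4; _P_NUCDIR = 5
_P_ATTACH = 6; _P_DETACH = 7; _P_DIFF = 8

_U64 = np.uint64


@njit(cache=True, inline="always")
def _mix(z):
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _u01(seed, step, purpose, entity, sub):
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    z = _mix(z ^ (_U64(step) * _U64(0xD6E8FEB86659FD93)))
    z = _mix(z ^ (_U64(purpose) * _U64(0xA5CB3D8D51B16E4D))
             ^ (_U64(entity) * _U64(0xC2B2AE3D27D4EB4F)) ^ _U64(sub))
    z = _mix(z)
    # 53-bit mantissa, offset so u is never exactly 0
    return (z >> _U64(11)) * (1.0 / 9007199254740992.0) + 5.551115123125783e-17


@njit(cache=True, inline="always")
def _norm2(seed, step, purpose, entity):
    """Two independent standard normals (Box-Muller)."""
    u1 = _u01(seed, step, purpose, entity, 0)
    u2 = _u01(seed, step, purpose, entity, 1)
    r = np.sqrt(-2.0 * np.log(u1))
    return r * np.cos(2.0 * np.pi * u2), r * np.sin(2.0 * np.pi * u2)


# ------------------------------------------------------------- geometry --

@njit(cache=True)
def nearest_on_ellipse(a, b, px, py):
    """Closest boundary point of the axis-aligned ellipse (a, b) for a point
    on or outside it (bisection on the standard orthogonal-projection
    equation; robust for points on the axes)."""
    sx = 1.0 if px >= 0.0 else -1.0
    sy = 1.0 if py >= 0.0 else -1.0
    p0 = abs(px); p1 = abs(py)
    ea = a * a; eb = b * b
    t_lo = 0.0
    t_hi = a * p0 + b * p1 + a
    for _ in range(200):
        f = (a * p0 / (t_hi + ea)) ** 2 + (b * p1 / (t_hi + eb)) ** 2 - 1.0
        if f < 0.0:
            break
        t_hi *= 2.0
    for _ in range(110):
        t = 0.5 * (t_lo + t_hi)
        f = (a * p0 / (t + ea)) ** 2 + (b * p1 / (t + eb)) ** 2 - 1.0
        if f > 0.0:
            t_lo = t
        else:
            t_hi = t
    t = 0.5 * (t_lo + t_hi)
    return sx * ea * p0 / (t + ea), sy * eb * p1 / (t + eb)


@njit(cache=True, inline="always")
def _confinement(px, py, a, b, k):
    """Penalty force on a point: zero inside, k·depth toward the nearest
    boundary point outside."""
    if (px / a) ** 2 + (py / b) ** 2 <= 1.0:
        return 0.0, 0.0
    qx, qy = nearest_on_ellipse(a, b, px, py)
    return k * (qx - px), k * (qy - py)


# -------------------------------------------------------------- formulas --

@njit(cache=True, inline="always")
def growth_speed_formula(v0, f_antagonistic, fg, l_poly, l_max):
    f = f_antagonistic if f_antagonistic > 0.0 else 0.0
    free = 1.0 - l_poly / l_max
    if free < 0.0:
        free = 0.0
    return v0 * free * np.exp(-f / fg)


@njit(cache=True, inline="always")
def catastrophe_rate_formula(v, v0, t_free, t_stalled):
    x = v / v0
    if x < 0.0:
        x = 0.0
    elif x > 1.0:
        x = 1.0
    return 1.0 / (t_stalled + (t_free - t_stalled) * x)


@njit(cache=True, inline="always")
def motor_speed_formula(v0, f_opposing, f_stall):
    f = f_opposing if f_opposing > 0.0 else 0.0
    v = v0 * (1.0 - f / f_stall)
    if v < 0.0:
        v = 0.0
    elif v > v0:
        v = v0
    return v


@njit(cache=True, inline="always")
def _mt_length(nv, last, l0):
    if nv < 2:
        return 0.0
    return (nv - 2) * l0 + last


@njit(cache=True, inline="always")
def _point_on_mt(verts, m, nv, last, l0, s):
    """Position and tangent at abscissa s (measured from the minus end)."""
    i = int(s / l0)
    nseg = nv - 1
    if i > nseg - 1:
        i = nseg - 1
    seglen = l0 if i < nseg - 1 else last
    local = s - i * l0
    t = local / seglen if seglen > 0.0 else 0.0
    if t > 1.0:
        t = 1.0
    elif t < 0.0:
        t = 0.0
    ax = verts[m, i, 0]; ay = verts[m, i, 1]
    bx = verts[m, i + 1, 0]; by = verts[m, i + 1, 1]
    dx = bx - ax; dy = by - ay
    dn = np.sqrt(dx * dx + dy * dy)
    if dn > 1e-12:
        ux = dx / dn; uy = dy / dn
    else:
        ux = 1.0; uy = 0.0
    return ax + t * dx, ay + t * dy, ux, uy, i, t


@njit(cache=True)
def _find_binding(qx, qy, capr, exclude_mt, exclude_body, mt_body,
                  mt_alive, mt_nv, mt_last, verts, bbox, l0):
    """Nearest MT point within capture radius of (qx, qy).

    Returns (mt, abscissa, found).  Scans MTs in id order with a strict
    improvement test, so equidistant candidates resolve to the lowest id.
    ``exclude_body`` skips fibers nucleated from that body: NE motors act
    on passing MTs, not on the aster anchored to their own nucleus (whose
    self-load is internal and nets to zero).
    """
    best_d2 = capr * capr * (1.0 + 1e-12)
    best_m = -1
    best_s = 0.0
    M = mt_alive.shape[0]
    for m in range(M):
        if mt_alive[m] == 0 or m == exclude_mt:
            continue
        if exclude_body >= 0 and mt_body[m] == exclude_body:
            continue
        if (qx < bbox[m, 0] - capr or qx > bbox[m, 1] + capr or
                qy < bbox[m, 2] - capr or qy > bbox[m, 3] + capr):
            continue
        nv = mt_nv[m]
        s_base = 0.0
        for seg in range(nv - 1):
            seglen = l0 if seg < nv - 2 else mt_last[m]
            ax = verts[m, seg, 0]; ay = verts[m, seg, 1]
            dx = verts[m, seg + 1, 0] - ax; dy = verts[m, seg + 1, 1] - ay
            L2 = dx * dx + dy * dy
            if L2 > 1e-24:
                t = ((qx - ax) * dx + (qy - ay) * dy) / L2
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
            else:
                t = 0.0
            cx = ax + t * dx; cy = ay + t * dy
            d2 = (qx - cx) ** 2 + (qy - cy) ** 2
            if d2 < best_d2:
                best_d2 = d2
                best_m = m
                best_s = s_base + t * seglen
            s_base += seglen
    return best_m, best_s, best_m >= 0


@njit(cache=True, inline="always")
def _anchor_point(body_pos, body_rad, body, angle):
    return (body_pos[body, 0] + body_rad[body] * np.cos(angle),
            body_pos[body, 1] + body_rad[body] * np.sin(angle))


@njit(cache=True)
def run_kernel(body_pos, body_rad, body_drag, body_mobile,
               site_body, site_angle, site_active, site_mt,
               mt_alive, mt_growing, mt_nv, mt_last, mt_body, verts,
               con_sp, con_anchor_body, con_anchor_angle, con_pos,
               con_state, con_mt, con_abs,
               sp_v0, sp_dir, sp_fstall, sp_kon, sp_koff, sp_capr, sp_springk,
               sp_fdetach, head_kind,
               P, pool, n_steps, stride, seed,
               fr_body, fr_poly, fr_sumlen, fr_nmts, fr_maxpen, ev):
    nb = body_pos.shape[0]
    ns = site_body.shape[0]
    M = mt_alive.shape[0]
    C = con_sp.shape[0]
    VMAX = verts.shape[1]
    dt = P[DT]; kT = P[KT]; l0 = P[SEG_L0]
    a = P[ELL_A]; b = P[ELL_B]
    kb = P[RIGID] / (l0 * l0 * l0)
    gamma_v = P[VISC] * l0

    f_body = np.zeros((nb, 2))
    f_vert = np.zeros((M, VMAX, 2))
    bbox = np.zeros((M, 4))
    mt_fant = np.zeros(M)

    # per-step attach probabilities are species constants
    p_on = 1.0 - np.exp(-sp_kon * dt)
    p_off = 1.0 - np.exp(-sp_koff * dt)
    p_nuc = 1.0 - np.exp(-P[NUC_RATE] * dt)
    sig_diff = np.sqrt(2.0 * P[CONN_D] * dt)

    fidx = 0
    for rec in range(1):  # record initial frame
        for i in range(nb):
            fr_body[0, i, 0] = body_pos[i, 0]
            fr_body[0, i, 1] = body_pos[i, 1]
        fr_poly[0] = pool[0]
        fr_sumlen[0] = 0.0
        fr_nmts[0] = 0
        fr_maxpen[0] = 0.0
        fidx = 1

    for step in range(n_steps):
        # ---------------- forces ----------------
        for i in range(nb):
            f_body[i, 0] = 0.0
            f_body[i, 1] = 0.0
        for m in range(M):
            if mt_alive[m] == 0:
                continue
            nv = mt_nv[m]
            for i in range(nv):
                f_vert[m, i, 0] = 0.0
                f_vert[m, i, 1] = 0.0
            # bounding box for binding searches
            xmin = verts[m, 0, 0]; xmax = xmin
            ymin = verts[m, 0, 1]; ymax = ymin
            for i in range(1, nv):
                x = verts[m, i, 0]; y = verts[m, i, 1]
                if x < xmin:
                    xmin = x
                elif x > xmax:
                    xmax = x
                if y < ymin:
                    ymin = y
                elif y > ymax:
                    ymax = y
            bbox[m, 0] = xmin; bbox[m, 1] = xmax
            bbox[m, 2] = ymin; bbox[m, 3] = ymax

        # fiber bending (small-angle harmonic) + vertex confinement +
        # vertex-body soft sterics
        for m in range(M):
            if mt_alive[m] == 0:
                continue
            nv = mt_nv[m]
            for i in range(1, nv - 1):
                bx = verts[m, i - 1, 0] - 2.0 * verts[m, i, 0] + verts[m, i + 1, 0]
                by = verts[m, i - 1, 1] - 2.0 * verts[m, i, 1] + verts[m, i + 1, 1]
                f_vert[m, i - 1, 0] -= kb * bx
                f_vert[m, i - 1, 1] -= kb * by
                f_vert[m, i, 0] += 2.0 * kb * bx
                f_vert[m, i, 1] += 2.0 * kb * by
                f_vert[m, i + 1, 0] -= kb * bx
                f_vert[m, i + 1, 1] -= kb * by
            for i in range(nv):
                px = verts[m, i, 0]; py = verts[m, i, 1]
                fx, fy = _confinement(px, py, a, b, P[CONF_K])
                f_vert[m, i, 0] += fx
                f_vert[m, i, 1] += fy
                for j in range(nb):
                    dx = px - body_pos[j, 0]
                    dy = py - body_pos[j, 1]
                    r = body_rad[j]
                    d2 = dx * dx + dy * dy
                    if d2 < r * r:
                        d = np.sqrt(d2)
                        if d > 1e-9:
                            ux = dx / d; uy = dy / d
                        else:
                            ux = 1.0; uy = 0.0
                        mag = P[STERIC_K] * (r - d)
                        f_vert[m, i, 0] += mag * ux
                        f_vert[m, i, 1] += mag * uy
                        f_body[j, 0] -= mag * ux
                        f_body[j, 1] -= mag * uy

        # body-body sterics and body confinement (reduced ellipse)
        for i in range(nb):
            for j in range(i + 1, nb):
                dx = body_pos[i, 0] - body_pos[j, 0]
                dy = body_pos[i, 1] - body_pos[j, 1]
                rsum = body_rad[i] + body_rad[j]
                d2 = dx * dx + dy * dy
                if d2 < rsum * rsum:
                    d = np.sqrt(d2)
                    if d > 1e-9:
                        ux = dx / d; uy = dy / d
                    else:
                        ux = 1.0; uy = 0.0  # coincident centers: fallback +x
                    mag = P[STERIC_K] * (rsum - d)
                    f_body[i, 0] += mag * ux
                    f_body[i, 1] += mag * uy
                    f_body[j, 0] -= mag * ux
                    f_body[j, 1] -= mag * uy
        maxpen = 0.0
        for i in range(nb):
            ra = a - body_rad[i]
            rb = b - body_rad[i]
            px = body_pos[i, 0]; py = body_pos[i, 1]
            fx, fy = _confinement(px, py, ra, rb, P[CONF_K])
            f_body[i, 0] += fx
            f_body[i, 1] += fy
            pen = np.sqrt(fx * fx + fy * fy) / P[CONF_K] if P[CONF_K] > 0 else 0.0
            if pen > maxpen:
                maxpen = pen

        # connector springs (zero rest length, equal and opposite)
        for c in range(C):
            sp = con_sp[c]
            # head invalidation: bound to a dead MT -> free
            for h in range(2):
                if con_state[c, h] == 1 and mt_alive[con_mt[c, h]] == 0:
                    con_state[c, h] = 0
                    con_mt[c, h] = -1
            # locate both heads
            ab = con_anchor_body[c]
            loc0 = False; loc1 = False
            x0 = 0.0; y0 = 0.0; x1 = 0.0; y1 = 0.0
            m0 = -1; i0 = 0; t0 = 0.0
            m1 = -1; i1 = 0; t1 = 0.0
            if ab >= 0:
                x0, y0 = _anchor_point(body_pos, body_rad, ab, con_anchor_angle[c])
                loc0 = True
            elif con_state[c, 0] == 1:
                m0 = con_mt[c, 0]
                s = con_abs[c, 0]
                x0, y0, _, _, i0, t0 = _point_on_mt(verts, m0, mt_nv[m0],
                                                    mt_last[m0], l0, s)
                loc0 = True
            if con_state[c, 1] == 1:
                m1 = con_mt[c, 1]
                s = con_abs[c, 1]
                x1, y1, _, _, i1, t1 = _point_on_mt(verts, m1, mt_nv[m1],
                                                    mt_last[m1], l0, s)
                loc1 = True
            if loc0 and loc1:
                k = sp_springk[sp]
                fx = k * (x1 - x0)   # force on head0
                fy = k * (y1 - y0)
                if ab >= 0:
                    f_body[ab, 0] += fx
                    f_body[ab, 1] += fy
                elif m0 >= 0:
                    f_vert[m0, i0, 0] += (1.0 - t0) * fx
                    f_vert[m0, i0, 1] += (1.0 - t0) * fy
                    f_vert[m0, i0 + 1, 0] += t0 * fx
                    f_vert[m0, i0 + 1, 1] += t0 * fy
                if m1 >= 0:
                    f_vert[m1, i1, 0] -= (1.0 - t1) * fx
                    f_vert[m1, i1, 1] -= (1.0 - t1) * fy
                    f_vert[m1, i1 + 1, 0] -= t1 * fx
                    f_vert[m1, i1 + 1, 1] -= t1 * fy

        # route minus-end vertex forces to the anchoring body;
        # antagonistic force on the growing tip
        for m in range(M):
            if mt_alive[m] == 0:
                continue
            bidx = mt_body[m]
            f_body[bidx, 0] += f_vert[m, 0, 0]
            f_body[bidx, 1] += f_vert[m, 0, 1]
            nv = mt_nv[m]
            tx = verts[m, nv - 1, 0] - verts[m, nv - 2, 0]
            ty = verts[m, nv - 1, 1] - verts[m, nv - 2, 1]
            tn = np.sqrt(tx * tx + ty * ty)
            if tn > 1e-12:
                tx /= tn; ty /= tn
            else:
                tx = 1.0; ty = 0.0
            fa = -(f_vert[m, nv - 1, 0] * tx + f_vert[m, nv - 1, 1] * ty)
            mt_fant[m] = fa if fa > 0.0 else 0.0

        # ---------------- motion ----------------
        for i in range(nb):
            if body_mobile[i] == 0:
                continue  # anchored centrosome-like body
            g = body_drag[i]
            zx, zy = _norm2(seed, step, _P_BODY, i)
            sig = np.sqrt(2.0 * kT * dt / g)
            body_pos[i, 0] += f_body[i, 0] / g * dt + sig * zx
            body_pos[i, 1] += f_body[i, 1] / g * dt + sig * zy
        sig_v = np.sqrt(2.0 * kT * dt / gamma_v)
        for m in range(M):
            if mt_alive[m] == 0:
                continue
            nv = mt_nv[m]
            for i in range(1, nv):
                zx, zy = _norm2(seed, step, _P_VERT, m * VMAX + i)
                verts[m, i, 0] += f_vert[m, i, 0] / gamma_v * dt + sig_v * zx
                verts[m, i, 1] += f_vert[m, i, 1] / gamma_v * dt + sig_v * zy
        # minus-end pinning to the (possibly moved) anchor + inextensibility
        # projection outward from the anchored minus end
        for s_i in range(ns):
            m = site_mt[s_i]
            if m < 0:
                continue
            bidx = site_body[s_i]
            axp, ayp = _anchor_point(body_pos, body_rad, bidx, site_angle[s_i])
            verts[m, 0, 0] = axp
            verts[m, 0, 1] = ayp
            nv = mt_nv[m]
            for i in range(1, nv):
                target = l0 if i - 1 < nv - 2 else mt_last[m]
                dx = verts[m, i, 0] - verts[m, i - 1, 0]
                dy = verts[m, i, 1] - verts[m, i - 1, 1]
                d = np.sqrt(dx * dx + dy * dy)
                if d > 1e-12:
                    sc = target / d
                else:
                    dx = 1.0; dy = 0.0; sc = target
                verts[m, i, 0] = verts[m, i - 1, 0] + dx * sc
                verts[m, i, 1] = verts[m, i - 1, 1] + dy * sc

        # unbound cytoplasmic connectors diffuse, confined to the ellipse
        for c in range(C):
            if con_anchor_body[c] >= 0:
                continue
            if con_state[c, 0] == 0 and con_state[c, 1] == 0:
                zx, zy = _norm2(seed, step, _P_DIFF, c)
                px = con_pos[c, 0] + sig_diff * zx
                py = con_pos[c, 1] + sig_diff * zy
                if (px / a) ** 2 + (py / b) ** 2 > 1.0:
                    px, py = nearest_on_ellipse(a, b, px, py)
                con_pos[c, 0] = px
                con_pos[c, 1] = py

        # ---------------- MT dynamic instability ----------------
        for m in range(M):
            if mt_alive[m] == 0:
                continue
            nv = mt_nv[m]
            if mt_growing[m] == 1:
                v = growth_speed_formula(P[VGROW0], mt_fant[m], P[FG],
                                         pool[0], P[LMAX])
                if nv >= VMAX:
                    v = 0.0
                dL = v * dt
                if dL > 0.0:
                    tx = verts[m, nv - 1, 0] - verts[m, nv - 2, 0]
                    ty = verts[m, nv - 1, 1] - verts[m, nv - 2, 1]
                    tn = np.sqrt(tx * tx + ty * ty)
                    if tn > 1e-12:
                        tx /= tn; ty /= tn
                    else:
                        tx = 1.0; ty = 0.0
                    verts[m, nv - 1, 0] += tx * dL
                    verts[m, nv - 1, 1] += ty * dL
                    mt_last[m] += dL
                    pool[0] += dL
                    if mt_last[m] > l0 and nv < VMAX:
                        # split the over-long terminal segment
                        excess = mt_last[m] - l0
                        tipx = verts[m, nv - 1, 0]
                        tipy = verts[m, nv - 1, 1]
                        verts[m, nv - 1, 0] = tipx - tx * excess
                        verts[m, nv - 1, 1] = tipy - ty * excess
                        verts[m, nv, 0] = tipx
                        verts[m, nv, 1] = tipy
                        mt_nv[m] = nv + 1
                        mt_last[m] = excess
                rate = catastrophe_rate_formula(v, P[VGROW0], P[CAT_TF], P[CAT_TS])
                if _u01(seed, step, _P_CAT, m, 0) < 1.0 - np.exp(-rate * dt):
                    mt_growing[m] = 0
                    ev[EV_CATASTROPHE] += 1
            else:
                dL = P[VSHRINK] * dt
                length = _mt_length(nv, mt_last[m], l0)
                if dL >= length:
                    # fully depolymerized: credit the pool; its site is freed
                    # in the sweep just below
                    pool[0] -= length
                    mt_alive[m] = 0
                    ev[EV_REMOVAL] += 1
                else:
                    pool[0] -= dL
                    rem = dL
                    while rem > 0.0 and mt_nv[m] >= 2:
                        if mt_last[m] > rem:
                            # shorten within the terminal segment
                            nv2 = mt_nv[m]
                            tx = verts[m, nv2 - 1, 0] - verts[m, nv2 - 2, 0]
                            ty = verts[m, nv2 - 1, 1] - verts[m, nv2 - 2, 1]
                            tn = np.sqrt(tx * tx + ty * ty)
                            if tn > 1e-12:
                                tx /= tn; ty /= tn
                            else:
                                tx = 1.0; ty = 0.0
                            verts[m, nv2 - 1, 0] -= tx * rem
                            verts[m, nv2 - 1, 1] -= ty * rem
                            mt_last[m] -= rem
                            rem = 0.0
                        else:
                            rem -= mt_last[m]
                            mt_nv[m] -= 1
                            mt_last[m] = l0
                    if mt_nv[m] < 2:
                        mt_alive[m] = 0
                        ev[EV_REMOVAL] += 1

        # free sites whose MT disappeared this step
        for s_i in range(ns):
            m = site_mt[s_i]
            if m >= 0 and mt_alive[m] == 0:
                site_mt[s_i] = -1

        # ---------------- connector kinetics ----------------
        for c in range(C):
            sp = con_sp[c]
            ab = con_anchor_body[c]
            for h in range(2):
                kind = head_kind[sp, h]
                if kind == HEAD_ANCHOR:
                    continue
                if con_state[c, h] == 1:
                    m = con_mt[c, h]
                    if mt_alive[m] == 0:
                        con_state[c, h] = 0
                        con_mt[c, h] = -1
                        continue
                    length = _mt_length(mt_nv[m], mt_last[m], l0)
                    if con_abs[c, h] > length:
                        # overtaken by a shrinking plus end: release rather
                        # than reel in (no depolymerization-coupled pulling)
                        con_state[c, h] = 0
                        con_mt[c, h] = -1
                        ev[EV_DETACH] += 1
                        continue
                    # spring force on this head (needs the partner's point)
                    s = con_abs[c, h]
                    hx, hy, ux, uy, _, _ = _point_on_mt(
                        verts, m, mt_nv[m], mt_last[m], l0, s)
                    oh = 1 - h
                    loc = False
                    ox = 0.0; oy = 0.0
                    if ab >= 0 and oh == 0:
                        ox, oy = _anchor_point(body_pos, body_rad, ab,
                                               con_anchor_angle[c])
                        loc = True
                    elif con_state[c, oh] == 1:
                        mo = con_mt[c, oh]
                        ox, oy, _, _, _, _ = _point_on_mt(
                            verts, mo, mt_nv[mo], mt_last[mo], l0,
                            con_abs[c, oh])
                        loc = True
                    if loc:
                        k = sp_springk[sp]
                        fhx = k * (ox - hx)
                        fhy = k * (oy - hy)
                        f_mag = np.sqrt(fhx * fhx + fhy * fhy)
                    else:
                        fhx = 0.0; fhy = 0.0; f_mag = 0.0
                    # first-order unbinding, load-amplified (Kramers)
                    if sp_fdetach[sp] < 1e30 and f_mag > 0.0:
                        x = f_mag / sp_fdetach[sp]
                        if x > 20.0:
                            x = 20.0
                        p_det = 1.0 - np.exp(-sp_koff[sp] * np.exp(x) * dt)
                    else:
                        p_det = p_off[sp]
                    if _u01(seed, step, _P_DETACH, c * 2 + h, 0) < p_det:
                        con_state[c, h] = 0
                        con_mt[c, h] = -1
                        ev[EV_DETACH] += 1
                        continue
                    if kind == HEAD_MOTOR:
                        d = sp_dir[sp]
                        f_par = fhx * ux * d + fhy * uy * d
                        f_opp = -f_par if f_par < 0.0 else 0.0
                        v = motor_speed_formula(sp_v0[sp], f_opp, sp_fstall[sp])
                        s = s + d * v * dt
                        if s < 0.0:
                            s = 0.0   # dynein dwells at the minus end
                        elif s > length:
                            s = length  # kinesin dwells at the plus end
                        con_abs[c, h] = s
                else:
                    # free head: first-order binding attempt
                    if _u01(seed, step, _P_ATTACH, c * 2 + h, 0) >= p_on[sp]:
                        continue
                    if ab >= 0:
                        qx, qy = _anchor_point(body_pos, body_rad, ab,
                                               con_anchor_angle[c])
                        excl = -1
                        exbody = ab
                    else:
                        oh = 1 - h
                        exbody = -1
                        if con_state[c, oh] == 1:
                            mo = con_mt[c, oh]
                            qx, qy, _, _, _, _ = _point_on_mt(
                                verts, mo, mt_nv[mo], mt_last[mo], l0,
                                con_abs[c, oh])
                            excl = mo
                        else:
                            qx = con_pos[c, 0]
                            qy = con_pos[c, 1]
                            excl = -1
                    mfound, sfound, ok = _find_binding(
                        qx, qy, sp_capr[sp], excl, exbody, mt_body,
                        mt_alive, mt_nv, mt_last, verts, bbox, l0)
                    if ok:
                        con_state[c, h] = 1
                        con_mt[c, h] = mfound
                        con_abs[c, h] = sfound
                        ev[EV_ATTACH] += 1
            # a singly-bound cytoplasmic complex rides at its bound head
            if ab < 0:
                if con_state[c, 0] == 1 or con_state[c, 1] == 1:
                    h = 0 if con_state[c, 0] == 1 else 1
                    m = con_mt[c, h]
                    px, py, _, _, _, _ = _point_on_mt(
                        verts, m, mt_nv[m], mt_last[m], l0, con_abs[c, h])
                    con_pos[c, 0] = px
                    con_pos[c, 1] = py

        # ---------------- nucleation ----------------
        for s_i in range(ns):
            if site_active[s_i] == 0 or site_mt[s_i] >= 0:
                continue
            if pool[0] + P[EPS_NUC] > P[LMAX]:
                continue
            if _u01(seed, step, _P_NUC, s_i, 0) >= p_nuc:
                continue
            m = s_i  # one MT slot per site
            dirx = 1.0 if _u01(seed, step, _P_NUCDIR, s_i, 0) < 0.5 else -1.0
            bidx = site_body[s_i]
            axp, ayp = _anchor_point(body_pos, body_rad, bidx, site_angle[s_i])
            mt_alive[m] = 1
            mt_growing[m] = 1
            mt_nv[m] = 2
            mt_last[m] = P[EPS_NUC]
            mt_body[m] = bidx
            verts[m, 0, 0] = axp
            verts[m, 0, 1] = ayp
            verts[m, 1, 0] = axp + dirx * P[EPS_NUC]
            verts[m, 1, 1] = ayp
            site_mt[s_i] = m
            pool[0] += P[EPS_NUC]
            ev[EV_NUCLEATION] += 1
            if ev[EV_FIRST_NUC_STEP] < 0:
                ev[EV_FIRST_NUC_STEP] = step

        # ---------------- frame recording ----------------
        if (step + 1) % stride == 0 or step == n_steps - 1:
            if fidx < fr_body.shape[0]:
                for i in range(nb):
                    fr_body[fidx, i, 0] = body_pos[i, 0]
                    fr_body[fidx, i, 1] = body_pos[i, 1]
                total = 0.0
                nmts = 0
                for m in range(M):
                    if mt_alive[m] == 1:
                        total += _mt_length(mt_nv[m], mt_last[m], l0)
                        nmts += 1
                fr_poly[fidx] = pool[0]
                fr_sumlen[fidx] = total
                fr_nmts[fidx] = nmts
                fr_maxpen[fidx] = maxpen
                fidx += 1
    return fidx
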