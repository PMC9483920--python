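"""Numba kernels for the grand-canonical Monte Carlo engine.

All kernels work in reduced units (sigma = epsilon = 1) on preallocated
arrays.  Particles live either in a hard-walled spherical shell centered at
the origin or in a periodic cubic box [0, L)^3.  A linked-cell list with
cubic cells of edge >= kappa accelerates the local energy evaluation; when
the domain is too small for three cells per side the single-cell (brute
force) path is used.

Randomness comes from numba's internal per-thread generator, seeded once per
run through :func:`seed_rng`, which makes every trajectory bit-reproducible
for a given seed.
"""

import numpy as np
from numba import njit

#: Energy treated as infinite (hard-core overlap / wall violation).
E_INF = 1.0e12


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _clamp(i, n):
    if i < 0:
        return 0
    if i >= n:
        return n - 1
    return i


@njit(cache=True, inline="always")
def _cell_index(x, y, z, lo, inv_edge, nc):
    ix = _clamp(int((x - lo) * inv_edge), nc)
    iy = _clamp(int((y - lo) * inv_edge), nc)
    iz = _clamp(int((z - lo) * inv_edge), nc)
    return (ix * nc + iy) * nc + iz


@njit(cache=True)
def build_cells(pos, n, head, nxt, cell_of, lo, inv_edge, nc):
    head[:] = -1
    for i in range(n):
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], lo, inv_edge, nc)
        nxt[i] = head[c]
        head[c] = i
        cell_of[i] = c


@njit(cache=True, inline="always")
def _cell_insert(i, c, head, nxt, cell_of):
    nxt[i] = head[c]
    head[c] = i
    cell_of[i] = c


@njit(cache=True)
def _cell_remove(i, head, nxt, cell_of):
    c = cell_of[i]
    j = head[c]
    if j == i:
        head[c] = nxt[i]
    else:
        while nxt[j] != i:
            j = nxt[j]
        nxt[j] = nxt[i]


@njit(cache=True, inline="always")
def _pair_energy(d2, zeta, lam2, kap, kap2):
    if d2 < 1.0:
        return E_INF
    if d2 < lam2:
        return -1.0
    if d2 < kap2:
        return zeta * (kap - np.sqrt(d2))
    return 0.0


@njit(cache=True)
def local_energy(
    px, py, pz, skip, pos, head, nxt, lo, inv_edge, nc, periodic, box_l,
    zeta, lam2, kap, kap2,
):
    """Interaction energy of a (trial) particle at (px,py,pz) with all
    others, excluding index ``skip`` (-1 to exclude nobody).  Returns E_INF
    as soon as a hard-core overlap is found."""
    e = 0.0
    ix = _clamp(int((px - lo) * inv_edge), nc)
    iy = _clamp(int((py - lo) * inv_edge), nc)
    iz = _clamp(int((pz - lo) * inv_edge), nc)
    half = 0 if nc == 1 else 1
    for dx in range(-half, half + 1):
        cx = ix + dx
        if periodic:
            cx %= nc
        elif cx < 0 or cx >= nc:
            continue
        for dy in range(-half, half + 1):
            cy = iy + dy
            if periodic:
                cy %= nc
            elif cy < 0 or cy >= nc:
                continue
            for dz in range(-half, half + 1):
                cz = iz + dz
                if periodic:
                    cz %= nc
                elif cz < 0 or cz >= nc:
                    continue
                j = head[(cx * nc + cy) * nc + cz]
                while j != -1:
                    if j != skip:
                        ddx = pos[j, 0] - px
                        ddy = pos[j, 1] - py
                        ddz = pos[j, 2] - pz
                        if periodic:
                            ddx -= box_l * np.rint(ddx / box_l)
                            ddy -= box_l * np.rint(ddy / box_l)
                            ddz -= box_l * np.rint(ddz / box_l)
                        d2 = ddx * ddx + ddy * ddy + ddz * ddz
                        if d2 < kap2:
                            ep = _pair_energy(d2, zeta, lam2, kap, kap2)
                            if ep >= E_INF:
                                return E_INF
                            e += ep
                    j = nxt[j]
    return e


@njit(cache=True)
def run_steps(
    pos, head, nxt, cell_of, n_in, u_in,
    n_steps, p_disp, delta, beta, z_vol,
    r_inn, r_out, box_l, lo, inv_edge, nc, periodic, interacting,
    zeta, lam2, kap, kap2,
):
    """Run ``n_steps`` trial moves of grand-canonical Metropolis MC.

    One step is one trial move: displacement with probability ``p_disp``,
    otherwise insertion or deletion with equal probability.  ``z_vol`` is
    the activity times the configurational volume (geometric shell volume or
    box volume), matching the uniform position proposal.  Returns the new
    particle count, running energy, per-step average of N, and the
    attempted/accepted counters of each move type.
    """
    n = n_in
    u = u_in
    sum_n = 0.0
    att_d = acc_d = att_i = acc_i = att_x = acc_x = 0
    r_inn2 = r_inn * r_inn
    r_out2 = r_out * r_out
    r_inn3 = r_inn * r_inn * r_inn
    r_out3 = r_out * r_out * r_out
    cap = pos.shape[0]
    p_half_exch = p_disp + 0.5 * (1.0 - p_disp)

    for _ in range(n_steps):
        w = np.random.random()
        if w < p_disp:
            # ---- displacement ----
            att_d += 1
            if n > 0:
                i = int(np.random.random() * n)
                if i >= n:
                    i = n - 1
                ox = pos[i, 0]
                oy = pos[i, 1]
                oz = pos[i, 2]
                px = ox + (np.random.random() - 0.5) * 2.0 * delta
                py = oy + (np.random.random() - 0.5) * 2.0 * delta
                pz = oz + (np.random.random() - 0.5) * 2.0 * delta
                ok = True
                if periodic:
                    px -= box_l * np.floor(px / box_l)
                    py -= box_l * np.floor(py / box_l)
                    pz -= box_l * np.floor(pz / box_l)
                else:
                    r2 = px * px + py * py + pz * pz
                    if r2 < r_inn2 or r2 > r_out2:
                        ok = False
                if ok:
                    du = 0.0
                    if interacting:
                        e_new = local_energy(
                            px, py, pz, i, pos, head, nxt, lo, inv_edge, nc,
                            periodic, box_l, zeta, lam2, kap, kap2,
                        )
                        if e_new >= E_INF:
                            ok = False
                        else:
                            e_old = local_energy(
                                ox, oy, oz, i, pos, head, nxt, lo, inv_edge,
                                nc, periodic, box_l, zeta, lam2, kap, kap2,
                            )
                            du = e_new - e_old
                    if ok and du > 0.0:
                        if np.random.random() >= np.exp(-beta * du):
                            ok = False
                    if ok:
                        _cell_remove(i, head, nxt, cell_of)
                        pos[i, 0] = px
                        pos[i, 1] = py
                        pos[i, 2] = pz
                        c = _cell_index(px, py, pz, lo, inv_edge, nc)
                        _cell_insert(i, c, head, nxt, cell_of)
                        u += du
                        acc_d += 1
        elif w < p_half_exch:
            # ---- insertion ----
            att_i += 1
            if n < cap:
                if periodic:
                    px = np.random.random() * box_l
                    py = np.random.random() * box_l
                    pz = np.random.random() * box_l
                else:
                    r3 = r_inn3 + np.random.random() * (r_out3 - r_inn3)
                    r = r3 ** (1.0 / 3.0)
                    gx = np.random.normal(0.0, 1.0)
                    gy = np.random.normal(0.0, 1.0)
                    gz = np.random.normal(0.0, 1.0)
                    norm = np.sqrt(gx * gx + gy * gy + gz * gz)
                    while norm < 1e-12:
                        gx = np.random.normal(0.0, 1.0)
                        gy = np.random.normal(0.0, 1.0)
                        gz = np.random.normal(0.0, 1.0)
                        norm = np.sqrt(gx * gx + gy * gy + gz * gz)
                    px = r * gx / norm
                    py = r * gy / norm
                    pz = r * gz / norm
                e = 0.0
                if interacting:
                    e = local_energy(
                        px, py, pz, -1, pos, head, nxt, lo, inv_edge, nc,
                        periodic, box_l, zeta, lam2, kap, kap2,
                    )
                if e < E_INF:
                    acc = z_vol / (n + 1.0) * np.exp(-beta * e)
                    if acc >= 1.0 or np.random.random() < acc:
                        pos[n, 0] = px
                        pos[n, 1] = py
                        pos[n, 2] = pz
                        c = _cell_index(px, py, pz, lo, inv_edge, nc)
                        _cell_insert(n, c, head, nxt, cell_of)
                        n += 1
                        u += e
                        acc_i += 1
        else:
            # ---- deletion ----
            att_x += 1
            if n > 0:
                i = int(np.random.random() * n)
                if i >= n:
                    i = n - 1
                e = 0.0
                if interacting:
                    e = local_energy(
                        pos[i, 0], pos[i, 1], pos[i, 2], i, pos, head, nxt,
                        lo, inv_edge, nc, periodic, box_l, zeta, lam2, kap,
                        kap2,
                    )
                # removing the particle changes the energy by -e
                acc = n / z_vol * np.exp(beta * e)
                if acc >= 1.0 or np.random.random() < acc:
                    _cell_remove(i, head, nxt, cell_of)
                    last = n - 1
                    if i != last:
                        _cell_remove(last, head, nxt, cell_of)
                        pos[i, 0] = pos[last, 0]
                        pos[i, 1] = pos[last, 1]
                        pos[i, 2] = pos[last, 2]
                        _cell_insert(i, cell_of[last], head, nxt, cell_of)
                    n = last
                    u -= e
                    acc_x += 1
        sum_n += n
    return n, u, sum_n, att_d, acc_d, att_i, acc_i, att_x, acc_x
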