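"""Numba kernels: cell-list neighbor search, forces, Langevin integration
and the dynamic-bond sweep.

Performance notes
-----------------
* Verlet pair list built from a cell grid with list cutoff
  max(pair cutoffs) + skin, rebuilt when any bead has moved more than
  skin/2 since the last build (this guarantees no pair can enter a cutoff
  unseen).
* Chain-bonded (i, i+1) pairs are excluded at build time.  Dynamically
  bonded pairs are NOT excluded at build time (bonds change between
  rebuilds); instead the Lennard-Jones term of a bonded pair is subtracted
  in the dynamic-bond loop, which is algebraically identical to a 1-2
  exclusion.
* Pair forces are capped below r = 0.5 a (the separation is clamped in the
  force law) and the event counted; valid initial configurations never
  trigger this.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OUTSIDE = 1
STATUS_UNSTABLE = 2
STATUS_OVERFLOW = 3

_R2_CAP = 0.25  # (0.5 a)^2 singularity guard


# ---------------------------------------------------------------------------
# neighbor list


@njit(cache=True)
def build_pairs(
    pos,
    types,
    n_chain,
    r_list2,
    box_R,
    ncell,
    eps_tab,
    cut2_tab,
    pair_i,
    pair_j,
    pair_eps4,
    pair_cut2,
    ap_i,
    ap_j,
):
    """Fill the Verlet pair list; returns (n_pairs, n_ap) or (-1, -1) on
    capacity overflow.  A-P pairs are additionally collected into a
    separate candidate list for the bond sweep."""
    N = pos.shape[0]
    inv_cell = ncell / (2.0 * box_R)
    ncells = ncell * ncell * ncell

    cid = np.empty(N, np.int32)
    for i in range(N):
        cx = int((pos[i, 0] + box_R) * inv_cell)
        cy = int((pos[i, 1] + box_R) * inv_cell)
        cz = int((pos[i, 2] + box_R) * inv_cell)
        if cx < 0:
            cx = 0
        elif cx >= ncell:
            cx = ncell - 1
        if cy < 0:
            cy = 0
        elif cy >= ncell:
            cy = ncell - 1
        if cz < 0:
            cz = 0
        elif cz >= ncell:
            cz = ncell - 1
        cid[i] = (cx * ncell + cy) * ncell + cz

    start = np.zeros(ncells + 1, np.int32)
    for i in range(N):
        start[cid[i] + 1] += 1
    for c in range(ncells):
        start[c + 1] += start[c]
    order = np.empty(N, np.int32)
    fill = start[:-1].copy()
    for i in range(N):
        order[fill[cid[i]]] = i
        fill[cid[i]] += 1

    cap = pair_i.shape[0]
    ap_cap = ap_i.shape[0]
    npair = 0
    nap = 0
    for i in range(N):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        ti = types[i]
        ci = cid[i]
        cz0 = ci % ncell
        cy0 = (ci // ncell) % ncell
        cx0 = ci // (ncell * ncell)
        for dx in range(-1, 2):
            cx = cx0 + dx
            if cx < 0 or cx >= ncell:
                continue
            for dy in range(-1, 2):
                cy = cy0 + dy
                if cy < 0 or cy >= ncell:
                    continue
                for dz in range(-1, 2):
                    cz = cz0 + dz
                    if cz < 0 or cz >= ncell:
                        continue
                    c = (cx * ncell + cy) * ncell + cz
                    for k in range(start[c], start[c + 1]):
                        j = order[k]
                        if j <= i:
                            continue
                        ddx = xi - pos[j, 0]
                        ddy = yi - pos[j, 1]
                        ddz = zi - pos[j, 2]
                        r2 = ddx * ddx + ddy * ddy + ddz * ddz
                        if r2 > r_list2:
                            continue
                        if j - i == 1 and j < n_chain:
                            continue  # chain bond: 1-2 exclusion
                        tj = types[j]
                        if npair >= cap:
                            return -1, -1
                        pair_i[npair] = i
                        pair_j[npair] = j
                        pair_eps4[npair] = 4.0 * eps_tab[ti, tj]
                        pair_cut2[npair] = cut2_tab[ti, tj]
                        npair += 1
                        if ti + tj == 2 and ti * tj == 0:  # A(0)-P(2) pair
                            if nap >= ap_cap:
                                return -1, -1
                            if ti == 0:
                                ap_i[nap] = i
                                ap_j[nap] = j
                            else:
                                ap_i[nap] = j
                                ap_j[nap] = i
                            nap += 1
    return npair, nap


# ---------------------------------------------------------------------------
# forces


@njit(cache=True, fastmath=True)
def compute_forces(
    pos,
    f,
    partner,
    n_chain,
    pair_i,
    pair_j,
    pair_eps4,
    pair_cut2,
    n_pairs,
    eps_tab,
    cut2_tab,
    types,
    k_spring,
    K,
    r0,
    r_break2,
    R_c,
    eps_confine,
    counters,
):
    """Accumulate all forces into f.  Returns a status code.

    counters[0] accumulates singularity-guard (capped-force) events.
    """
    N = pos.shape[0]
    for i in range(N):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    # non-bonded pairs (full list; bonded-pair LJ subtracted below).
    # The list is ordered by i, so accumulate bead i locally per group.
    ii = -1
    xi = yi = zi = fx = fy = fz = 0.0
    for p in range(n_pairs):
        i = pair_i[p]
        if i != ii:
            if ii >= 0:
                f[ii, 0] += fx
                f[ii, 1] += fy
                f[ii, 2] += fz
            ii = i
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            fx = fy = fz = 0.0
        j = pair_j[p]
        dx = xi - pos[j, 0]
        dy = yi - pos[j, 1]
        dz = zi - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < pair_cut2[p]:
            if r2 < _R2_CAP:
                r2 = _R2_CAP
                if partner[i] != j:
                    # bonded pairs are LJ-excluded anyway (their capped
                    # term cancels exactly below); only a genuine
                    # non-bonded overlap is worth flagging
                    counters[0] += 1
            ir2 = 1.0 / r2
            ir6 = ir2 * ir2 * ir2
            # F/r = 6*eps4*(2 r^-12 - r^-6)/r^2, repulsive positive
            coef = 6.0 * pair_eps4[p] * (2.0 * ir6 * ir6 - ir6) * ir2
            fx += coef * dx
            fy += coef * dy
            fz += coef * dz
            f[j, 0] -= coef * dx
            f[j, 1] -= coef * dy
            f[j, 2] -= coef * dz
    if ii >= 0:
        f[ii, 0] += fx
        f[ii, 1] += fy
        f[ii, 2] += fz

    # chain springs
    for i in range(n_chain - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        coef = -2.0 * k_spring * (r - 1.0) / r
        f[i, 0] += coef * dx
        f[i, 1] += coef * dy
        f[i, 2] += coef * dz
        f[i + 1, 0] -= coef * dx
        f[i + 1, 1] -= coef * dy
        f[i + 1, 2] -= coef * dz

    # dynamic bonds: harmonic force plus removal of the pair's LJ term
    for i in range(N):
        j = partner[i]
        if j > i:
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < r_break2:
                r = np.sqrt(r2)
                coef = -2.0 * K * (r - r0) / r
                # subtract the LJ force this pair received in the pair loop
                cut2 = cut2_tab[types[i], types[j]]
                if r2 < cut2:
                    r2c = r2
                    if r2c < _R2_CAP:
                        r2c = _R2_CAP
                    ir2 = 1.0 / r2c
                    ir6 = ir2 * ir2 * ir2
                    eps4 = 4.0 * eps_tab[types[i], types[j]]
                    coef -= 6.0 * eps4 * (2.0 * ir6 * ir6 - ir6) * ir2
                f[i, 0] += coef * dx
                f[i, 1] += coef * dy
                f[i, 2] += coef * dz
                f[j, 0] -= coef * dx
                f[j, 1] -= coef * dy
                f[j, 2] -= coef * dz

    # spherical confinement
    wca2 = 2.0 ** (1.0 / 3.0)
    for i in range(N):
        r2 = pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2
        r = np.sqrt(r2)
        gap = R_c - r
        if gap <= 0.0:
            return STATUS_OUTSIDE
        if gap * gap < wca2 and r > 0.0:
            ig = 1.0 / gap
            ig6 = ig * ig * ig
            ig6 = ig6 * ig6
            # dU/dgap < 0 inside the repulsive zone; force points inward
            dudg = 4.0 * eps_confine * (-12.0 * ig6 * ig6 + 6.0 * ig6) * ig
            coef = dudg / r
            f[i, 0] += coef * pos[i, 0]
            f[i, 1] += coef * pos[i, 1]
            f[i, 2] += coef * pos[i, 2]
    return STATUS_OK


# ---------------------------------------------------------------------------
# energies


@njit(cache=True)
def energy_report(
    pos,
    partner,
    n_chain,
    pair_i,
    pair_j,
    pair_eps4,
    pair_cut2,
    n_pairs,
    eps_tab,
    cut2_tab,
    types,
    k_spring,
    K,
    r0,
    r_break2,
    R_c,
    eps_confine,
):
    """(U_stretch, U_LJ, U_confine, U_bond) from the current pair list."""
    u_lj = 0.0
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < pair_cut2[p]:
            if r2 < _R2_CAP:
                r2 = _R2_CAP
            ir6 = 1.0 / (r2 * r2 * r2)
            u_lj += pair_eps4[p] * (ir6 * ir6 - ir6)

    u_spring = 0.0
    for i in range(n_chain - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u_spring += k_spring * (r - 1.0) ** 2

    u_bond = 0.0
    N = pos.shape[0]
    for i in range(N):
        j = partner[i]
        if j > i:
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < r_break2:
                r = np.sqrt(r2)
                u_bond += K * (r - r0) ** 2
                # active bond: remove this pair's LJ term (1-2 exclusion)
                cut2 = cut2_tab[types[i], types[j]]
                if r2 < cut2:
                    if r2 < _R2_CAP:
                        r2 = _R2_CAP
                    ir6 = 1.0 / (r2 * r2 * r2)
                    u_lj -= 4.0 * eps_tab[types[i], types[j]] * (
                        ir6 * ir6 - ir6
                    )

    u_conf = 0.0
    wca = 2.0 ** (1.0 / 6.0)
    for i in range(N):
        r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        gap = R_c - r
        if gap < wca:
            ig6 = (1.0 / gap) ** 6
            u_conf += 4.0 * eps_confine * (ig6 * ig6 - ig6)
    return u_spring, u_lj, u_conf, u_bond


# ---------------------------------------------------------------------------
# dynamic bonds


@njit(cache=True)
def bond_sweep(pos, partner, ap_i, ap_j, n_ap, r_bond2, r_break2):
    """One bond update: break over-stretched bonds, then form new ones.

    Formation: all unbonded A-P candidate pairs within r_bond are bonded
    greedily, nearest pair first, ties broken by (chromatin index, protein
    index) — deterministic.  Returns the number of changes.
    """
    changed = 0
    N = pos.shape[0]
    for i in range(N):
        j = partner[i]
        if j > i:
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > r_break2:
                partner[i] = -1
                partner[j] = -1
                changed += 1

    # collect free candidate pairs within the capture radius
    nc = 0
    cd = np.empty(n_ap, np.float64)
    ca = np.empty(n_ap, np.int32)
    cp = np.empty(n_ap, np.int32)
    for k in range(n_ap):
        a = ap_i[k]
        p = ap_j[k]
        if partner[a] >= 0 or partner[p] >= 0:
            continue
        dx = pos[a, 0] - pos[p, 0]
        dy = pos[a, 1] - pos[p, 1]
        dz = pos[a, 2] - pos[p, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= r_bond2:
            cd[nc] = r2
            ca[nc] = a
            cp[nc] = p
            nc += 1

    # insertion sort by (distance, chromatin index, protein index)
    for k in range(1, nc):
        d = cd[k]
        a = ca[k]
        p = cp[k]
        m = k - 1
        while m >= 0 and (
            cd[m] > d or (cd[m] == d and (ca[m] > a or (ca[m] == a and cp[m] > p)))
        ):
            cd[m + 1] = cd[m]
            ca[m + 1] = ca[m]
            cp[m + 1] = cp[m]
            m -= 1
        cd[m + 1] = d
        ca[m + 1] = a
        cp[m + 1] = p

    for k in range(nc):
        a = ca[k]
        p = cp[k]
        if partner[a] < 0 and partner[p] < 0:
            partner[a] = p
            partner[p] = a
            changed += 1
    return changed


# ---------------------------------------------------------------------------
# integration


@njit(cache=True, fastmath=True)
def advance_segment(
    pos,
    vel,
    f,
    types,
    partner,
    n_chain,
    eps_tab,
    cut2_tab,
    k_spring,
    K,
    r0,
    r_break2,
    R_c,
    eps_confine,
    dt,
    c1,
    c2,
    normals,
    pair_i,
    pair_j,
    pair_eps4,
    pair_cut2,
    ap_i,
    ap_j,
    meta,
    pos_ref,
    r_list2,
    box_R,
    ncell,
    skin,
):
    """Advance ``normals.shape[0]`` BAOAB Langevin steps.

    meta: int64[4] = (n_pairs, n_ap, n_capped, error_bead) carried across
    calls; pos_ref holds positions at the last neighbor-list build.  The
    list is rebuilt when the two largest bead displacements since the
    build sum to more than the skin (no pair can then have closed an
    unseen gap).  Forces in ``f`` must be valid on entry and on exit.
    """
    n_steps = normals.shape[0]
    N = pos.shape[0]
    half_dt = 0.5 * dt
    max_step2 = 0.25  # instability guard: (0.5 a)^2 per step
    counters = np.zeros(1, np.int64)

    for s in range(n_steps):
        unstable = False
        m1 = 0.0  # largest squared displacement since build
        m2 = 0.0  # second largest
        for i in range(N):
            vx = vel[i, 0] + half_dt * f[i, 0]
            vy = vel[i, 1] + half_dt * f[i, 1]
            vz = vel[i, 2] + half_dt * f[i, 2]
            x0 = pos[i, 0]
            y0 = pos[i, 1]
            z0 = pos[i, 2]
            x = x0 + half_dt * vx
            y = y0 + half_dt * vy
            z = z0 + half_dt * vz
            vx = c1 * vx + c2 * normals[s, i, 0]
            vy = c1 * vy + c2 * normals[s, i, 1]
            vz = c1 * vz + c2 * normals[s, i, 2]
            x += half_dt * vx
            y += half_dt * vy
            z += half_dt * vz
            dx = x - x0
            dy = y - y0
            dz = z - z0
            if dx * dx + dy * dy + dz * dz > max_step2:
                unstable = True
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
            rx = x - pos_ref[i, 0]
            ry = y - pos_ref[i, 1]
            rz = z - pos_ref[i, 2]
            d2 = rx * rx + ry * ry + rz * rz
            if d2 > m1:
                m2 = m1
                m1 = d2
            elif d2 > m2:
                m2 = d2
        if unstable:
            meta[3] = s
            return STATUS_UNSTABLE
        if np.sqrt(m1) + np.sqrt(m2) > skin:
            npair, nap = build_pairs(
                pos,
                types,
                n_chain,
                r_list2,
                box_R,
                ncell,
                eps_tab,
                cut2_tab,
                pair_i,
                pair_j,
                pair_eps4,
                pair_cut2,
                ap_i,
                ap_j,
            )
            if npair < 0:
                return STATUS_OVERFLOW
            meta[0] = npair
            meta[1] = nap
            for i in range(N):
                pos_ref[i, 0] = pos[i, 0]
                pos_ref[i, 1] = pos[i, 1]
                pos_ref[i, 2] = pos[i, 2]
        status = compute_forces(
            pos,
            f,
            partner,
            n_chain,
            pair_i,
            pair_j,
            pair_eps4,
            pair_cut2,
            meta[0],
            eps_tab,
            cut2_tab,
            types,
            k_spring,
            K,
            r0,
            r_break2,
            R_c,
            eps_confine,
            counters,
        )
        if status != STATUS_OK:
            meta[3] = s
            return status
        for i in range(N):
            vel[i, 0] += half_dt * f[i, 0]
            vel[i, 1] += half_dt * f[i, 1]
            vel[i, 2] += half_dt * f[i, 2]
    meta[2] += counters[0]
    return STATUS_OK
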