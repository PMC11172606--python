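"""Numba kernels: pair potentials, bonded terms, Verlet-list construction
and the BAOAB Langevin inner loop.

Everything here is single-threaded with a fixed summation order (pairs
iterate lexicographically) so that trajectories are bit-reproducible and a
Verlet-list run is bit-identical to a brute-force-neighbor run: pairs
between the interaction cutoff and the list cutoff contribute exact zeros.

Units: A, ps, amu, kcal/mol. 1 kcal/mol = 418.4 amu A^2/ps^2.
"""

import math

import numpy as np
from numba import njit

F_CONV = 418.4  # kcal/mol -> amu A^2/ps^2
KB = 0.0019872041  # kcal/mol/K


@njit(cache=True)
def _minimg(d, L):
    return d - L * np.floor(d / L + 0.5)


@njit(cache=True)
def _switch(r, rc, w):
    """C1 smoothstep from 1 at rc-w down to 0 at rc. Returns (S, dS/dr)."""
    if r >= rc:
        return 0.0, 0.0
    if r <= rc - w:
        return 1.0, 0.0
    t = (rc - r) / w
    return t * t * (3.0 - 2.0 * t), -(6.0 * t - 6.0 * t * t) / w


@njit(cache=True)
def _lj_pair(r, sig, epsv, rc, w):
    """Shifted-switched Lennard-Jones 12-6: zero energy and force at rc."""
    if r >= rc:
        return 0.0, 0.0
    q = sig / r
    sr2 = q * q
    sr6 = sr2 * sr2 * sr2
    sr12 = sr6 * sr6
    e = 4.0 * epsv * (sr12 - sr6)
    de = 4.0 * epsv * (-12.0 * sr12 + 6.0 * sr6) / r
    qc = sig / rc
    qc2 = qc * qc
    src6 = qc2 * qc2 * qc2
    shift = 4.0 * epsv * (src6 * src6 - src6)
    s, ds = _switch(r, rc, w)
    return (e - shift) * s, de * s + (e - shift) * ds


@njit(cache=True)
def _solv_pair(r, rcontact, dgsum, lam, rc, w):
    """Gaussian solvent-exclusion term. A neighbour at distance r buries a
    Gaussian-weighted fraction of the pair's solvation free energy; burial
    of hydrophilic particles (dG < 0) is penalised, of hydrophobic ones
    rewarded. Plateau inside the contact distance keeps the core repulsion
    purely Lennard-Jones."""
    if r >= rc:
        return 0.0, 0.0
    if r <= rcontact:
        g, dg_dr = 1.0, 0.0
    else:
        u = (r - rcontact) / lam
        g = np.exp(-u * u)
        dg_dr = -2.0 * u / lam * g
    s, ds = _switch(r, rc, w)
    a = -dgsum
    return a * g * s, a * (dg_dr * s + g * ds)


@njit(cache=True)
def _go_pair(r, r0, depth):
    """12-10 native-contact well, minimum -depth at r0."""
    q = r0 / r
    q2 = q * q
    q10 = q2 * q2 * q2 * q2 * q2
    q12 = q10 * q2
    e = depth * (5.0 * q12 - 6.0 * q10)
    de = depth * 60.0 * (q10 - q12) / r
    return e, de


@njit(cache=True)
def _hb_radial(r, r0, ss, cut):
    """10-12 hydrogen-bond well normalised to -1 at r0, switched off at
    ``cut``. Returns (u, du/dr)."""
    q = r0 / r
    q2 = q * q
    q10 = q2 * q2 * q2 * q2 * q2
    q12 = q10 * q2
    u = 5.0 * q12 - 6.0 * q10
    du = 60.0 * (q10 - q12) / r
    s, ds = _switch(r, cut, cut - ss)
    return u * s, du * s + u * ds



@njit(cache=True)
def _wrap_positions(pos, L, out):
    for i in range(pos.shape[0]):
        out[i, 0] = pos[i, 0] - L * np.floor(pos[i, 0] / L)
        out[i, 1] = pos[i, 1] - L * np.floor(pos[i, 1] / L)
        out[i, 2] = pos[i, 2] - L * np.floor(pos[i, 2] / L)


@njit(cache=True)
def _wd(d, L, hL):
    """Minimum image of a difference of wrapped coordinates (|d| < L)."""
    if d > hL:
        return d - L
    if d < -hL:
        return d + L
    return d

@njit(cache=True)
def _build_pairs(pos, L, cut, excl, resseq, mol,
                 wvs, wvl, wss, wsl, d_short, d_long, s14,
                 sigma, eps, dg, rc):
    """Lexicographic i<j Verlet list with per-pair sequence-separation
    interpolated weights. excl: 0 include, 1 exclude, 2 include at the 1-4
    scale factor."""
    n = pos.shape[0]
    cut2 = cut * cut
    hL = 0.5 * L
    pw = np.empty((n, 3))
    _wrap_positions(pos, L, pw)
    m = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, j] == 1:
                continue
            dx = _wd(pw[i, 0] - pw[j, 0], L, hL)
            dy = _wd(pw[i, 1] - pw[j, 1], L, hL)
            dz = _wd(pw[i, 2] - pw[j, 2], L, hL)
            if dx * dx + dy * dy + dz * dz < cut2:
                m += 1
    pairs = np.empty((m, 2), dtype=np.int32)
    pwv = np.empty(m)
    pws = np.empty(m)
    psc = np.empty(m)
    psig = np.empty(m)
    peps4 = np.empty(m)
    pdg = np.empty(m)
    pshift = np.empty(m)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, j] == 1:
                continue
            dx = _wd(pw[i, 0] - pw[j, 0], L, hL)
            dy = _wd(pw[i, 1] - pw[j, 1], L, hL)
            dz = _wd(pw[i, 2] - pw[j, 2], L, hL)
            if dx * dx + dy * dy + dz * dz >= cut2:
                continue
            pairs[k, 0] = i
            pairs[k, 1] = j
            if mol[i] != mol[j]:
                pwv[k] = wvl
                pws[k] = wsl
            else:
                d = abs(resseq[i] - resseq[j])
                if d <= d_short:
                    pwv[k] = wvs
                    pws[k] = wss
                elif d >= d_long:
                    pwv[k] = wvl
                    pws[k] = wsl
                else:
                    t = (d - d_short) / (d_long - d_short)
                    pwv[k] = wvs + t * (wvl - wvs)
                    pws[k] = wss + t * (wsl - wss)
            psc[k] = s14 if excl[i, j] == 2 else 1.0
            sig = 0.5 * (sigma[i] + sigma[j])
            epsij = np.sqrt(eps[i] * eps[j])
            psig[k] = sig
            peps4[k] = 4.0 * epsij
            pdg[k] = dg[i] + dg[j]
            qc = sig / rc
            qc2 = qc * qc
            src6 = qc2 * qc2 * qc2
            pshift[k] = 4.0 * epsij * (src6 * src6 - src6)
            k += 1
    return pairs, pwv, pws, psc, psig, peps4, pdg, pshift


@njit(cache=True)
def _forces(pos, L,
            pairs, pwv, pws, psc, psig, peps4, pdg, pshift,
            lam, rc, sw,
            bonds, bond_b0, kb,
            angles, ang_t0, ka,
            tors, tor_p0, kt,
            dN, dH, dres, dmol, aO, ares, amol,
            eps_hb, hb_r0, hb_ss, hb_cut,
            go_a, go_b, go_r0, go_w, eps_go,
            f):
    """Fill f with -grad E; return per-term energies and an error pair
    (err_i >= 0 flags overlapping particles)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_bond = 0.0
    e_vdw = 0.0
    e_solv = 0.0
    e_hb = 0.0
    e_go = 0.0
    hL = 0.5 * L
    inv_sw = 1.0 / sw
    inv_lam = 1.0 / lam
    pw = np.empty((n, 3))
    _wrap_positions(pos, L, pw)

    # nonbonded pairs
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _wd(pw[i, 0] - pw[j, 0], L, hL)
        dy = _wd(pw[i, 1] - pw[j, 1], L, hL)
        dz = _wd(pw[i, 2] - pw[j, 2], L, hL)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 0.01:
            return e_bond, e_vdw, e_solv, e_hb, e_go, i, j
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        sig = psig[p]
        # switch S(r) on [rc - sw, rc]
        if r <= rc - sw:
            swv = 1.0
            dsw = 0.0
        else:
            t = (rc - r) * inv_sw
            swv = t * t * (3.0 - 2.0 * t)
            dsw = -(6.0 * t - 6.0 * t * t) * inv_sw
        q = sig * inv_r
        sr2 = q * q
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        elj = peps4[p] * (sr12 - sr6) - pshift[p]
        delj = peps4[p] * (-12.0 * sr12 + 6.0 * sr6) * inv_r
        ev = elj * swv
        dev = delj * swv + elj * dsw
        if r <= sig:
            g = 1.0
            dgdr = 0.0
        else:
            u = (r - sig) * inv_lam
            g = math.exp(-u * u)
            dgdr = -2.0 * u * inv_lam * g
        a = -pdg[p]
        es = a * g * swv
        des = a * (dgdr * swv + g * dsw)
        sc = psc[p]
        e_vdw += sc * pwv[p] * ev
        e_solv += sc * pws[p] * es
        dedr = sc * (pwv[p] * dev + pws[p] * des)
        g = -dedr * inv_r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    # bonds (unwrapped coordinates: bonded neighbours are never imaged)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_b0[b]
        e_bond += 0.5 * kb * dr * dr
        g = -kb * dr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    # angles: cosine-harmonic V = (ka/2)(cos t - cos t0)^2, whose gradient
    # is free of the 1/sin singularity at collinear geometries
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        dc = c - ang_t0[a]  # ang_t0 stores cos(theta0)
        e_bond += 0.5 * ka * dc * dc
        coef = -ka * dc  # = -dV/dcos
        # dcos/d(i) = (v_hat - c u_hat)/|u| ; dcos/d(k) = (u_hat - c v_hat)/|v|
        gix = coef * (vx / nv - c * ux / nu) / nu
        giy = coef * (vy / nv - c * uy / nu) / nu
        giz = coef * (vz / nv - c * uz / nu) / nu
        gkx = coef * (ux / nu - c * vx / nv) / nv
        gky = coef * (uy / nu - c * vy / nv) / nv
        gkz = coef * (uz / nu - c * vz / nv) / nv
        f[i, 0] += gix
        f[i, 1] += giy
        f[i, 2] += giz
        f[k, 0] += gkx
        f[k, 1] += gky
        f[k, 2] += gkz
        f[j, 0] -= gix + gkx
        f[j, 1] -= giy + gky
        f[j, 2] -= giz + gkz

    # torsions: V = kt (1 - cos(phi - phi0))
    for t in range(tors.shape[0]):
        p1 = tors[t, 0]
        p2 = tors[t, 1]
        p3 = tors[t, 2]
        p4 = tors[t, 3]
        b1x = pos[p2, 0] - pos[p1, 0]
        b1y = pos[p2, 1] - pos[p1, 1]
        b1z = pos[p2, 2] - pos[p1, 2]
        b2x = pos[p3, 0] - pos[p2, 0]
        b2y = pos[p3, 1] - pos[p2, 1]
        b2z = pos[p3, 2] - pos[p2, 2]
        b3x = pos[p4, 0] - pos[p3, 0]
        b3y = pos[p4, 1] - pos[p3, 1]
        b3z = pos[p4, 2] - pos[p3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # phi = atan2(dot(cross(n1,n2), b2hat), dot(n1,n2))
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        y = -(cx * b2x + cy * b2y + cz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        e_bond += kt * (1.0 - np.cos(phi - tor_p0[t]))
        dvdphi = kt * np.sin(phi - tor_p0[t])
        # dphi/dp1 = |b2|/|n1|^2 n1 ; dphi/dp4 = -|b2|/|n2|^2 n2
        # (signs fixed by the atan2 convention above, verified against
        # central differences of the dihedral)
        g1x = nb2 / n1sq * n1x
        g1y = nb2 / n1sq * n1y
        g1z = nb2 / n1sq * n1z
        g4x = -nb2 / n2sq * n2x
        g4y = -nb2 / n2sq * n2y
        g4z = -nb2 / n2sq * n2z
        db12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        db32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g2x = -(1.0 + db12) * g1x + db32 * g4x
        g2y = -(1.0 + db12) * g1y + db32 * g4y
        g2z = -(1.0 + db12) * g1z + db32 * g4z
        g3x = db12 * g1x - (1.0 + db32) * g4x
        g3y = db12 * g1y - (1.0 + db32) * g4y
        g3z = db12 * g1z - (1.0 + db32) * g4z
        f[p1, 0] -= dvdphi * g1x
        f[p1, 1] -= dvdphi * g1y
        f[p1, 2] -= dvdphi * g1z
        f[p2, 0] -= dvdphi * g2x
        f[p2, 1] -= dvdphi * g2y
        f[p2, 2] -= dvdphi * g2z
        f[p3, 0] -= dvdphi * g3x
        f[p3, 1] -= dvdphi * g3y
        f[p3, 2] -= dvdphi * g3z
        f[p4, 0] -= dvdphi * g4x
        f[p4, 1] -= dvdphi * g4y
        f[p4, 2] -= dvdphi * g4z

    # backbone hydrogen bonds: E = eps_hb * cos^2(theta_NHO) * u(r_HO)
    # for theta > 90 deg; identical well depth at all sequence separations.
    for di in range(dN.shape[0]):
        iN = dN[di]
        iH = dH[di]
        for ai in range(aO.shape[0]):
            if dmol[di] == amol[ai] and abs(dres[di] - ares[ai]) < 2:
                continue
            iO = aO[ai]
            vx = _wd(pw[iO, 0] - pw[iH, 0], L, hL)
            vy = _wd(pw[iO, 1] - pw[iH, 1], L, hL)
            vz = _wd(pw[iO, 2] - pw[iH, 2], L, hL)
            r2 = vx * vx + vy * vy + vz * vz
            if r2 >= hb_cut * hb_cut:
                continue
            r = np.sqrt(r2)
            ux = pos[iN, 0] - pos[iH, 0]
            uy = pos[iN, 1] - pos[iH, 1]
            uz = pos[iN, 2] - pos[iH, 2]
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            c = (ux * vx + uy * vy + uz * vz) / (nu * r)
            if c >= 0.0:
                continue  # theta <= 90 deg
            rad, drad = _hb_radial(r, hb_r0, hb_ss, hb_cut)
            e_hb += eps_hb * c * c * rad
            dedc = 2.0 * eps_hb * c * rad
            dedr = eps_hb * c * c * drad
            # dc/du and dc/dv
            dcux = vx / (nu * r) - c * ux / (nu * nu)
            dcuy = vy / (nu * r) - c * uy / (nu * nu)
            dcuz = vz / (nu * r) - c * uz / (nu * nu)
            dcvx = ux / (nu * r) - c * vx / r2
            dcvy = uy / (nu * r) - c * vy / r2
            dcvz = uz / (nu * r) - c * vz / r2
            # forces = -dE/dpos; u depends on N,H; v on O,H; r on O,H
            fNx = -dedc * dcux
            fNy = -dedc * dcuy
            fNz = -dedc * dcuz
            fOx = -(dedc * dcvx + dedr * vx / r)
            fOy = -(dedc * dcvy + dedr * vy / r)
            fOz = -(dedc * dcvz + dedr * vz / r)
            f[iN, 0] += fNx
            f[iN, 1] += fNy
            f[iN, 2] += fNz
            f[iO, 0] += fOx
            f[iO, 1] += fOy
            f[iO, 2] += fOz
            f[iH, 0] -= fNx + fOx
            f[iH, 1] -= fNy + fOy
            f[iH, 2] -= fNz + fOz

    # structure-based (Go) native contacts, direct (unimaged) distances
    for g in range(go_a.shape[0]):
        i = go_a[g]
        j = go_b[g]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        ev, dev = _go_pair(r, go_r0[g], eps_go * go_w[g])
        e_go += ev
        gg = -dev / r
        f[i, 0] += gg * dx
        f[i, 1] += gg * dy
        f[i, 2] += gg * dz
        f[j, 0] -= gg * dx
        f[j, 1] -= gg * dy
        f[j, 2] -= gg * dz

    return e_bond, e_vdw, e_solv, e_hb, e_go, -1, -1


@njit(cache=True)
def _run_chunk(pos, vel, inv_m, noise, dt, c1, kT, L,
               sigma, eps, dg, lam, rc, sw,
               bonds, bond_b0, kb,
               angles, ang_t0, ka,
               tors, tor_p0, kt,
               dN, dH, dres, dmol, aO, ares, amol,
               eps_hb, hb_r0, hb_ss, hb_cut,
               go_a, go_b, go_r0, go_w, eps_go,
               excl, resseq, mol,
               wvs, wvl, wss, wsl, d_short, d_long, s14,
               skin, use_nlist):
    """BAOAB chunk over noise.shape[0] steps; modifies pos/vel in place.

    Returns (e_bond, e_vdw, e_solv, e_hb, e_go, sum_mvv, err_code,
    err_step, err_i, err_j). err_code: 0 ok, 1 singularity, 2 instability.
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    cut = rc + skin if use_nlist else rc
    pairs, pwv, pws, psc, psig, peps4, pdg, pshift = _build_pairs(
        pos, L, cut, excl, resseq, mol, wvs, wvl, wss, wsl,
        d_short, d_long, s14, sigma, eps, dg, rc)
    pos_ref = pos.copy()
    prev = np.empty((n, 3))
    f = np.empty((n, 3))
    eb, ev, es, eh, eg, erri, errj = _forces(
        pos, L, pairs, pwv, pws, psc, psig, peps4, pdg, pshift, lam, rc, sw,
        bonds, bond_b0, kb, angles, ang_t0, ka, tors, tor_p0, kt,
        dN, dH, dres, dmol, aO, ares, amol, eps_hb, hb_r0, hb_ss, hb_cut,
        go_a, go_b, go_r0, go_w, eps_go, f)
    if erri >= 0:
        return eb, ev, es, eh, eg, 0.0, 1, 0, erri, errj
    sum_mvv = 0.0
    half = 0.5 * dt
    c2fac = (1.0 - c1 * c1) * kT * F_CONV
    for s in range(n_steps):
        for i in range(n):
            prev[i, 0] = pos[i, 0]
            prev[i, 1] = pos[i, 1]
            prev[i, 2] = pos[i, 2]
            a = half * inv_m[i] * F_CONV
            vel[i, 0] += a * f[i, 0]
            vel[i, 1] += a * f[i, 1]
            vel[i, 2] += a * f[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
            sd = np.sqrt(c2fac * inv_m[i])
            vel[i, 0] = c1 * vel[i, 0] + sd * noise[s, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + sd * noise[s, i, 1]
            vel[i, 2] = c1 * vel[i, 2] + sd * noise[s, i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        # instability and neighbor-list housekeeping
        moved = not use_nlist
        half_skin2 = 0.25 * skin * skin
        for i in range(n):
            ddx = pos[i, 0] - prev[i, 0]
            ddy = pos[i, 1] - prev[i, 1]
            ddz = pos[i, 2] - prev[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > 4.0:
                return eb, ev, es, eh, eg, sum_mvv, 2, s, i, -1
            if use_nlist and not moved:
                rx = pos[i, 0] - pos_ref[i, 0]
                ry = pos[i, 1] - pos_ref[i, 1]
                rz = pos[i, 2] - pos_ref[i, 2]
                if rx * rx + ry * ry + rz * rz > half_skin2:
                    moved = True
        if moved:
            pairs, pwv, pws, psc, psig, peps4, pdg, pshift = _build_pairs(
                pos, L, cut, excl, resseq, mol, wvs, wvl, wss, wsl,
                d_short, d_long, s14, sigma, eps, dg, rc)
            if use_nlist:
                for i in range(n):
                    pos_ref[i, 0] = pos[i, 0]
                    pos_ref[i, 1] = pos[i, 1]
                    pos_ref[i, 2] = pos[i, 2]
        eb, ev, es, eh, eg, erri, errj = _forces(
            pos, L, pairs, pwv, pws, psc, psig, peps4, pdg, pshift, lam, rc, sw,
            bonds, bond_b0, kb, angles, ang_t0, ka, tors, tor_p0, kt,
            dN, dH, dres, dmol, aO, ares, amol, eps_hb, hb_r0, hb_ss, hb_cut,
            go_a, go_b, go_r0, go_w, eps_go, f)
        if erri >= 0:
            return eb, ev, es, eh, eg, sum_mvv, 1, s, erri, errj
        for i in range(n):
            a = half * inv_m[i] * F_CONV
            vel[i, 0] += a * f[i, 0]
            vel[i, 1] += a * f[i, 1]
            vel[i, 2] += a * f[i, 2]
            m_i = 1.0 / inv_m[i]
            sum_mvv += m_i * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    return eb, ev, es, eh, eg, sum_mvv, 0, n_steps - 1, -1, -1
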