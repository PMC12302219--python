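"""McMurchie-Davidson evaluation of Gaussian AO integrals.

All integrals are computed over *raw* Cartesian primitives
``x^i y^j z^k exp(-a r^2)`` (no per-component normalization); normalization
and contraction conventions are handled one level up in :mod:`xccprop.basis`.
The Hermite-expansion (E) and Hermite-Coulomb (R) tables follow the standard
McMurchie-Davidson recursions; the Boys function uses a downward-stable
series for small arguments and the asymptotic form plus upward recursion for
large ones.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "overlap_kinetic",
    "nuclear_attraction",
    "moment_integrals",
    "eri_cartesian",
]

_SQRT_PI = float(np.sqrt(np.pi))


@njit(cache=True)
def _boys(mmax, T, out):
    """Fill out[0..mmax] with Boys functions F_m(T)."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if T < 35.0:
        # series for the highest order, then downward recursion
        expT = np.exp(-T)
        s = 0.0
        term = 1.0 / (2.0 * mmax + 1.0)
        k = 0
        while True:
            s += term
            k += 1
            term *= 2.0 * T / (2.0 * mmax + 2.0 * k + 1.0)
            if term < 1e-17 * s or k > 200:
                break
        out[mmax] = s * expT
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + expT) / (2.0 * m + 1.0)
    else:
        expT = np.exp(-T)
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for m in range(mmax):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - expT) / (2.0 * T)


@njit(cache=True)
def _e_table(la, lb, a, b, AB):
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction."""
    p = a + b
    mu = a * b / p
    E = np.zeros((la + 1, lb + 1, la + lb + 1))
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    XPA = -b * AB / p  # P - A with AB = A - B
    XPB = a * AB / p   # P - B
    for i in range(la):
        for t in range(i + 2):
            v = 0.0
            if t > 0:
                v += E[i, 0, t - 1] / (2.0 * p)
            v += XPA * E[i, 0, t]
            if t + 1 <= i:
                v += (t + 1.0) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 2):
                v = 0.0
                if t > 0:
                    v += E[i, j, t - 1] / (2.0 * p)
                v += XPB * E[i, j, t]
                if t + 1 <= i + j:
                    v += (t + 1.0) * E[i, j, t + 1]
                E[i, j + 1, t] = v
    return E


@njit(cache=True)
def _r_table(L, p, PCx, PCy, PCz):
    """Hermite Coulomb integrals R_{t,u,v} up to total order L."""
    T = p * (PCx * PCx + PCy * PCy + PCz * PCz)
    F = np.zeros(L + 1)
    _boys(L, T, F)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))
    mp = 1.0
    for n in range(L + 1):
        R[n, 0, 0, 0] = mp * F[n]
        mp *= -2.0 * p
    for total in range(1, L + 1):
        for t in range(total + 1):
            for u in range(total - t + 1):
                v = total - t - u
                for n in range(L - total, -1, -1):
                    if v > 0:
                        val = PCz * R[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1.0) * R[n + 1, t, u, v - 2]
                    elif u > 0:
                        val = PCy * R[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1.0) * R[n + 1, t, u - 2, v]
                    else:
                        val = PCx * R[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1.0) * R[n + 1, t - 2, u, v]
                    R[n, t, u, v] = val
    return R


def _cart_components(l):
    """Cartesian monomial exponents for angular momentum l (lexicographic)."""
    return [(lx, ly, l - lx - ly) for lx in range(l, -1, -1)
            for ly in range(l - lx, -1, -1)]


def overlap_kinetic(la, lb, a, b, A, B):
    """Primitive overlap and kinetic blocks over raw Cartesians.

    Returns (S, T) arrays of shape (ncart(la), ncart(lb)).
    """
    # 1D overlaps up to la+2 / lb+2 needed for kinetic
    p = a + b
    pref = _SQRT_PI / np.sqrt(p)
    E = [_e_table(la + 2, lb + 2, a, b, A[d] - B[d]) for d in range(3)]
    s1d = [pref * E[d][:, :, 0] for d in range(3)]

    ca, cb = _cart_components(la), _cart_components(lb)
    S = np.zeros((len(ca), len(cb)))
    T = np.zeros((len(ca), len(cb)))
    for ia, (ax, ay, az) in enumerate(ca):
        for ib, (bx, by, bz) in enumerate(cb):
            sx, sy, sz = s1d[0][ax, bx], s1d[1][ay, by], s1d[2][az, bz]
            S[ia, ib] = sx * sy * sz

            def kin1d(d, i, j):
                s = s1d[d]
                t = b * (2 * j + 1) * s[i, j] - 2.0 * b * b * s[i, j + 2]
                if j >= 2:
                    t -= 0.5 * j * (j - 1) * s[i, j - 2]
                return t

            T[ia, ib] = (kin1d(0, ax, bx) * sy * sz
                         + sx * kin1d(1, ay, by) * sz
                         + sx * sy * kin1d(2, az, bz))
    return S, T


def moment_integrals(la, lb, a, b, A, B, origin):
    """First and second Cartesian moment integrals about ``origin``.

    Returns (dip, sec): dip[3, na, nb] = <a| x_C,alpha |b>;
    sec[6, na, nb] = <a| x_C,alpha x_C,beta |b> with alpha<=beta ordered
    (xx, xy, xz, yy, yz, zz).
    """
    p = a + b
    pref = _SQRT_PI / np.sqrt(p)
    E = [_e_table(la + 2, lb, a, b, A[d] - B[d]) for d in range(3)]
    s1d = [pref * E[d][:, :, 0] for d in range(3)]
    AC = [A[d] - origin[d] for d in range(3)]

    def m0(d, i, j):
        return s1d[d][i, j]

    def m1(d, i, j):
        return s1d[d][i + 1, j] + AC[d] * s1d[d][i, j]

    def m2(d, i, j):
        return (s1d[d][i + 2, j] + 2.0 * AC[d] * s1d[d][i + 1, j]
                + AC[d] * AC[d] * s1d[d][i, j])

    ca, cb = _cart_components(la), _cart_components(lb)
    dip = np.zeros((3, len(ca), len(cb)))
    sec = np.zeros((6, len(ca), len(cb)))
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    for ia, ka in enumerate(ca):
        for ib, kb in enumerate(cb):
            base = [m0(d, ka[d], kb[d]) for d in range(3)]
            first = [m1(d, ka[d], kb[d]) for d in range(3)]
            second = [m2(d, ka[d], kb[d]) for d in range(3)]
            for al in range(3):
                prod = 1.0
                for d in range(3):
                    prod *= first[d] if d == al else base[d]
                dip[al, ia, ib] = prod
            for ip, (al, be) in enumerate(pairs):
                prod = 1.0
                if al == be:
                    for d in range(3):
                        prod *= second[d] if d == al else base[d]
                else:
                    for d in range(3):
                        if d == al or d == be:
                            prod *= first[d]
                        else:
                            prod *= base[d]
                sec[ip, ia, ib] = prod
    return dip, sec


def nuclear_attraction(la, lb, a, b, A, B, atoms):
    """Primitive nuclear-attraction block -sum_I Z_I <a|1/r_I|b>."""
    p = a + b
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    E = [_e_table(la, lb, a, b, A[d] - B[d]) for d in range(3)]
    ca, cb = _cart_components(la), _cart_components(lb)
    L = la + lb
    V = np.zeros((len(ca), len(cb)))
    for Z, C in atoms:
        R = _r_table(L, p, P[0] - C[0], P[1] - C[1], P[2] - C[2])
        for ia, ka in enumerate(ca):
            for ib, kb in enumerate(cb):
                acc = 0.0
                for t in range(ka[0] + kb[0] + 1):
                    ex = E[0][ka[0], kb[0], t]
                    for u in range(ka[1] + kb[1] + 1):
                        ey = E[1][ka[1], kb[1], u]
                        for v in range(ka[2] + kb[2] + 1):
                            acc += ex * ey * E[2][ka[2], kb[2], v] * R[0, t, u, v]
                V[ia, ib] -= Z * acc * 2.0 * np.pi / p
    return V


@njit(cache=True)
def _pair_hermite(la, lb, a, b, Ax, Ay, Az, Bx, By, Bz, ncarta, ncartb, comps_a, comps_b):
    """Hermite coefficients c[comp_ab, t, u, v] for one primitive pair."""
    Ex = _e_table(la, lb, a, b, Ax - Bx)
    Ey = _e_table(la, lb, a, b, Ay - By)
    Ez = _e_table(la, lb, a, b, Az - Bz)
    L = la + lb
    out = np.zeros((ncarta * ncartb, L + 1, L + 1, L + 1))
    for ia in range(ncarta):
        axx = comps_a[ia, 0]
        ayy = comps_a[ia, 1]
        azz = comps_a[ia, 2]
        for ib in range(ncartb):
            bxx = comps_b[ib, 0]
            byy = comps_b[ib, 1]
            bzz = comps_b[ib, 2]
            idx = ia * ncartb + ib
            for t in range(axx + bxx + 1):
                ex = Ex[axx, bxx, t]
                for u in range(ayy + byy + 1):
                    exy = ex * Ey[ayy, byy, u]
                    for v in range(azz + bzz + 1):
                        out[idx, t, u, v] = exy * Ez[azz, bzz, v]
    return out


@njit(cache=True)
def _eri_quartet(cbra, Lbra, pbra, Pb, cket, Lket, pket, Pk, out):
    """Accumulate primitive (bra|ket) Cartesian ERI block into out."""
    alpha = pbra * pket / (pbra + pket)
    L = Lbra + Lket
    R = _r_table(L, alpha,
                 Pb[0] - Pk[0], Pb[1] - Pk[1], Pb[2] - Pk[2])
    pref = 2.0 * np.pi ** 2.5 / (pbra * pket * np.sqrt(pbra + pket))
    nb = cbra.shape[0]
    nk = cket.shape[0]
    for ibra in range(nb):
        for iket in range(nk):
            acc = 0.0
            for t in range(Lbra + 1):
                for u in range(Lbra + 1 - t):
                    for v in range(Lbra + 1 - t - u):
                        cb = cbra[ibra, t, u, v]
                        if cb == 0.0:
                            continue
                        for tt in range(Lket + 1):
                            for uu in range(Lket + 1 - tt):
                                for vv in range(Lket + 1 - tt - uu):
                                    ck = cket[iket, tt, uu, vv]
                                    if ck == 0.0:
                                        continue
                                    sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                    acc += cb * ck * sgn * R[0, t + tt, u + uu, v + vv]
            out[ibra, iket] += pref * acc
    return out


def eri_cartesian(shells):
    """Full Cartesian-primitive-contracted ERI tensor (chemists' (ab|cd)).

    ``shells`` is a list of tuples (l, center(3,), exps(K,), coefs(K,)) where
    coefs already include primitive normalization. Returns the tensor over
    contracted Cartesian components in shell order.
    """
    ncart = [(s[0] + 1) * (s[0] + 2) // 2 for s in shells]
    offs = np.concatenate([[0], np.cumsum(ncart)]).astype(int)
    nao = offs[-1]
    comps = {l: np.array(_cart_components(l), dtype=np.int64) for l in range(5)}

    # precompute contracted Hermite coefficient tables per shell pair
    nsh = len(shells)
    pair_data = {}
    for A in range(nsh):
        lA, cA, eA, kA = shells[A]
        for B in range(A + 1):
            lB, cB, eB, kB = shells[B]
            plist = []
            for ia, a in enumerate(eA):
                for ib, b in enumerate(eB):
                    p = a + b
                    P = (a * cA + b * cB) / p
                    herm = _pair_hermite(lA, lB, a, b,
                                         cA[0], cA[1], cA[2],
                                         cB[0], cB[1], cB[2],
                                         ncart[A], ncart[B],
                                         comps[lA], comps[lB])
                    plist.append((kA[ia] * kB[ib], p, P, herm))
            pair_data[(A, B)] = plist

    g = np.zeros((nao, nao, nao, nao))
    for A in range(nsh):
        for B in range(A + 1):
            bra = pair_data[(A, B)]
            Lbra = shells[A][0] + shells[B][0]
            for C in range(A + 1):
                Dmax = B if C == A else C
                for D in range(Dmax + 1):
                    ket = pair_data[(C, D)]
                    Lket = shells[C][0] + shells[D][0]
                    block = np.zeros((ncart[A] * ncart[B], ncart[C] * ncart[D]))
                    for wab, p, P, hab in bra:
                        for wcd, q, Q, hcd in ket:
                            tmp = np.zeros_like(block)
                            _eri_quartet(hab, Lbra, p, P, hcd, Lket, q, Q, tmp)
                            block += wab * wcd * tmp
                    blk = block.reshape(ncart[A], ncart[B], ncart[C], ncart[D])
                    sA, sB = offs[A], offs[B]
                    sC, sD = offs[C], offs[D]
                    for perm in _sym8(sA, ncart[A], sB, ncart[B], sC, ncart[C], sD, ncart[D]):
                        (oa, ob, oc, od), axes = perm
                        g[oa[0]:oa[1], ob[0]:ob[1], oc[0]:oc[1], od[0]:od[1]] = \
                            blk.transpose(axes)
    return g


def _sym8(sA, nA, sB, nB, sC, nC, sD, nD):
    """Index ranges + transposes for scattering one unique ERI block."""
    A = (sA, sA + nA)
    B = (sB, sB + nB)
    C = (sC, sC + nC)
    D = (sD, sD + nD)
    seen = set()
    out = []
    for (ra, rb, rc, rd), ax in [
        ((A, B, C, D), (0, 1, 2, 3)),
        ((B, A, C, D), (1, 0, 2, 3)),
        ((A, B, D, C), (0, 1, 3, 2)),
        ((B, A, D, C), (1, 0, 3, 2)),
        ((C, D, A, B), (2, 3, 0, 1)),
        ((D, C, A, B), (3, 2, 0, 1)),
        ((C, D, B, A), (2, 3, 1, 0)),
        ((D, C, B, A), (3, 2, 1, 0)),
    ]:
        key = (ra, rb, rc, rd)
        if key not in seen:
            seen.add(key)
            out.append((key, ax))
    return out
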