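"""String-driven direct CI with optional Abelian point-group blocking.

A determinant-basis Davidson FCI designed for the dipole-surface reference
at cc-pVDZ scale (18 active orbitals, 8 electrons).  The sigma vector
follows the classic spin-summed two-step algorithm: gather D_kl = E_kl c
over packed orbital pairs, one dense GEMM against the (one-electron-
absorbed) integral supermatrix, scatter back.  For z-axis molecules the
C2v orbital irreps (labels "a1","b1","b2","a2"; products by XOR) restrict
the determinant basis to the totally symmetric block and block the GEMM by
pair irrep, cutting cost roughly an order of magnitude; with all orbitals
labeled a1 the code reduces to plain C1 FCI.  Work arrays are built per
string-irrep row block to bound memory.

This engine is the production large-scale path; the brute-force
:mod:`xccprop.oracle` stays independent and cross-checks it on small cases.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from numba import njit

from .integrals import MolecularIntegrals

__all__ = ["DirectCI"]

_IRREP_ID = {"": 0, "a1": 0, "b1": 1, "b2": 2, "a2": 3}


@njit(cache=True)
def _gather_a(D, C, tab, nb, c_off):
    # D[p, I*nb + Ib] += s * C[c_off + J*nb + Ib]
    for e in range(tab.shape[0]):
        p, J, I, s = tab[e, 0], tab[e, 2], tab[e, 3], tab[e, 4]
        do = I * nb
        co = c_off + J * nb
        for k in range(nb):
            D[p, do + k] += s * C[co + k]


@njit(cache=True)
def _scatter_a(sig, G, tab, nb, s_off):
    # sig[s_off + I*nb + Ib] += s * G[p, J*nb + Ib]
    for e in range(tab.shape[0]):
        p, J, I, s = tab[e, 0], tab[e, 2], tab[e, 3], tab[e, 4]
        so = s_off + I * nb
        go = J * nb
        for k in range(nb):
            sig[so + k] += s * G[p, go + k]


@njit(cache=True)
def _sym_add_inplace(D, n):
    """D[p] <- D[p] + D[p]^T for square per-pair blocks, in place."""
    for p in range(D.shape[0]):
        for i in range(n):
            D[p, i * n + i] *= 2.0
            for j in range(i + 1, n):
                s = D[p, i * n + j] + D[p, j * n + i]
                D[p, i * n + j] = s
                D[p, j * n + i] = s


@njit(cache=True)
def _add_transposed(D, Y, nR, nS):
    """D[p, i*nS + j] += Y[p, j*nR + i], cache-blocked."""
    B = 64
    for p in range(D.shape[0]):
        for i0 in range(0, nR, B):
            i1 = min(i0 + B, nR)
            for j0 in range(0, nS, B):
                j1 = min(j0 + B, nS)
                for i in range(i0, i1):
                    for j in range(j0, j1):
                        D[p, i * nS + j] += Y[p, j * nR + i]


class DirectCI:
    """Davidson FCI over the Sz=0, totally symmetric determinant block."""

    def __init__(self, ints: MolecularIntegrals, irreps=None):
        self.ints = ints
        n = ints.n_orb
        self.n = n
        self.na = ints.n_elec // 2
        if irreps is None:
            irreps = ints.mo_irrep or [""] * n
        self.orb_irrep = np.array([_IRREP_ID[x] for x in irreps],
                                  dtype=np.int64)

        groups = [[] for _ in range(4)]
        for occ in combinations(range(n), self.na):
            s = 0
            g = 0
            for p in occ:
                s |= 1 << p
                g ^= int(self.orb_irrep[p])
            groups[g].append(s)
        self.strs = [np.array(sorted(gr), dtype=np.int64) for gr in groups]
        self.N = np.array([len(s) for s in self.strs], dtype=np.int64)
        self.c_off = np.zeros(4, dtype=np.int64)
        for g in range(1, 4):
            self.c_off[g] = self.c_off[g - 1] + int(self.N[g - 1]) ** 2
        self.dim = int(np.sum(self.N ** 2))

        self.pairs = [[] for _ in range(4)]
        for k in range(n):
            for l in range(k + 1):
                h = int(self.orb_irrep[k] ^ self.orb_irrep[l])
                self.pairs[h].append((k, l))
        pair_local = {}
        for h in range(4):
            for idx, (k, l) in enumerate(self.pairs[h]):
                pair_local[(k, l)] = idx

        # excitation tables split by (pair irrep h, string irrep of J)
        idx_of = [{int(s): i for i, s in enumerate(self.strs[g])}
                  for g in range(4)]
        self.tables = [[None] * 4 for _ in range(4)]
        for h in range(4):
            rows = [[] for _ in range(4)]
            for g in range(4):
                for Jloc, s in enumerate(self.strs[g]):
                    s = int(s)
                    for k, l in self.pairs[h]:
                        plocal = pair_local[(k, l)]
                        cands = ((k, l),) if k == l else ((k, l), (l, k))
                        for kk, ll in cands:
                            if not (s >> ll) & 1:
                                continue
                            s1 = s & ~(1 << ll)
                            if (s1 >> kk) & 1:
                                continue
                            s2 = s1 | (1 << kk)
                            ph = (bin(s & ((1 << ll) - 1)).count("1")
                                  + bin(s1 & ((1 << kk) - 1)).count("1"))
                            sign = 1 if ph % 2 == 0 else -1
                            Iloc = idx_of[g ^ h][s2]
                            rows[g].append((plocal, g, Jloc, Iloc, sign))
            for g in range(4):
                self.tables[h][g] = np.array(rows[g], dtype=np.int64).reshape(
                    -1, 5)

        self._build_w()
        self._build_diag()

        # reusable sigma work buffers (sized for the largest block)
        mx = 0
        for h in range(4):
            m = len(self.pairs[h])
            for gR in range(4):
                mx = max(mx, m * int(self.N[gR]) * int(self.N[gR ^ h]))
        self._bufY = np.empty(mx)
        self._bufY2 = np.empty(mx)
        self._bufG = np.empty(mx)

    def _build_w(self):
        n = self.n
        g = self.ints.g
        f1e = self.ints.h - 0.5 * np.einsum("jiik->jk", g)
        f1e = f1e * (1.0 / self.ints.n_elec)
        h2e = g.copy()
        for k in range(n):
            h2e[k, k, :, :] += f1e
            h2e[:, :, k, k] += f1e
        self.W = []
        for h in range(4):
            plist = self.pairs[h]
            m = len(plist)
            W = np.empty((m, m))
            for i, (k, l) in enumerate(plist):
                for j, (a, b) in enumerate(plist):
                    W[i, j] = h2e[k, l, a, b]
            self.W.append(0.5 * W)

    def _build_diag(self):
        n = self.n
        g = self.ints.g
        J = np.einsum("ppqq->pq", g)
        K = np.einsum("pqqp->pq", g)
        hd = np.diag(self.ints.h)
        diag = np.empty(self.dim)
        for gr in range(4):
            if self.N[gr] == 0:
                continue
            O = np.zeros((self.N[gr], n))
            for i, s in enumerate(self.strs[gr]):
                s = int(s)
                for p in range(n):
                    if (s >> p) & 1:
                        O[i, p] = 1.0
            h_sum = O @ hd
            ss = 0.5 * (np.einsum("ip,pq,iq->i", O, J - K, O)
                        - O @ np.diag(J - K))
            cross = O @ J @ O.T
            blk = (h_sum[:, None] + h_sum[None, :]
                   + ss[:, None] + ss[None, :] + cross)
            self_off = self.c_off[gr]
            diag[self_off:self_off + int(self.N[gr]) ** 2] = blk.ravel()
        self.Hdiag = diag

    # ------------------------------------------------------------ sigma

    def _flip(self, v):
        """Alpha-beta exchange: transpose every (g, g) determinant block."""
        out = np.empty_like(v)
        for g in range(4):
            n = int(self.N[g])
            if n == 0:
                continue
            o = int(self.c_off[g])
            out[o:o + n * n] = v[o:o + n * n].reshape(n, n).T.ravel()
        return out

    n_sigma = 0

    def sigma(self, c):
        """Two-electron sigma for a spin-symmetric (singlet-block) vector.

        Uses C = C^flip to build the pair density from alpha excitations
        only (contiguous memory access): D = Y + flip(Y), sigma = Z +
        flip(Z) with Z the alpha scatter of G = W D.
        """
        self.n_sigma += 1
        Z = np.zeros_like(c)
        for h in range(4):
            m = len(self.pairs[h])
            if m == 0:
                continue
            done = set()
            for gR in range(4):
                gS = gR ^ h
                key = (min(gR, gS), max(gR, gS))
                if key in done:
                    continue
                done.add(key)
                nR, nS = int(self.N[gR]), int(self.N[gS])
                if nR == 0 or nS == 0:
                    continue
                D_R = self._bufY[:m * nR * nS].reshape(m, nR * nS)
                D_R.fill(0.0)
                ta_S = self.tables[h][gS]
                if ta_S.size:
                    _gather_a(D_R, c, ta_S, nS, int(self.c_off[gS]))
                if gS != gR:
                    Y_S = self._bufY2[:m * nS * nR].reshape(m, nS * nR)
                    Y_S.fill(0.0)
                    ta_R = self.tables[h][gR]
                    if ta_R.size:
                        _gather_a(Y_S, c, ta_R, nR, int(self.c_off[gR]))
                    _add_transposed(D_R, Y_S, nR, nS)
                else:
                    _sym_add_inplace(D_R, nR)
                G_R = self._bufG[:m * nR * nS].reshape(m, nR * nS)
                np.matmul(self.W[h], D_R, out=G_R)
                tr = self.tables[h][gR]
                if tr.size:
                    _scatter_a(Z, G_R, tr, nS, int(self.c_off[gS]))
                if gS != gR:
                    G_S = self._bufY[:m * nS * nR].reshape(m, nS, nR)
                    G_S.fill(0.0)
                    _add_transposed(G_S.reshape(m, nS * nR),
                                    G_R, nS, nR)
                    ts = self.tables[h][gS]
                    if ts.size:
                        _scatter_a(Z, G_S.reshape(m, nS * nR), ts, nR,
                                   int(self.c_off[gR]))
        return Z + self._flip(Z)

    def solve(self, c0=None, tol=1e-6, max_cycle=80, max_space=14,
              subspace0=None):
        """Lowest eigenpair by Davidson with Olsen-corrected updates.

        ``c0`` warm starts from a previous vector; ``subspace0`` (a list of
        vectors, e.g. :attr:`last_subspace` of the previous geometry's
        solver) seeds the whole search space.  Returns (E_total, c).
        """
        dim = self.dim
        seeds = []
        if subspace0 is not None:
            seeds.extend(subspace0)
        elif c0 is not None:
            seeds.append(c0)
        else:
            c0 = np.zeros(dim)
            c0[int(np.argmin(self.Hdiag))] = 1.0
            seeds.append(c0)
        b, sb = [], []
        for v in seeds:
            t = 0.5 * (v + self._flip(v))   # singlet-block projection
            for _ in range(2):
                for bi in b:
                    t -= (bi @ t) * bi
            nt = np.linalg.norm(t)
            if nt < 1e-8:
                continue
            b.append(t / nt)
            sb.append(self.sigma(b[-1]))
        rn = np.inf
        for _ in range(max_cycle):
            m = len(b)
            Hm = np.empty((m, m))
            for i in range(m):
                for j in range(m):
                    Hm[i, j] = b[i] @ sb[j]
            Hm = 0.5 * (Hm + Hm.T)
            w, V = np.linalg.eigh(Hm)
            theta, y = w[0], V[:, 0]
            x = sum(yi * bi for yi, bi in zip(y, b))
            sx = sum(yi * si for yi, si in zip(y, sb))
            r = sx - theta * x
            rn = np.linalg.norm(r)
            if rn < tol:
                self.last_subspace = b[-3:] + [x]
                return theta + self.ints.e_core, x / np.linalg.norm(x)
            denom = theta - self.Hdiag
            denom = np.where(np.abs(denom) < 1e-8, -1e-8, denom)
            Dr = r / denom
            Dx = x / denom
            eta = (x @ Dr) / (x @ Dx)       # Olsen orthogonality shift
            t = Dr - eta * Dx
            if len(b) >= max_space:
                b = [x / np.linalg.norm(x)]
                sb = [self.sigma(b[0])]
            t = 0.5 * (t + self._flip(t))
            for _pass in range(2):          # double Gram-Schmidt
                for bi in b:
                    t -= (bi @ t) * bi
            nt = np.linalg.norm(t)
            if nt < 1e-10:
                self.last_subspace = b[-3:] + [x]
                return theta + self.ints.e_core, x / np.linalg.norm(x)
            t /= nt
            b.append(t)
            sb.append(self.sigma(t))
        raise RuntimeError(f"Davidson did not converge (residual {rn:.2e})")

    # ------------------------------------------------------------- RDM

    def rdm1(self, c):
        """Spin-summed symmetric 1-RDM of a normalized spin-symmetric vector."""
        m = len(self.pairs[0])
        vals = np.zeros(m)
        for gR in range(4):
            nR = int(self.N[gR])
            if nR == 0:
                continue
            D = np.zeros((m, nR * nR))
            ta = self.tables[0][gR]
            if ta.size:
                _gather_a(D, c, ta, nR, int(self.c_off[gR]))
            blk = c[self.c_off[gR]:self.c_off[gR] + nR * nR]
            vals += 2.0 * (D @ blk)   # beta part equals alpha by spin symmetry
        gam = np.zeros((self.n, self.n))
        for idx, (k, l) in enumerate(self.pairs[0]):
            if k == l:
                gam[k, k] = vals[idx]
            else:
                gam[k, l] = gam[l, k] = 0.5 * vals[idx]
        return gam
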