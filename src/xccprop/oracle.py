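"""Brute-force determinant-space engine (FCI, exact CC expectations).

Everything here is built from explicit second-quantized operators over
Sz=0 determinant bases: single-spin excitation matrices are assembled from
bit-string algebra, composed into the Hamiltonian, cluster operators and
one-electron observables as sparse matrices.  Exponentials of (nilpotent)
cluster operators are evaluated by their exactly terminating series.  This
module is deliberately simple and slow -- it is the ground truth that the
production amplitude solvers and density formulas are tested against, and
shares no code path with them.

Hard cap: n_orb <= 14 (the basis grows combinatorially).  Larger FCI
problems (the HF/cc-pVDZ dipole-surface reference) are handled by the
string-driven direct CI in :mod:`xccprop.bigfci`.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from .integrals import MolecularIntegrals

__all__ = ["DetSpace"]


def _bit_strings(n_orb, n_elec):
    out = []
    for occ in combinations(range(n_orb), n_elec):
        s = 0
        for p in occ:
            s |= 1 << p
        out.append(s)
    out.sort()
    return out


class DetSpace:
    """Sz=0 determinant space with operator algebra over sparse matrices."""

    MAX_ORB = 14
    MAX_DIM = 4_000_000

    def __init__(self, n_orb, n_elec):
        if n_orb > self.MAX_ORB:
            raise ValueError(f"determinant oracle capped at {self.MAX_ORB} orbitals")
        if n_elec % 2:
            raise ValueError("Sz=0 space requires an even electron count")
        self.n_orb = n_orb
        self.n_elec = n_elec
        self.n_alpha = n_elec // 2
        self.strings = _bit_strings(n_orb, self.n_alpha)
        self.nstr = len(self.strings)
        self.index = {s: i for i, s in enumerate(self.strings)}
        self.dim = self.nstr * self.nstr
        if self.dim > self.MAX_DIM:
            raise ValueError("determinant space too large for the oracle")

    # ---------------------------------------------------------- operators

    @lru_cache(maxsize=None)
    def _exc_string(self, q, p):
        """Sparse one-spin matrix of a_q^dagger a_p over strings."""
        rows, cols, vals = [], [], []
        for j, s in enumerate(self.strings):
            if not (s >> p) & 1:
                continue
            s1 = s & ~(1 << p)
            if (s1 >> q) & 1:
                continue
            s2 = s1 | (1 << q)
            # phase: electrons below p in s, electrons below q in s1
            ph = (-1) ** (bin(s & ((1 << p) - 1)).count("1")
                          + bin(s1 & ((1 << q) - 1)).count("1"))
            rows.append(self.index[s2])
            cols.append(j)
            vals.append(float(ph))
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.nstr, self.nstr))

    @lru_cache(maxsize=None)
    def exc(self, p, q, spin):
        """Full-space a_q(spin)^dagger a_p(spin) (moves an electron p -> q)."""
        m = self._exc_string(q, p)
        eye = sp.identity(self.nstr, format="csr")
        if spin == "a":
            return sp.kron(m, eye, format="csr")
        # beta strings ordered after alpha: sign from alpha parity is global
        # (+1) because beta operators commute with an even alpha product only
        # when n_alpha is even; we keep the standard alpha-then-beta ordered
        # convention in which single beta excitations carry (-1)^n_alpha twice
        # (creation+annihilation), i.e. +1 overall.
        return sp.kron(eye, m, format="csr")

    @lru_cache(maxsize=None)
    def E(self, p, q):
        """Singlet excitation E moving p -> q summed over spins."""
        return self.exc(p, q, "a") + self.exc(p, q, "b")

    @lru_cache(maxsize=None)
    def pair(self, i, a):
        """Pair excitation P_a^dagger P_i (moves the i-pair to orbital a)."""
        return sp.kron(self._exc_string(a, i), self._exc_string(a, i),
                       format="csr")

    def one_body(self, X):
        """Operator sum_pq X_pq E(p->q) for a symmetric MO matrix X."""
        n = self.n_orb
        op = sp.csr_matrix((self.dim, self.dim))
        for p in range(n):
            for q in range(n):
                if abs(X[p, q]) > 1e-15:
                    op = op + X[p, q] * self.E(p, q)
        return op

    def hamiltonian(self, ints: MolecularIntegrals):
        """Sparse H (without e_core) from h and (pq|rs)."""
        n = self.n_orb
        H = self.one_body(ints.h)
        g = ints.g
        for p in range(n):
            for q in range(n):
                Epq = self.E(q, p)   # E_pq in physics convention: q -> p? see note
                for r in range(n):
                    for s in range(n):
                        v = g[p, q, r, s]
                        if abs(v) < 1e-14:
                            continue
                        # (pq|rs) [E(q->p) E(s->r) - delta_qr E(s->p)] / 2
                        term = Epq @ self.E(s, r)
                        if q == r:
                            term = term - self.E(s, p)
                        H = H + 0.5 * v * term
        return H

    # ------------------------------------------------------------- states

    def ref_vector(self, n_occ):
        s = 0
        for p in range(n_occ):
            s |= 1 << p
        i = self.index[s]
        v = np.zeros(self.dim)
        v[i * self.nstr + i] = 1.0
        return v

    def cluster_operator(self, n_occ, t1=None, t2=None, t_pair=None):
        """Sparse T from spin-free amplitudes.

        t1[i,a]; t2[i,j,a,b] spin-free doubles (T2 = 1/2 sum t E_ai E_bj);
        t_pair[i,a] pure pair amplitudes (equivalent to t2[i,i,a,a]).
        """
        no = n_occ
        T = sp.csr_matrix((self.dim, self.dim))
        if t1 is not None:
            for i in range(no):
                for a in range(no, self.n_orb):
                    if abs(t1[i, a - no]) > 1e-15:
                        T = T + t1[i, a - no] * self.E(i, a)
        if t2 is not None:
            for i in range(no):
                for j in range(no):
                    for a in range(no, self.n_orb):
                        for b in range(no, self.n_orb):
                            v = t2[i, j, a - no, b - no]
                            if abs(v) > 1e-15:
                                T = T + 0.5 * v * (self.E(i, a) @ self.E(j, b))
        if t_pair is not None:
            for i in range(no):
                for a in range(no, self.n_orb):
                    if abs(t_pair[i, a - no]) > 1e-15:
                        T = T + t_pair[i, a - no] * self.pair(i, a)
        return T

    def exp_apply(self, T, v, sign=1.0):
        """exp(sign*T) v by the terminating series."""
        out = v.copy()
        term = v.copy()
        for k in range(1, 60):
            term = sign / k * (T @ term)
            nrm = np.linalg.norm(term)
            if nrm == 0.0:
                break
            out = out + term
            if nrm < 1e-16 * max(1.0, np.linalg.norm(out)):
                break
        return out

    # ------------------------------------------------------------ solvers

    def fci_solve(self, ints: MolecularIntegrals):
        H = self.hamiltonian(ints)
        if self.dim <= 1200:
            w, v = np.linalg.eigh(H.toarray())
            return w[0] + ints.e_core, v[:, 0]
        w, v = eigsh(H, k=1, which="SA", tol=1e-11, maxiter=5000)
        return w[0] + ints.e_core, v[:, 0]

    def rdm1(self, vec):
        """Spin-summed 1-RDM gamma_pq = <E_p^q> of a normalized CI vector."""
        n = self.n_orb
        g = np.zeros((n, n))
        for p in range(n):
            for q in range(n):
                g[p, q] = vec @ (self.E(p, q) @ vec)
        return 0.5 * (g + g.T)

    def cc_expectation(self, T, X, n_occ):
        """<e^T 0| X |e^T 0> / <e^T 0|e^T 0> for one-electron X (MO matrix)."""
        v = self.exp_apply(T, self.ref_vector(n_occ))
        Xop = self.one_body(X)
        return float(v @ (Xop @ v) / (v @ v))

    def cc_density(self, T, n_occ):
        """Exact 1-RDM of the (unnormalized) e^T|0> state, normalized."""
        v = self.exp_apply(T, self.ref_vector(n_occ))
        v = v / np.linalg.norm(v)
        return self.rdm1(v)

    def projective_residual(self, ints, T, bras):
        """<mu| e^-T H e^T |0> for each bra operator in ``bras``.

        ``bras`` is a list of sparse excitation operators B; the bra is
        (B|0>)^T.  Returns the residual vector.
        """
        n_occ = ints.n_elec // 2
        ref = self.ref_vector(n_occ)
        H = self.hamiltonian(ints)
        w = self.exp_apply(T, ref)
        w = H @ w + ints.e_core * w
        w = self.exp_apply(T, w, sign=-1.0)
        out = np.empty(len(bras))
        for k, B in enumerate(bras):
            mu = B @ ref
            out[k] = mu @ w
        return out
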