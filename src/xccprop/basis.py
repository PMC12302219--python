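"""Gaussian basis sets and AO-basis construction.

Two families are shipped: STO-3G (H, He, O) with the standard published
contraction tables, and cc-pVDZ (H, F) where only the primitive exponents
are tabulated -- the s/p contraction vectors are *derived at run time* from
atomic mean-field calculations in the primitive space, which is exactly how
correlation-consistent general contractions are constructed (the contracted
functions are the atomic HF orbitals).  Spherical (5-component) d functions
are used.

The public entry point is :func:`build_basis`, which returns the contracted
Cartesian shell list consumed by :mod:`xccprop.mdints` plus the
Cartesian-to-final-AO transformation and per-AO symmetry labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import mdints

__all__ = ["build_basis", "AOBasis", "ELEMENT_Z"]

ELEMENT_Z = {"H": 1, "He": 2, "O": 8, "F": 9}

# exponents / published contractions ------------------------------------

_STO3G_S_COEF = (0.15432897, 0.53532814, 0.44463454)

STO3G = {
    "H": [("s", (3.42525091, 0.62391373, 0.16885540), _STO3G_S_COEF)],
    "He": [("s", (6.36242139, 1.15892300, 0.31364979), _STO3G_S_COEF)],
    "O": [
        ("s", (130.70932, 23.808861, 6.4436083), _STO3G_S_COEF),
        ("s", (5.0331513, 1.1695961, 0.3803890),
         (-0.09996723, 0.39951283, 0.70011547)),
        ("p", (5.0331513, 1.1695961, 0.3803890),
         (0.15591627, 0.60768372, 0.39195739)),
    ],
}

# cc-pVDZ primitive exponents (contractions derived from atomic SCF)
CCPVDZ_PRIM = {
    "H": {"s": (13.0100, 1.9620, 0.4446, 0.1220),
          "s_free": (0.1220,), "p_free": (0.7270,)},
    "F": {"s": (14710.0, 2207.0, 494.90, 140.20, 45.640,
                16.290, 6.0910, 1.3140, 0.38970),
          "s_free": (0.38970,),
          "p": (22.670, 4.9770, 1.3470, 0.34710),
          "p_free": (0.34710,), "d_free": (1.6400,)},
}

_L_OF = {"s": 0, "p": 1, "d": 2}

# spherical-harmonic combinations of raw Cartesian d monomials
# cart order (xx, xy, xz, yy, yz, zz); row scale fixed by final normalization
_C2S_D = np.array([
    [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],   # z2
    [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],     # xz
    [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],     # yz
    [1.0, 0.0, 0.0, -1.0, 0.0, 0.0],    # x2-y2
    [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],     # xy
])

# C2v irrep (z-axis molecules): labels per spherical component
_IRREP = {
    ("s", 0): "a1",
    ("p", 0): "a1", ("p", 1): "b1", ("p", 2): "b2",  # z, x, y order below
    ("d", 0): "a1", ("d", 1): "b1", ("d", 2): "b2",
    ("d", 3): "a1", ("d", 4): "a2",
}


def _prim_norm(l, a):
    """Normalization of the axial raw Cartesian primitive x^l exp(-a r^2)."""
    dfact = 1.0
    for k in range(2 * l - 1, 0, -2):
        dfact *= k
    return (2.0 * a / np.pi) ** 0.75 * (4.0 * a) ** (l / 2.0) / np.sqrt(dfact)


@dataclass
class AOBasis:
    """Contracted AO basis over one molecule.

    shells: list of (l, center, exps, coefs) with primitive norms folded in
            (Cartesian raw-monomial convention of :mod:`xccprop.mdints`).
    cart2ao: (ncart, nao) matrix from raw Cartesian components to the final
             normalized (spherical where l=2) AO set.
    labels:  per-AO (element, shell-type, component) strings.
    irreps:  per-AO C2v irrep labels, valid when all atoms lie on the z axis.
    """

    shells: list
    cart2ao: np.ndarray
    labels: list
    irreps: list
    atoms: list = field(default_factory=list)

    @property
    def nao(self):
        return self.cart2ao.shape[1]


def _atomic_scf_vectors(element):
    """Atomic fractional-occupation RHF in the primitive cc-pVDZ space.

    Returns dict {"s": (nprim_s, n_s_contr) vectors, "p": ...} of atomic
    orbital coefficients over normalized primitives.
    """
    spec = CCPVDZ_PRIM[element]
    Z = ELEMENT_Z[element]
    center = np.zeros(3)
    shells = []
    kinds = []
    for a in spec["s"]:
        shells.append((0, center, np.array([a]), np.array([_prim_norm(0, a)])))
        kinds.append("s")
    for a in spec.get("p", ()):
        shells.append((1, center, np.array([a]), np.array([_prim_norm(1, a)])))
        kinds.append("p")

    S, T, V, _, _ = _one_electron(shells, [(float(Z), center)], np.zeros(3))
    h = T + V
    ns = kinds.count("s")
    nprim_p = kinds.count("p")

    if element == "H":
        # one-electron problem: exact orbital = lowest eigenvector of h
        e, c = _geig(h[:ns, :ns], S[:ns, :ns])
        return {"s": c[:, [0]]}

    g = mdints.eri_cartesian(shells)

    # occupations: closed subshells x2, open p shell spherically averaged
    nelec = Z
    n_core_s = 2 if nelec > 2 else 1
    n_p = nelec - 2 * n_core_s            # electrons in the p shell
    focc_p = n_p / 3.0                    # per Cartesian component

    nao = S.shape[0]
    s_idx = np.arange(ns)
    # p components: shells appended per primitive, 3 cartesians each
    D = np.zeros((nao, nao))
    e_old = 0.0
    cs = cp = None
    for it in range(200):
        J = np.einsum("pqrs,rs->pq", g, D)
        K = np.einsum("prqs,rs->pq", g, D)
        F = h + J - 0.5 * K
        # s block
        es, cs = _geig(F[np.ix_(s_idx, s_idx)], S[np.ix_(s_idx, s_idx)])
        # p_z block: columns of p shells, z-component
        pz_idx = np.array([ns + 3 * k + 2 for k in range(nprim_p)])
        ep, cp = _geig(F[np.ix_(pz_idx, pz_idx)], S[np.ix_(pz_idx, pz_idx)])
        Dn = np.zeros_like(D)
        for i in range(n_core_s):
            Dn[np.ix_(s_idx, s_idx)] += 2.0 * np.outer(cs[:, i], cs[:, i])
        for comp in range(3):
            idx = np.array([ns + 3 * k + comp for k in range(nprim_p)])
            Dn[np.ix_(idx, idx)] += focc_p * np.outer(cp[:, 0], cp[:, 0])
        D = 0.5 * (D + Dn) if it > 0 else Dn
        e_el = np.sum(D * (h + 0.5 * (J - 0.5 * K)))
        if abs(e_el - e_old) < 1e-11 and it > 3:
            break
        e_old = e_el
    return {"s": cs[:, :n_core_s], "p": cp[:, [0]]}


@lru_cache(maxsize=None)
def _ccpvdz_element_shells(element):
    """(l, exps, coefs) tuples for one element, coefs over normalized prims."""
    spec = CCPVDZ_PRIM[element]
    vec = _atomic_scf_vectors(element)
    out = []
    s_exps = np.array(spec["s"])
    for col in range(vec["s"].shape[1]):
        out.append((0, s_exps, vec["s"][:, col].copy()))
    for a in spec["s_free"]:
        out.append((0, np.array([a]), np.array([1.0])))
    if "p" in spec:
        p_exps = np.array(spec["p"])
        out.append((1, p_exps, vec["p"][:, 0].copy()))
    for a in spec.get("p_free", ()):
        out.append((1, np.array([a]), np.array([1.0])))
    for a in spec.get("d_free", ()):
        out.append((2, np.array([a]), np.array([1.0])))
    return tuple(out)


def _element_shells(element, basis):
    if basis.lower() == "sto-3g":
        return [(_L_OF[l], np.array(e), np.array(c)) for l, e, c in STO3G[element]]
    if basis.lower() == "cc-pvdz":
        return [(l, e.copy(), c.copy()) for l, e, c in _ccpvdz_element_shells(element)]
    raise ValueError(f"unknown basis {basis!r}")


def build_basis(atoms, basis):
    """Build the AO basis for ``atoms`` = [(element, xyz_bohr), ...]."""
    shells = []
    labels = []
    irreps = []
    blocks = []  # per-shell Cartesian->AO blocks
    for elem, xyz in atoms:
        center = np.asarray(xyz, dtype=float)
        for l, exps, coefs in _element_shells(elem, basis):
            norms = np.array([_prim_norm(l, a) for a in exps])
            shells.append((l, center, exps, coefs * norms))
            if l == 0:
                blocks.append(np.eye(1))
                labels.append((elem, "s", ""))
                irreps.append(_IRREP[("s", 0)])
            elif l == 1:
                # cart order (x, y, z) -> AO order (z, x, y)
                B = np.zeros((3, 3))
                B[2, 0] = 1.0  # z first
                B[0, 1] = 1.0  # x
                B[1, 2] = 1.0  # y
                blocks.append(B)
                for comp, tag in enumerate(("z", "x", "y")):
                    labels.append((elem, "p", tag))
                    irreps.append(_IRREP[("p", comp)])
            elif l == 2:
                blocks.append(_C2S_D.T.copy())
                for comp, tag in enumerate(("z2", "xz", "yz", "x2-y2", "xy")):
                    labels.append((elem, "d", tag))
                    irreps.append(_IRREP[("d", comp)])
            else:  # pragma: no cover
                raise ValueError("angular momentum beyond d not supported")

    ncart = sum(b.shape[0] for b in blocks)
    nao = sum(b.shape[1] for b in blocks)
    C = np.zeros((ncart, nao))
    i = j = 0
    for b in blocks:
        C[i:i + b.shape[0], j:j + b.shape[1]] = b
        i += b.shape[0]
        j += b.shape[1]

    ab = AOBasis(shells=shells, cart2ao=C, labels=labels, irreps=irreps,
                 atoms=[(ELEMENT_Z[e], np.asarray(x, float)) for e, x in atoms])
    # normalize AOs against the actual overlap
    S, _, _, _, _ = _one_electron(shells, ab.atoms, np.zeros(3))
    Ssph = C.T @ S @ C
    ab.cart2ao = C / np.sqrt(np.diag(Ssph))[None, :]
    return ab


def _one_electron(shells, atoms, origin):
    """Cartesian S, T, V, dipole(3), second-moment(6) matrices."""
    ncart = [(s[0] + 1) * (s[0] + 2) // 2 for s in shells]
    offs = np.concatenate([[0], np.cumsum(ncart)]).astype(int)
    nao = offs[-1]
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    V = np.zeros((nao, nao))
    dip = np.zeros((3, nao, nao))
    sec = np.zeros((6, nao, nao))
    for A, (lA, cA, eA, kA) in enumerate(shells):
        for B, (lB, cB, eB, kB) in enumerate(shells):
            if B > A:
                continue
            sl = np.s_[offs[A]:offs[A + 1], offs[B]:offs[B + 1]]
            for ia, a in enumerate(eA):
                for ib, b in enumerate(eB):
                    w = kA[ia] * kB[ib]
                    s, t = mdints.overlap_kinetic(lA, lB, a, b, cA, cB)
                    v = mdints.nuclear_attraction(lA, lB, a, b, cA, cB, atoms)
                    d1, d2 = mdints.moment_integrals(lA, lB, a, b, cA, cB, origin)
                    S[sl] += w * s
                    T[sl] += w * t
                    V[sl] += w * v
                    dip[(np.s_[:],) + np.s_[sl]] += w * d1
                    sec[(np.s_[:],) + np.s_[sl]] += w * d2
            if A != B:
                S[offs[B]:offs[B + 1], offs[A]:offs[A + 1]] = S[sl].T
                T[offs[B]:offs[B + 1], offs[A]:offs[A + 1]] = T[sl].T
                V[offs[B]:offs[B + 1], offs[A]:offs[A + 1]] = V[sl].T
                for k in range(3):
                    dip[k, offs[B]:offs[B + 1], offs[A]:offs[A + 1]] = dip[k][sl].T
                for k in range(6):
                    sec[k, offs[B]:offs[B + 1], offs[A]:offs[A + 1]] = sec[k][sl].T
    return S, T, V, dip, sec


def one_electron_ao(ab: AOBasis, origin=(0.0, 0.0, 0.0)):
    """S, T, V, dipole, second moments in the final AO basis."""
    S, T, V, dip, sec = _one_electron(ab.shells, ab.atoms, np.asarray(origin))
    C = ab.cart2ao
    tr = lambda M: C.T @ M @ C
    return (tr(S), tr(T), tr(V),
            np.array([tr(dip[k]) for k in range(3)]),
            np.array([tr(sec[k]) for k in range(6)]))


def eri_ao(ab: AOBasis):
    """Two-electron integrals (chemists' notation) in the final AO basis."""
    g = mdints.eri_cartesian(ab.shells)
    C = ab.cart2ao
    g = np.einsum("pqrs,pi->iqrs", g, C, optimize=True)
    g = np.einsum("iqrs,qj->ijrs", g, C, optimize=True)
    g = np.einsum("ijrs,rk->ijks", g, C, optimize=True)
    g = np.einsum("ijks,sl->ijkl", g, C, optimize=True)
    return g


def cross_overlap(ab1: AOBasis, ab2: AOBasis):
    """Overlap matrix <AO_i(geometry 1)|AO_j(geometry 2)> (nao1 x nao2)."""
    sh1, sh2 = ab1.shells, ab2.shells
    nc1 = [(s[0] + 1) * (s[0] + 2) // 2 for s in sh1]
    nc2 = [(s[0] + 1) * (s[0] + 2) // 2 for s in sh2]
    o1 = np.concatenate([[0], np.cumsum(nc1)]).astype(int)
    o2 = np.concatenate([[0], np.cumsum(nc2)]).astype(int)
    S = np.zeros((o1[-1], o2[-1]))
    for A, (lA, cA, eA, kA) in enumerate(sh1):
        for B, (lB, cB, eB, kB) in enumerate(sh2):
            blk = np.zeros((nc1[A], nc2[B]))
            for ia, a in enumerate(eA):
                for ib, b in enumerate(eB):
                    s, _ = mdints.overlap_kinetic(lA, lB, a, b, cA, cB)
                    blk += kA[ia] * kB[ib] * s
            S[o1[A]:o1[A + 1], o2[B]:o2[B + 1]] = blk
    return ab1.cart2ao.T @ S @ ab2.cart2ao


def _geig(F, S):
    """Generalized symmetric eigenproblem F c = S c e."""
    from scipy.linalg import eigh
    e, c = eigh(F, S)
    return e, c
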