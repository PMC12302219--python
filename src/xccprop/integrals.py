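"""MO-basis Hamiltonian and property-operator containers with file I/O.

The in-memory representation every solver works from is
:class:`MolecularIntegrals` -- a dense MO-basis one-electron matrix ``h``,
two-electron tensor ``g`` in chemists' notation ``(pq|rs)``, a scalar energy
offset ``e_core`` and the active electron count.  Orbital rotations, frozen
core folding and Fock construction all live here so that pCCD, CC and CI
layers never touch AO quantities.

FCIDUMP files follow the Molpro convention: namelist header with
NORB/NELEC/MS2, 1-based ``value i j k l`` lines with 8-fold permutational
symmetry implied, ``value i j 0 0`` one-electron elements and the scalar
core energy on index ``0 0 0 0``.  Orbital symmetry labels are accepted and
ignored (C1 treatment).  Property operators are stored in a single JSON
container.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MolecularIntegrals", "PropertyOperators",
    "read_fcidump", "write_fcidump",
    "read_property_operators", "write_property_operators",
    "transform_mo", "freeze_core", "fock_matrix", "rotate_operators",
]


@dataclass
class MolecularIntegrals:
    """MO-basis Hamiltonian: E = e_core + sum h_pq gamma_pq + 1/2 sum (pq|rs) Gamma."""

    n_orb: int
    n_elec: int
    e_core: float
    h: np.ndarray
    g: np.ndarray
    mo_irrep: list = field(default_factory=list)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        n = self.n_orb
        if self.h.shape != (n, n) or self.g.shape != (n, n, n, n):
            raise ValueError("integral array shapes inconsistent with n_orb")
        if self.n_elec % 2 or self.n_elec > 2 * n or self.n_elec < 0:
            raise ValueError("n_elec must be even and <= 2*n_orb")
        if np.max(np.abs(self.h - self.h.T)) > 1e-10:
            raise ValueError("one-electron matrix not symmetric")

    def check_symmetry(self, tol=1e-10):
        g = self.g
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if np.max(np.abs(g - g.transpose(perm))) > tol:
                raise ValueError("two-electron tensor violates 8-fold symmetry")
        return True

    @property
    def n_occ(self):
        return self.n_elec // 2


@dataclass
class PropertyOperators:
    """MO-basis multipole operator matrices plus the nuclear frame.

    dip[k] = <p| r_k |q>, k in (x, y, z);
    quad[k] = <p| (3 r_a r_b - delta_ab r^2)/2 |q> for ab in
    (xx, xy, xz, yy, yz, zz); the three diagonal components sum to zero.
    """

    atoms: list                      # [(Z, xyz bohr), ...]
    dip: np.ndarray                  # (3, n, n)
    quad: np.ndarray                 # (6, n, n)

    QUAD_ORDER = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))

    def __post_init__(self):
        self.dip = np.asarray(self.dip, dtype=float)
        self.quad = np.asarray(self.quad, dtype=float)
        tr = self.quad[0] + self.quad[3] + self.quad[5]
        if np.max(np.abs(tr)) > 1e-8:
            raise ValueError("quadrupole operator matrices are not traceless")

    @property
    def mu_nuc(self):
        return sum(Z * np.asarray(R, float) for Z, R in self.atoms)

    @property
    def theta_nuc(self):
        th = np.zeros((3, 3))
        for Z, R in self.atoms:
            R = np.asarray(R, float)
            r2 = R @ R
            th += 0.5 * Z * (3.0 * np.outer(R, R) - r2 * np.eye(3))
        return th


# ----------------------------------------------------------------- FCIDUMP

def write_fcidump(ints: MolecularIntegrals, path, tol=1e-16):
    n = ints.n_orb
    orbsym = ",".join(["1"] * n)
    with open(path, "w") as f:
        f.write(f"&FCI NORB={n},NELEC={ints.n_elec},MS2=0,\n")
        f.write(f" ORBSYM={orbsym},\n ISYM=1,\n&END\n")
        g = ints.g
        for p in range(n):
            for q in range(p + 1):
                for r in range(p + 1):
                    smax = q if r == p else r
                    for s in range(smax + 1):
                        v = g[p, q, r, s]
                        if abs(v) > tol:
                            f.write(f"{v:23.16e} {p+1:3d} {q+1:3d} {r+1:3d} {s+1:3d}\n")
        for p in range(n):
            for q in range(p + 1):
                v = ints.h[p, q]
                if abs(v) > tol:
                    f.write(f"{v:23.16e} {p+1:3d} {q+1:3d}   0   0\n")
        f.write(f"{ints.e_core:23.16e}   0   0   0   0\n")
    return path


def read_fcidump(path) -> MolecularIntegrals:
    header = ""
    body_lines = []
    with open(path) as f:
        in_header = True
        for line in f:
            if in_header:
                header += " " + line.strip()
                if "&END" in line.upper() or line.strip() == "/" or line.strip().endswith("/"):
                    in_header = False
                continue
            if line.strip():
                body_lines.append(line)
    m = re.search(r"NORB\s*=\s*(\d+)", header, re.I)
    if not m:
        raise ValueError("malformed FCIDUMP header: NORB missing")
    n = int(m.group(1))
    m = re.search(r"NELEC\s*=\s*(\d+)", header, re.I)
    if not m:
        raise ValueError("malformed FCIDUMP header: NELEC missing")
    nelec = int(m.group(1))
    m = re.search(r"MS2\s*=\s*(-?\d+)", header, re.I)
    ms2 = int(m.group(1)) if m else 0
    if ms2 != 0:
        raise ValueError("only closed-shell (MS2=0) FCIDUMP files are supported")

    h = np.zeros((n, n))
    g = np.zeros((n, n, n, n))
    e_core = 0.0
    for line in body_lines:
        parts = line.split()
        v = float(parts[0].replace("D", "E").replace("d", "e"))
        p, q, r, s = (int(x) for x in parts[1:5])
        if max(p, q, r, s) > n:
            raise ValueError(f"orbital index out of range in line: {line!r}")
        if p == 0:
            e_core = v
        elif r == 0:
            i, j = p - 1, q - 1
            h[i, j] = h[j, i] = v
        else:
            i, j, k, l = p - 1, q - 1, r - 1, s - 1
            for a, b, c, d in ((i, j, k, l), (j, i, k, l), (i, j, l, k),
                               (j, i, l, k), (k, l, i, j), (l, k, i, j),
                               (k, l, j, i), (l, k, j, i)):
                g[a, b, c, d] = v
    return MolecularIntegrals(n_orb=n, n_elec=nelec, e_core=e_core, h=h, g=g)


# ------------------------------------------------------------ transformations

def transform_mo(ints: MolecularIntegrals, U: np.ndarray) -> MolecularIntegrals:
    """Rotate to a new MO basis phi'_p = sum_q phi_q U_qp (U orthogonal)."""
    U = np.asarray(U, float)
    n = ints.n_orb
    if U.shape != (n, n) or np.max(np.abs(U.T @ U - np.eye(n))) > 1e-10:
        raise ValueError("U must be an orthogonal n_orb x n_orb matrix")
    h = U.T @ ints.h @ U
    g = np.einsum("pqrs,pi->iqrs", ints.g, U, optimize=True)
    g = np.einsum("iqrs,qj->ijrs", g, U, optimize=True)
    g = np.einsum("ijrs,rk->ijks", g, U, optimize=True)
    g = np.einsum("ijks,sl->ijkl", g, U, optimize=True)
    return replace(ints, h=h, g=g, mo_irrep=[])


def rotate_operators(props: PropertyOperators, U: np.ndarray) -> PropertyOperators:
    """Apply the same orbital rotation to all property operator matrices."""
    dip = np.array([U.T @ M @ U for M in props.dip])
    quad = np.array([U.T @ M @ U for M in props.quad])
    return PropertyOperators(atoms=list(props.atoms), dip=dip, quad=quad)


def freeze_core(ints: MolecularIntegrals, n_frozen: int) -> MolecularIntegrals:
    """Fold the first n_frozen doubly occupied orbitals into e_core/h."""
    if n_frozen == 0:
        return ints
    if n_frozen >= ints.n_elec // 2:
        raise ValueError("cannot freeze all occupied orbitals")
    c = np.arange(n_frozen)
    a = np.arange(n_frozen, ints.n_orb)
    g = ints.g
    e_core = ints.e_core + 2.0 * np.trace(ints.h[np.ix_(c, c)])
    Jcc = np.einsum("ccdd->", g[np.ix_(c, c, c, c)])
    Kcc = np.einsum("cddc->", g[np.ix_(c, c, c, c)])
    e_core += 2.0 * Jcc - Kcc
    h = ints.h[np.ix_(a, a)].copy()
    h += 2.0 * np.einsum("pqcc->pq", g[np.ix_(a, a, c, c)])
    h -= np.einsum("pccq->pq", g[np.ix_(a, c, c, a)])
    return MolecularIntegrals(
        n_orb=len(a), n_elec=ints.n_elec - 2 * n_frozen, e_core=e_core,
        h=h, g=g[np.ix_(a, a, a, a)].copy(),
        mo_irrep=[ints.mo_irrep[i] for i in a] if ints.mo_irrep else [])


def fock_matrix(ints: MolecularIntegrals, n_occ: int) -> np.ndarray:
    """Closed-shell Fock matrix f_pq = h_pq + sum_i [2(pq|ii) - (pi|iq)]."""
    o = np.arange(n_occ)
    f = ints.h.copy()
    f += 2.0 * np.einsum("pqii->pq", ints.g[:, :, o][:, :, :, o])
    f -= np.einsum("piiq->pq", ints.g[:, o][:, :, o, :])
    return f


def reference_energy(ints: MolecularIntegrals) -> float:
    """Energy of the closed-shell reference determinant."""
    o = np.arange(ints.n_occ)
    e = ints.e_core + 2.0 * np.trace(ints.h[np.ix_(o, o)])
    goo = ints.g[np.ix_(o, o, o, o)]
    e += 2.0 * np.einsum("iijj->", goo) - np.einsum("ijji->", goo)
    return float(e)


# ------------------------------------------------------- property-file I/O

def write_property_operators(props: PropertyOperators, path):
    data = {
        "atoms": [[float(Z), list(map(float, R))] for Z, R in props.atoms],
        "dip": [M.tolist() for M in props.dip],
        "quad": [M.tolist() for M in props.quad],
    }
    with open(path, "w") as f:
        json.dump(data, f)
    return path


def read_property_operators(path) -> PropertyOperators:
    with open(path) as f:
        data = json.load(f)
    atoms = [(Z, np.array(R)) for Z, R in data["atoms"]]
    return PropertyOperators(atoms=atoms,
                             dip=np.array(data["dip"]),
                             quad=np.array(data["quad"]))
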