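"""Fixture generation: molecules -> MO-basis Hamiltonians + property operators.

Geometry conventions follow the diatomic placement used throughout the
package: molecules on the z axis, H at the origin for HF with F on +z.
All quantities are atomic units internally; bond lengths in the public API
are Angstrom where noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import basis as _basis
from . import scf as _scf
from .integrals import MolecularIntegrals, PropertyOperators

__all__ = ["make_system", "System", "ANGSTROM"]

ANGSTROM = 1.8897259886  # bohr per Angstrom


@dataclass
class System:
    ints: MolecularIntegrals
    props: PropertyOperators
    scf: _scf.SCFResult
    name: str


def _mo_transform_all(ab, scfres, charge):
    C = scfres.mo_coeff
    S, T, V, dip_ao, sec_ao = _basis.one_electron_ao(ab)
    g_ao = _basis.eri_ao(ab)
    h = C.T @ (T + V) @ C
    g = np.einsum("pqrs,pi->iqrs", g_ao, C, optimize=True)
    g = np.einsum("iqrs,qj->ijrs", g, C, optimize=True)
    g = np.einsum("ijrs,rk->ijks", g, C, optimize=True)
    g = np.einsum("ijks,sl->ijkl", g, C, optimize=True)
    nelec = sum(int(Z) for Z, _ in ab.atoms) - charge
    ints = MolecularIntegrals(n_orb=ab.nao, n_elec=nelec,
                              e_core=scfres.e_nuc, h=h, g=g,
                              mo_irrep=list(scfres.mo_irrep))
    dip = np.array([C.T @ M @ C for M in dip_ao])
    # traceless quadrupole operator (3 r_a r_b - delta r^2)/2 from raw moments
    # sec order: xx, xy, xz, yy, yz, zz
    r2 = sec_ao[0] + sec_ao[3] + sec_ao[5]
    quad_ao = np.empty_like(sec_ao)
    for k, (a, b) in enumerate(PropertyOperators.QUAD_ORDER):
        q = 1.5 * sec_ao[k]
        if a == b:
            q = q - 0.5 * r2
        quad_ao[k] = q
    quad = np.array([C.T @ M @ C for M in quad_ao])
    props = PropertyOperators(atoms=list(ab.atoms), dip=dip, quad=quad)
    return ints, props


def _spec_for(name, r=None):
    name = name.lower()
    if name == "h2_sto3g":
        rr = 1.4 if r is None else r
        atoms = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, rr))]
        bas, chg = "sto-3g", 0
    elif name in ("heh+_sto3g", "hehp_sto3g"):
        rr = 1.4632 if r is None else r
        atoms = [("He", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, rr))]
        bas, chg = "sto-3g", 1
    elif name == "h2o_sto3g":
        roh = 0.9572 * ANGSTROM
        ang = np.deg2rad(104.52)
        x = roh * np.sin(ang / 2)
        z = roh * np.cos(ang / 2)
        atoms = [("O", (0.0, 0.0, 0.0)),
                 ("H", (x, 0.0, z)), ("H", (-x, 0.0, z))]
        bas, chg = "sto-3g", 0
    elif name == "hf_ccpvdz":
        rr = (0.917 if r is None else r) * ANGSTROM
        atoms = [("H", (0.0, 0.0, 0.0)), ("F", (0.0, 0.0, rr))]
        bas, chg = "cc-pvdz", 0
    else:
        raise ValueError(f"unknown system {name!r}")
    return atoms, bas, chg


def _basis_for(name, r=None):
    atoms, bas, _ = _spec_for(name, r)
    return _basis.build_basis(atoms, bas)


def make_system(name, r=None, charge=None) -> System:
    """Build one of the named test systems.

    name in {"h2_sto3g", "heh+_sto3g", "h2o_sto3g", "hf_ccpvdz"};
    ``r`` (Angstrom for hf_ccpvdz, bohr otherwise) overrides the default
    bond length for the diatomics.
    """
    atoms, bas, chg = _spec_for(name, r)
    if charge is not None:
        chg = charge
    ab = _basis.build_basis(atoms, bas)
    res = _scf.rhf(ab, charge=chg)
    if not res.converged:
        raise RuntimeError(f"SCF failed to converge for {name}")
    ints, props = _mo_transform_all(ab, res, chg)
    return System(ints=ints, props=props, scf=res, name=name)
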