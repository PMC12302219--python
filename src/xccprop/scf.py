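"""Closed-shell restricted Hartree-Fock over the in-repo AO engine.

For molecules whose nuclei all lie on the z axis the SCF is solved per
C2v symmetry block (the AO sets of different irreps are strictly
decoupled), which keeps degenerate pi orbitals symmetry-pure -- important
for the symmetry-restricted large-scale CI downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from . import basis as _basis

__all__ = ["rhf", "SCFResult"]


@dataclass
class SCFResult:
    energy: float
    mo_coeff: np.ndarray      # AO x MO
    mo_energy: np.ndarray
    mo_irrep: list            # per-MO irrep label ("a1" ... or "" in C1)
    n_occ: int
    converged: bool
    dipole: np.ndarray        # SCF dipole (a.u., electronic+nuclear)
    e_nuc: float


def _nuclear_repulsion(atoms):
    e = 0.0
    for i, (Zi, Ri) in enumerate(atoms):
        for Zj, Rj in atoms[i + 1:]:
            e += Zi * Zj / np.linalg.norm(np.asarray(Ri) - np.asarray(Rj))
    return e


def _on_z_axis(atoms):
    return all(abs(R[0]) < 1e-12 and abs(R[1]) < 1e-12 for _, R in atoms)


def rhf(ab: _basis.AOBasis, charge=0, conv=1e-10, max_cycle=200):
    """Solve RHF; returns an :class:`SCFResult` with symmetry-pure MOs."""
    S, T, V, dip, _ = _basis.one_electron_ao(ab)
    g = _basis.eri_ao(ab)
    h = T + V
    nelec = sum(int(Z) for Z, _ in ab.atoms) - charge
    if nelec % 2:
        raise ValueError("RHF requires an even electron count")
    n_occ = nelec // 2
    e_nuc = _nuclear_repulsion(ab.atoms)
    nao = ab.nao

    use_sym = _on_z_axis(ab.atoms)
    if use_sym:
        blocks = {}
        for i, ir in enumerate(ab.irreps):
            blocks.setdefault(ir, []).append(i)
        blocks = {k: np.array(v) for k, v in blocks.items()}
    else:
        blocks = {"": np.arange(nao)}

    def diag(F):
        e_all = np.empty(nao)
        c_all = np.zeros((nao, nao))
        ir_all = [""] * nao
        col = 0
        for ir, idx in blocks.items():
            e, c = eigh(F[np.ix_(idx, idx)], S[np.ix_(idx, idx)])
            for k in range(len(idx)):
                e_all[col] = e[k]
                c_all[idx, col] = c[:, k]
                ir_all[col] = ir
                col += 1
        order = np.argsort(e_all, kind="stable")
        return e_all[order], c_all[:, order], [ir_all[o] for o in order]

    e_mo, C, irs = diag(h)
    D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    e_old = 0.0
    diis_F, diis_err = [], []
    converged = False
    for cyc in range(max_cycle):
        J = np.einsum("pqrs,rs->pq", g, D, optimize=True)
        K = np.einsum("prqs,rs->pq", g, D, optimize=True)
        F = h + J - 0.5 * K
        err = F @ D @ S - S @ D @ F
        diis_F.append(F.copy())
        diis_err.append(err.ravel())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            n = len(diis_F)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = diis_err[i] @ diis_err[j]
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:n]
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
            except np.linalg.LinAlgError:
                pass
        e_mo, C, irs = diag(F)
        D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        e_el = 0.5 * np.sum(D * (h + F)) if False else np.sum(D * h) + 0.5 * np.sum(
            D * (np.einsum("pqrs,rs->pq", g, D, optimize=True)
                 - 0.5 * np.einsum("prqs,rs->pq", g, D, optimize=True)))
        if abs(e_el - e_old) < conv and np.max(np.abs(err)) < 1e-7:
            converged = True
            break
        e_old = e_el

    mu_nuc = sum(Z * np.asarray(R) for Z, R in ab.atoms)
    mu = mu_nuc - np.array([np.sum(D * dip[k]) for k in range(3)])
    return SCFResult(energy=e_el + e_nuc, mo_coeff=C, mo_energy=e_mo,
                     mo_irrep=irs, n_occ=n_occ, converged=converged,
                     dipole=mu, e_nuc=e_nuc)
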