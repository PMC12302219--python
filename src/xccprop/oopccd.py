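"""Variational orbital optimization of pCCD (oo-pCCD).

The pCCD Lagrangian E + sum lam*R is stationary in the amplitudes and
multipliers, so its orbital derivative is the plain contraction of the
response RDMs with derivative integrals: g = 2(F^T - F) with the
generalized Fock F built from the (diagonal) one-particle and
seniority-zero two-particle response densities.  Orbitals are updated as
U <- U exp(kappa) with an approximate-Newton step (diagonal curvature,
SCF-like for occ-virt rotations) protected by a backtracking line search;
all rotation classes are active because pCCD is not invariant under
occupied-occupied or virtual-virtual rotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .integrals import (MolecularIntegrals, PropertyOperators, fock_matrix,
                        rotate_operators, transform_mo)
from . import pccd as _pccd

__all__ = ["OrbitalSolution", "orbital_gradient", "optimize_orbitals"]


@dataclass
class OrbitalSolution:
    U: np.ndarray
    ints_rotated: MolecularIntegrals
    props_rotated: PropertyOperators | None
    amps: _pccd.PairAmplitudes
    grad_norm: float
    energy: float
    macro_iterations: int
    converged: bool


def orbital_gradient(ints: MolecularIntegrals, rdms: _pccd.SZRDMs):
    """Antisymmetric orbital-rotation gradient 2(F^T - F).

    F_pq = gamma_pp h_pq + sum_m [4 N_pm (qp|mm) - 2 N_pm (qm|mp)
           + 2 Psym_pm (qm|pm)] + 2 nu_p (qp|pp).
    """
    n = ints.n_orb
    h, g = ints.h, ints.g
    nu, N = rdms.nu, rdms.nunu
    P = 0.5 * (rdms.pairP + rdms.pairP.T)
    gam = 2.0 * nu

    F = gam[:, None] * h.T  # F_pq = gamma_pp h_qp (h symmetric)
    gA = np.einsum("qpmm->pqm", g)
    gB = np.einsum("qmmp->pqm", g)
    gC = np.einsum("qmpm->pqm", g)
    Nno = N - np.diag(np.diag(N))
    Poff = P - np.diag(np.diag(P))
    F += 4.0 * np.einsum("pqm,pm->pq", gA, Nno)
    F -= 2.0 * np.einsum("pqm,pm->pq", gB, Nno)
    F += 2.0 * np.einsum("pqm,pm->pq", gC, Poff)
    F += 2.0 * nu[:, None] * np.einsum("qppp->pq", g)
    return 2.0 * (F.T - F)


def _solve_at(ints, t0=None):
    amps = _pccd.solve_pccd(ints, t0=t0)
    amps = _pccd.solve_pccd_lambda(ints, amps)
    rdms = _pccd.pccd_response_rdms(amps, ints.n_orb)
    return amps, rdms


def _dexp_correct(kappa, G, order=12):
    """Exact gradient transport to exp coordinates: sum_k ad_kappa^k G /(k+1)!."""
    out = G.copy()
    term = G.copy()
    for k in range(1, order + 1):
        term = (kappa @ term - term @ kappa) / (k + 1.0)
        out += term
        if np.max(np.abs(term)) < 1e-15:
            break
    return out


def optimize_orbitals(ints: MolecularIntegrals,
                      props: PropertyOperators | None = None,
                      start: np.ndarray | None = None,
                      gtol=1e-6, max_macro=400,
                      restarts=2, perturb=0.05, seed=12345) -> OrbitalSolution:
    """Minimize the pCCD energy over orthogonal orbital rotations.

    The search runs in exponential coordinates U = U_start exp(kappa) with
    L-BFGS; the chain-rule factor d(exp kappa) is applied exactly, so the
    optimizer sees consistent gradients at every point.  ``start`` warm
    starts a geometry scan with the previous point's rotation.

    Cold starts apply small seeded random rotations and keep the lowest of
    ``restarts`` runs: the canonical-orbital point is typically a *symmetric
    saddle* of the pCCD energy (the variational optimum breaks spatial
    symmetry toward localized orbitals), and an exactly symmetric start
    would never leave it.
    """
    from scipy.optimize import minimize

    if start is None and restarts > 0:
        rng = np.random.default_rng(seed)
        best = None
        n = ints.n_orb
        for _ in range(restarts):
            W = rng.standard_normal((n, n)) * perturb
            U0 = expm(0.5 * (W - W.T))
            sol = optimize_orbitals(ints, props, start=U0, gtol=gtol,
                                    max_macro=max_macro, restarts=0)
            if best is None or sol.energy < best.energy - 1e-10:
                best = sol
        return best

    n = ints.n_orb
    iu = np.triu_indices(n, k=1)
    base = transform_mo(ints, start) if start is not None else ints
    U0 = np.eye(n) if start is None else start.copy()

    # diagonal curvature estimate for preconditioning (SCF-like occ-virt)
    amps0, rdms0 = _solve_at(base)
    f0 = np.diag(fock_matrix(base, ints.n_occ))
    gam0 = 2.0 * rdms0.nu
    Hd = np.abs((gam0[:, None] - gam0[None, :]) * (f0[None, :] - f0[:, None])) * 2.0
    Hd = np.maximum(Hd, 0.2)
    scale = 1.0 / np.sqrt(Hd[iu])

    state = {"t0": amps0.t, "neval": 1}

    def unpack(y):
        kappa = np.zeros((n, n))
        kappa[iu] = y * scale
        return kappa - kappa.T

    def fg(y):
        kappa = unpack(y)
        U = expm(kappa)
        cur = transform_mo(base, U)
        amps, rdms = _solve_at(cur, t0=state["t0"])
        state["t0"] = amps.t
        state["neval"] += 1
        state["last"] = (U, cur, amps, rdms)
        G = orbital_gradient(cur, rdms)
        Gx = _dexp_correct(kappa, G)
        return amps.e_total, Gx[iu] * scale

    y = np.zeros(len(iu[0]))
    U, cur, amps, rdms = np.eye(n), base, amps0, rdms0
    gnorm = float(np.max(np.abs(orbital_gradient(base, rdms0))))
    for attempt in range(6):
        if gnorm < gtol:
            break
        res = minimize(fg, y, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_macro, "gtol": 1e-14,
                                "ftol": 1e-15, "maxcor": 30})
        y = res.x
        fg(y)
        U, cur, amps, rdms = state["last"]
        gnorm = float(np.max(np.abs(orbital_gradient(cur, rdms))))
    Utot = U0 @ U
    props_rot = rotate_operators(props, Utot) if props is not None else None
    return OrbitalSolution(U=Utot, ints_rotated=cur, props_rotated=props_rot,
                           amps=amps, grad_norm=gnorm, energy=amps.e_total,
                           macro_iterations=state["neval"],
                           converged=gnorm < gtol)
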