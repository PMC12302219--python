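"""pair-CCD (pCCD / AP1roG): amplitudes, Lagrange multipliers, response RDMs.

The pCCD wave function is |Psi> = exp(T_p)|0> with T_p containing only
electron-pair double excitations i-ibar -> a-abar.  Projecting
exp(-T_p) H exp(T_p) onto the pair-excited determinants gives residual
equations that involve only the seniority-zero integral slices
J_pq = (pp|qq), K_pq = (pq|qp) and the Fock diagonal, and are quadratic in
the amplitudes.  The closed-form residual used here was derived from the
hard-core-boson representation of the seniority-zero sector and is verified
against the brute-force determinant oracle in the test suite:

  R_ia = K_ia + D_ia t_ia
         + sum_{b!=a} K_ab t_ib + sum_{j!=i} K_ij t_ja
         - 2 t_ia [ sum_b K_ib t_ib + sum_j K_ja t_ja - K_ia t_ia ]
         + sum_{jb} K_jb t_ib t_ja

with the diagonal pair-excitation energy
  D_ia = 2(f_aa - f_ii) + J_aa + J_ii - 4 J_ia + 2 K_ia.

The Lagrange multipliers solve the linear system J^T lam = -K_ov with the
exact amplitude Jacobian J (the residual is quadratic, so the Jacobian is
analytic).  Response (Lagrangian) reduced density matrices follow from
<0|(1+Lambda) exp(-T) ... exp(T)|0>; the one-particle density is diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals import MolecularIntegrals, fock_matrix, reference_energy

__all__ = ["PairAmplitudes", "solve_pccd", "solve_pccd_lambda",
           "pccd_response_rdms", "SZRDMs"]


@dataclass
class PairAmplitudes:
    t: np.ndarray                     # occ x virt
    lam: np.ndarray | None = None
    converged: bool = False
    residual_norm: float = np.inf
    e_corr: float = 0.0
    e_total: float = 0.0
    n_occ: int = 0


def seniority_slices(ints: MolecularIntegrals):
    """J_pq=(pp|qq), K_pq=(pq|qp), Fock diagonal f_pp."""
    g = ints.g
    J = np.einsum("ppqq->pq", g)
    K = np.einsum("pqqp->pq", g)
    f = np.diag(fock_matrix(ints, ints.n_occ))
    return J, K, f


def _residual(t, J, K, f, no):
    nv = t.shape[1]
    o = slice(0, no)
    v = slice(no, no + nv)
    Kov = K[o, v]
    Kvv = K[v, v]
    Koo = K[o, o]
    D = (2.0 * (f[v][None, :] - f[o][:, None])
         + np.diag(J[v, v])[None, :] + np.diag(J[o, o])[:, None]
         - 4.0 * J[o, v] + 2.0 * K[o, v])
    R = Kov + D * t
    R += t @ (Kvv - np.diag(np.diag(Kvv)))
    R += (Koo - np.diag(np.diag(Koo))) @ t
    R -= 2.0 * t * ((t * Kov).sum(axis=1, keepdims=True)
                    + (Kov * t).sum(axis=0, keepdims=True)
                    - Kov * t)
    R += (t @ Kov.T) @ t
    return R, D


def _jacobian(t, J, K, f, no):
    """Exact Jacobian d R_ia / d t_jb as (no*nv, no*nv)."""
    nv = t.shape[1]
    o = slice(0, no)
    v = slice(no, no + nv)
    Kov = K[o, v]
    Kvv = K[v, v] - np.diag(np.diag(K[v, v]))
    Koo = K[o, o] - np.diag(np.diag(K[o, o]))
    _, D = _residual(t, J, K, f, no)
    Jm = np.zeros((no, nv, no, nv))
    idx_o = np.arange(no)
    idx_v = np.arange(nv)
    # diagonal + linear couplings
    Jm[idx_o[:, None], idx_v[None, :], idx_o[:, None], idx_v[None, :]] += D
    for i in range(no):
        Jm[i, :, i, :] += Kvv.T  # d/dt_ib of sum_b' t_ib' Kvv[b',a]
    for a in range(nv):
        Jm[:, a, :, a] += Koo  # careful: symmetric Koo
    # quadratic terms
    rowsum = (t * Kov).sum(axis=1)
    colsum = (Kov * t).sum(axis=0)
    for i in range(no):
        for a in range(nv):
            Jm[i, a, i, a] += -2.0 * (rowsum[i] + colsum[a] - Kov[i, a] * t[i, a])
            # -2 t_ia d/dt_jb [...]
            Jm[i, a, i, :] += -2.0 * t[i, a] * Kov[i, :]
            Jm[i, a, :, a] += -2.0 * t[i, a] * Kov[:, a]
            Jm[i, a, i, a] += 2.0 * t[i, a] * Kov[i, a]
    # d/dt_jb of sum_{j'b'} K_j'b' t_ib' t_j'a = [i==j] sum_j' K_j'b t_j'a
    #                                          + [a==b] sum_b' K_jb' t_ib'
    M1 = Kov.T @ t          # (nv, nv): M1[b, a] = sum_j' K_j'b t_j'a
    M2 = t @ Kov.T          # (no, no): M2[i, j] = sum_b' t_ib' K_jb'
    for i in range(no):
        Jm[i, :, i, :] += M1.T
    for a in range(nv):
        Jm[:, a, :, a] += M2
    return Jm.reshape(no * nv, no * nv)


def solve_pccd(ints: MolecularIntegrals, n_occ=None, tol=1e-8, max_iter=200,
               diis_size=6, t0=None) -> PairAmplitudes:
    """Solve the pCCD amplitude equations by preconditioned quasi-Newton + DIIS."""
    no = ints.n_occ if n_occ is None else n_occ
    nv = ints.n_orb - no
    J, K, f = seniority_slices(ints)
    o = slice(0, no)
    v = slice(no, no + nv)
    denom = 2.0 * (f[o][:, None] - f[v][None, :])
    denom = np.where(np.abs(denom) < 1e-3, denom - 1e-3 * np.sign(denom + 1e-300), denom)
    t = (K[o, v] / denom) if t0 is None else t0.copy()

    e_ref = reference_energy(ints)
    trace = []
    tvecs, evecs = [], []
    e_old = np.inf
    for it in range(max_iter):
        R, D = _residual(t, J, K, f, no)
        rnorm = np.max(np.abs(R))
        e_corr = float(np.sum(K[o, v] * t))
        trace.append((it, rnorm, e_corr))
        if np.max(np.abs(t)) > 1e3:
            raise RuntimeError(f"pCCD amplitudes diverged (|t|>1e3) at iteration {it}")
        if rnorm < tol and abs(e_corr - e_old) < 1e-10:
            return PairAmplitudes(t=t, converged=True, residual_norm=rnorm,
                                  e_corr=e_corr, e_total=e_ref + e_corr, n_occ=no)
        e_old = e_corr
        prec = -D.copy()
        prec[np.abs(prec) < 1e-3] = 1e-3
        t = t + R / prec
        tvecs.append(t.ravel().copy())
        evecs.append((R / prec).ravel().copy())
        if len(tvecs) > diis_size:
            tvecs.pop(0)
            evecs.pop(0)
        if len(tvecs) > 1:
            n = len(tvecs)
            B = np.empty((n + 1, n + 1))
            B[:n, :n] = np.array([[ei @ ej for ej in evecs] for ei in evecs])
            B[n, :] = B[:, n] = -1.0
            B[n, n] = 0.0
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:n]
                t = sum(wi * np.asarray(ti) for wi, ti in zip(w, tvecs)).reshape(no, nv)
            except np.linalg.LinAlgError:
                pass
    raise RuntimeError(
        f"pCCD did not converge in {max_iter} iterations "
        f"(last residual {trace[-1][1]:.2e}); trace={trace[-5:]}")


def solve_pccd_lambda(ints: MolecularIntegrals, amps: PairAmplitudes) -> PairAmplitudes:
    """Solve the linear Lambda equations J^T lam = -dE/dt."""
    if not amps.converged:
        raise ValueError("Lambda equations need converged pCCD amplitudes")
    no = amps.n_occ
    nv = amps.t.shape[1]
    J, K, f = seniority_slices(ints)
    Jac = _jacobian(amps.t, J, K, f, no)
    rhs = -K[:no, no:].ravel()
    try:
        lam = np.linalg.solve(Jac.T, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular pCCD Jacobian: degenerate pair spectrum") from exc
    amps.lam = lam.reshape(no, nv)
    return amps


@dataclass
class SZRDMs:
    """Seniority-zero response RDM pieces of the pCCD Lagrangian state.

    nu[p]      = <nu_p>            (pair occupation, 0..1)
    nunu[p,q]  = <nu_p nu_q>       (p != q meaningful)
    pairP[p,q] = <P_p^dag P_q>     (pair transfer q -> p)
    gamma      = spin-summed 1-RDM (diagonal, 2*nu)
    """

    nu: np.ndarray
    nunu: np.ndarray
    pairP: np.ndarray
    n_occ: int

    @property
    def gamma(self):
        return np.diag(2.0 * self.nu)


def pccd_response_rdms(amps: PairAmplitudes, n_orb: int) -> SZRDMs:
    if amps.lam is None:
        raise ValueError("response RDMs require Lambda amplitudes")
    no = amps.n_occ
    nv = n_orb - no
    t, lam = amps.t, amps.lam
    lt = float(np.sum(lam * t))

    nu = np.zeros(n_orb)
    nu[:no] = 1.0 - (lam * t).sum(axis=1)
    nu[no:] = (lam * t).sum(axis=0)

    nunu = np.zeros((n_orb, n_orb))
    occ_dep = (lam * t).sum(axis=1)          # per occupied i
    for j in range(no):
        for k in range(no):
            if j != k:
                nunu[j, k] = 1.0 - occ_dep[j] - occ_dep[k]
    # occ j, virt b: sum_{i != j} lam_ib t_ib
    ov = np.einsum("ib,ib->b", lam, t)[None, :] - lam * t
    nunu[:no, no:] = ov
    nunu[no:, :no] = ov.T
    # virt-virt: zero at this truncation

    P = np.zeros((n_orb, n_orb))
    # occ-virt block <b_i^dag b_a> (de-excitation expectation)
    P_ov = (1.0 - lt) * t
    P_ov += np.einsum("jb,jb,ia->ia", lam, t, t)
    P_ov += np.einsum("jb,ja,ib->ia", lam, t, t)
    # remove j==i and b==a double-counted pieces of the (j!=i, b!=a) sum
    P_ov -= np.einsum("ib,ib,ia->ia", lam, t, t) + np.einsum("ib,ia,ib->ia", lam, t, t)
    P_ov -= np.einsum("ja,ja,ia->ia", lam, t, t) + np.einsum("ja,ia,ja->ia", lam, t, t)
    P_ov += 2.0 * lam * t * t
    P[:no, no:] = P_ov
    P[no:, :no] = lam.T
    # occ-occ (l != k): sum_b lam_kb t_lb
    Poo = t @ lam.T            # Poo[l,k] = sum_b t_lb lam_kb
    P[:no, :no] = Poo - np.diag(np.diag(Poo))
    # virt-virt (d != c): sum_j lam_jd t_jc
    Pvv = lam.T @ t            # Pvv[d,c] = sum_j lam_jd t_jc
    P[no:, no:] = Pvv - np.diag(np.diag(Pvv))
    # diagonals of P coincide with nu
    P[np.arange(no), np.arange(no)] = nu[:no]
    P[np.arange(no, n_orb), np.arange(no, n_orb)] = nu[no:]

    return SZRDMs(nu=nu, nunu=nunu, pairP=P, n_occ=no)


def sz_energy(ints: MolecularIntegrals, rdms: SZRDMs) -> float:
    """Total energy from the seniority-zero RDM pieces (cross-check)."""
    J = np.einsum("ppqq->pq", ints.g)
    K = np.einsum("pqqp->pq", ints.g)
    h = np.diag(ints.h)
    n = ints.n_orb
    off = ~np.eye(n, dtype=bool)
    e = ints.e_core
    e += np.sum((2.0 * h + np.diag(J)) * rdms.nu)
    e += np.sum(((2.0 * J - K) * rdms.nunu)[off])
    e += np.sum((K * rdms.pairP)[off])
    return float(e)
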