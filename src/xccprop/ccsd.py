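"""Spin-orbital CC solvers: CCD, CCSD, fpCCD, fpCCSD, fpLCCD, fpLCCSD.

All variants are defined projectively, <mu| e^-T H e^T |0> = 0 over the
variant's excitation manifold, and all share one residual routine written
in the antisymmetrized spin-orbital representation (standard
Stanton-Gauss-Watts-Bartlett intermediates with the *full* Fock matrix, so
the routine returns the true projective residual also for non-canonical
orbitals such as the pCCD-optimized basis).  Spin-free amplitudes are
exposed for the density layer: t2[i,j,a,b] = t2so[i-alpha, j-beta, a-alpha,
b-beta], which maps the electron-pair channel onto t2[i,i,a,a].

Frozen-pair (fp) variants seed the pair channel from converged pCCD
amplitudes and never update it; the linearized variants (fpLCC) solve the
equations of (H + [H, T'])|Psi_pCCD> = E|Psi_pCCD> -- the residual linear
in the external amplitudes -- evaluated exactly by complex-step
linearization of the full residual around T'=0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import MolecularIntegrals, fock_matrix, reference_energy
from .pccd import PairAmplitudes

__all__ = ["ClusterAmplitudes", "solve_cc", "solve_fpcc", "solve_fplcc"]


@dataclass
class ClusterAmplitudes:
    t1so: np.ndarray            # (O, V) spin-orbital singles
    t2so: np.ndarray            # (O, O, V, V) antisymmetrized doubles
    n_occ: int                  # spatial occupied count
    method_tag: str
    e_corr: float
    e_total: float
    converged: bool
    residual_norm: float
    pair_frozen: bool = False
    pair_source: np.ndarray | None = None

    @property
    def t1(self):
        """Spin-free singles t_i^a (None-like zeros for doubles-only models)."""
        return self.t1so[0::2, 0::2].real.copy()

    @property
    def t2(self):
        """Spin-free doubles t_ij^ab."""
        return self.t2so[0::2, 1::2, 0::2, 1::2].real.copy()

    @property
    def has_singles(self):
        return "sd" in self.method_tag or self.method_tag == "ccsd"


def spin_orbital_ints(ints: MolecularIntegrals):
    """Spin-orbital Fock and antisymmetrized <pq||rs> (interleaved spins)."""
    n = ints.n_orb
    f_sp = fock_matrix(ints, ints.n_occ)
    nso = 2 * n
    f = np.zeros((nso, nso))
    f[0::2, 0::2] = f_sp
    f[1::2, 1::2] = f_sp
    # <pq|rs> = (pr|qs) delta(sp,sr) delta(sq,ss)
    g = ints.g
    phys = np.zeros((nso, nso, nso, nso))
    for sp in (0, 1):
        for sq in (0, 1):
            phys[sp::2, sq::2, sp::2, sq::2] = g.transpose(0, 2, 1, 3)
    eri = phys - phys.transpose(0, 1, 3, 2)
    return f, eri


def _residual(f, eri, t1, t2, no):
    """Projective CCSD residuals (R1, R2) with full (non-canonical) f."""
    o = slice(0, no)
    v = slice(no, None)
    dt = np.result_type(f, t1, t2)
    fov = f[o, v].astype(dt)
    tau_t = t2 + 0.5 * (np.einsum("ia,jb->ijab", t1, t1)
                        - np.einsum("ib,ja->ijab", t1, t1))
    tau = t2 + (np.einsum("ia,jb->ijab", t1, t1)
                - np.einsum("ib,ja->ijab", t1, t1))

    Fae = f[v, v].astype(dt) - 0.5 * np.einsum("me,ma->ae", fov, t1)
    Fae += np.einsum("mf,mafe->ae", t1, eri[o, v, v, v])
    Fae -= 0.5 * np.einsum("mnaf,mnef->ae", tau_t, eri[o, o, v, v])

    Fmi = f[o, o].astype(dt) + 0.5 * np.einsum("ie,me->mi", t1, fov)
    Fmi += np.einsum("ne,mnie->mi", t1, eri[o, o, o, v])
    Fmi += 0.5 * np.einsum("inef,mnef->mi", tau_t, eri[o, o, v, v])

    Fme = fov + np.einsum("nf,mnef->me", t1, eri[o, o, v, v])

    Wmnij = eri[o, o, o, o].astype(dt)
    x = np.einsum("je,mnie->mnij", t1, eri[o, o, o, v])
    Wmnij += x - np.einsum("ie,mnje->mnij", t1, eri[o, o, o, v])
    Wmnij += 0.25 * np.einsum("ijef,mnef->mnij", tau, eri[o, o, v, v])

    Wabef = eri[v, v, v, v].astype(dt)
    y = np.einsum("mb,amef->abef", t1, eri[v, o, v, v])
    Wabef += -y + np.einsum("ma,bmef->abef", t1, eri[v, o, v, v])
    Wabef += 0.25 * np.einsum("mnab,mnef->abef", tau, eri[o, o, v, v])

    Wmbej = eri[o, v, v, o].astype(dt)
    Wmbej += np.einsum("jf,mbef->mbej", t1, eri[o, v, v, v])
    Wmbej -= np.einsum("nb,mnej->mbej", t1, eri[o, o, v, o])
    Wmbej -= np.einsum("jnfb,mnef->mbej", 0.5 * t2
                       + np.einsum("jf,nb->jnfb", t1, t1), eri[o, o, v, v])

    # --- singles residual
    R1 = fov.copy()
    R1 += np.einsum("ie,ae->ia", t1, Fae) - np.einsum("ma,mi->ia", t1, Fmi)
    R1 += np.einsum("imae,me->ia", t2, Fme)
    R1 -= np.einsum("nf,naif->ia", t1, eri[o, v, o, v])
    R1 -= 0.5 * np.einsum("imef,maef->ia", t2, eri[o, v, v, v])
    R1 -= 0.5 * np.einsum("mnae,nmei->ia", t2, eri[o, o, v, o])

    # --- doubles residual
    R2 = eri[o, o, v, v].astype(dt)
    x = np.einsum("ijae,be->ijab", t2, Fae - 0.5 * np.einsum("mb,me->be", t1, Fme))
    R2 += x - x.transpose(0, 1, 3, 2)
    x = np.einsum("imab,mj->ijab", t2, Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme))
    R2 -= x - x.transpose(1, 0, 2, 3)
    R2 += 0.5 * np.einsum("mnab,mnij->ijab", tau, Wmnij)
    R2 += 0.5 * np.einsum("ijef,abef->ijab", tau, Wabef)
    x = (np.einsum("imae,mbej->ijab", t2, Wmbej)
         - np.einsum("ie,ma,mbej->ijab", t1, t1, eri[o, v, v, o]))
    x = x - x.transpose(0, 1, 3, 2)
    x = x - x.transpose(1, 0, 2, 3)
    R2 += x
    x = np.einsum("ie,abej->ijab", t1, eri[v, v, v, o])
    R2 += x - x.transpose(1, 0, 2, 3)
    x = np.einsum("ma,mbij->ijab", t1, eri[o, v, o, o])
    R2 -= x - x.transpose(0, 1, 3, 2)
    return R1, R2


def _cc_energy(f, eri, t1, t2, no):
    o = slice(0, no)
    v = slice(no, None)
    e = np.einsum("ia,ia->", f[o, v], t1)
    e += 0.25 * np.einsum("ijab,ijab->", eri[o, o, v, v], t2)
    e += 0.5 * np.einsum("ijab,ia,jb->", eri[o, o, v, v], t1, t1)
    return e


def _pair_mask(no_sp, nv_sp):
    """Boolean mask of the electron-pair channel in spin-orbital t2."""
    O, V = 2 * no_sp, 2 * nv_sp
    m = np.zeros((O, O, V, V), dtype=bool)
    for i in range(no_sp):
        for a in range(nv_sp):
            ia, ib = 2 * i, 2 * i + 1
            aa, ab = 2 * a, 2 * a + 1
            for (x, y) in ((ia, ib), (ib, ia)):
                for (u, w) in ((aa, ab), (ab, aa)):
                    m[x, y, u, w] = True
    return m


def _pair_seed(t_pair, no_sp, nv_sp):
    O, V = 2 * no_sp, 2 * nv_sp
    t2 = np.zeros((O, O, V, V))
    for i in range(no_sp):
        for a in range(nv_sp):
            ia, ib = 2 * i, 2 * i + 1
            aa, ab = 2 * a, 2 * a + 1
            t = t_pair[i, a]
            t2[ia, ib, aa, ab] = t
            t2[ib, ia, ab, aa] = t
            t2[ia, ib, ab, aa] = -t
            t2[ib, ia, aa, ab] = -t
    return t2


class _DIIS:
    def __init__(self, size=6):
        self.size = size
        self.xs, self.es = [], []

    def update(self, x, e):
        self.xs.append(x.copy())
        self.es.append(e.copy())
        if len(self.xs) > self.size:
            self.xs.pop(0)
            self.es.pop(0)
        if len(self.xs) < 2:
            return x
        n = len(self.xs)
        B = np.empty((n + 1, n + 1))
        B[:n, :n] = np.array([[ei @ ej for ej in self.es] for ei in self.es])
        B[n, :] = B[:, n] = -1.0
        B[n, n] = 0.0
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            w = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return x
        return sum(wi * xi for wi, xi in zip(w, self.xs))


def _iterate(f, eri, no, with_singles, freeze_mask=None, t2_init=None,
             t1_init=None, linear_ref=None, tol=1e-8, max_iter=300,
             method_tag=""):
    """Shared quasi-Newton + DIIS driver.

    freeze_mask: entries of t2 never updated (their residual is projected out).
    linear_ref: pair t2 array Tp for the fpLCC complex-step linearization.
    """
    nv = f.shape[0] - no
    fd = np.diag(f).real
    D1 = fd[:no, None] - fd[None, no:]
    D2 = (fd[:no, None, None, None] + fd[None, :no, None, None]
          - fd[None, None, no:, None] - fd[None, None, None, no:])
    D1 = np.where(np.abs(D1) < 1e-2, np.sign(D1 + 1e-300) * 1e-2, D1)
    D2 = np.where(np.abs(D2) < 1e-2, np.sign(D2 + 1e-300) * 1e-2, D2)

    t1 = np.zeros((no, nv)) if t1_init is None else t1_init.copy()
    if t2_init is None:
        o, v = slice(0, no), slice(no, None)
        t2 = eri[o, o, v, v] / D2
    else:
        t2 = t2_init.copy()

    def residual(t1x, t2x):
        if linear_ref is not None:
            h = 1e-120
            base = linear_ref
            R1c, R2c = _residual(f, eri, t1x * (1j * h),
                                 base + t2x * (1j * h), no)
            R1 = R1c.imag / h
            R2 = R2c.imag / h
            R1b, R2b = _residual(f, eri, np.zeros_like(t1x), base, no)
            return R1 + R1b.real, R2 + R2b.real
        return _residual(f, eri, t1x, t2x, no)

    diis = _DIIS()
    for it in range(max_iter):
        R1, R2 = residual(t1, t2)
        if freeze_mask is not None:
            R2 = R2.copy()
            R2[freeze_mask] = 0.0
        if not with_singles:
            R1 = np.zeros_like(R1)
        rnorm = max(np.max(np.abs(R1)) if R1.size else 0.0, np.max(np.abs(R2)))
        if np.max(np.abs(t2)) > 1e3:
            raise RuntimeError(f"{method_tag}: amplitudes diverged")
        if rnorm < tol:
            return t1, t2, rnorm, it
        t1n = t1 + (R1 / D1 if with_singles else 0.0)
        t2n = t2 + R2 / D2
        if freeze_mask is not None:
            t2n[freeze_mask] = t2[freeze_mask]
        x = np.concatenate([np.ravel(t1n), np.ravel(t2n)])
        e = np.concatenate([np.ravel(R1 / D1), np.ravel(R2 / D2)])
        x = diis.update(x, e)
        t1 = x[:t1.size].reshape(t1.shape)
        t2 = x[t1.size:].reshape(t2.shape)
        if freeze_mask is not None:
            t2[freeze_mask] = t2n[freeze_mask]
        # keep exact antisymmetry
        t2 = 0.25 * (t2 - t2.transpose(0, 1, 3, 2)
                     - t2.transpose(1, 0, 2, 3) + t2.transpose(1, 0, 3, 2))
    raise RuntimeError(
        f"{method_tag} did not converge in {max_iter} iterations "
        f"(residual {rnorm:.2e})"
        + ("; the fpLCC linear system may be near-singular at this geometry"
           if linear_ref is not None else ""))


def solve_cc(ints: MolecularIntegrals, method="ccsd", tol=1e-8,
             max_iter=300, guess: ClusterAmplitudes | None = None
             ) -> ClusterAmplitudes:
    """Standard CCD or CCSD from the closed-shell reference."""
    method = method.lower()
    if method not in ("ccd", "ccsd"):
        raise ValueError(f"unknown CC method {method!r}")
    no = 2 * ints.n_occ
    f, eri = spin_orbital_ints(ints)
    t1, t2, rnorm, _ = _iterate(f, eri, no, with_singles=(method == "ccsd"),
                                t1_init=None if guess is None else guess.t1so,
                                t2_init=None if guess is None else guess.t2so,
                                tol=tol, max_iter=max_iter, method_tag=method)
    e_corr = float(_cc_energy(f, eri, t1, t2, no).real)
    return ClusterAmplitudes(t1so=t1, t2so=t2, n_occ=ints.n_occ,
                             method_tag=method, e_corr=e_corr,
                             e_total=reference_energy(ints) + e_corr,
                             converged=True, residual_norm=rnorm)


def solve_fpcc(ints: MolecularIntegrals, pair: PairAmplitudes, variant="sd",
               tol=1e-8, max_iter=300,
               guess: ClusterAmplitudes | None = None) -> ClusterAmplitudes:
    """Frozen-pair CC: pair doubles fixed from pCCD, external manifold solved."""
    if not pair.converged:
        raise ValueError("frozen-pair CC requires converged pCCD amplitudes")
    variant = variant.lower()
    if variant not in ("d", "sd"):
        raise ValueError("variant must be 'd' or 'sd'")
    no_sp = ints.n_occ
    nv_sp = ints.n_orb - no_sp
    no = 2 * no_sp
    f, eri = spin_orbital_ints(ints)
    mask = _pair_mask(no_sp, nv_sp)
    t2_0 = _pair_seed(pair.t, no_sp, nv_sp)
    t1_0 = None
    if guess is not None:
        t1_0 = guess.t1so
        t2_0 = guess.t2so.copy()
        t2_0[mask] = _pair_seed(pair.t, no_sp, nv_sp)[mask]
    t1, t2, rnorm, _ = _iterate(f, eri, no, with_singles=(variant == "sd"),
                                freeze_mask=mask, t2_init=t2_0, t1_init=t1_0,
                                tol=tol, max_iter=max_iter,
                                method_tag=f"fpcc{variant}")
    e_corr = float(_cc_energy(f, eri, t1, t2, no).real)
    return ClusterAmplitudes(t1so=t1, t2so=t2, n_occ=no_sp,
                             method_tag=f"fpcc{variant}", e_corr=e_corr,
                             e_total=reference_energy(ints) + e_corr,
                             converged=True, residual_norm=rnorm,
                             pair_frozen=True, pair_source=pair.t.copy())


def solve_fplcc(ints: MolecularIntegrals, pair: PairAmplitudes, variant="sd",
                tol=1e-8, max_iter=300,
                guess: ClusterAmplitudes | None = None) -> ClusterAmplitudes:
    """Linearized frozen-pair CC (single-commutator BCH truncation)."""
    if not pair.converged:
        raise ValueError("fpLCC requires converged pCCD amplitudes")
    variant = variant.lower()
    if variant not in ("d", "sd"):
        raise ValueError("variant must be 'd' or 'sd'")
    no_sp = ints.n_occ
    nv_sp = ints.n_orb - no_sp
    no = 2 * no_sp
    f, eri = spin_orbital_ints(ints)
    mask = _pair_mask(no_sp, nv_sp)
    Tp = _pair_seed(pair.t, no_sp, nv_sp)
    t1_0 = None
    t2x_0 = np.zeros_like(Tp)
    if guess is not None:
        t1_0 = guess.t1so
        t2x_0 = guess.t2so - _pair_seed(guess.pair_source, no_sp, nv_sp) \
            if guess.pair_source is not None else guess.t2so.copy()
        t2x_0[mask] = 0.0
    t1, t2x, rnorm, _ = _iterate(f, eri, no, with_singles=(variant == "sd"),
                                 freeze_mask=mask, t2_init=t2x_0, t1_init=t1_0,
                                 linear_ref=Tp, tol=tol, max_iter=max_iter,
                                 method_tag=f"fplcc{variant}")
    t2 = Tp + t2x
    # energy of the linearized model: E(Tp) + directional term
    h = 1e-120
    e0 = _cc_energy(f, eri, np.zeros((no, 2 * nv_sp)), Tp, no)
    e1 = _cc_energy(f, eri, t1 * (1j * h), Tp + t2x * (1j * h), no).imag / h
    e_corr = float(e0.real + e1)
    return ClusterAmplitudes(t1so=t1, t2so=t2, n_occ=no_sp,
                             method_tag=f"fplcc{variant}", e_corr=e_corr,
                             e_total=reference_energy(ints) + e_corr,
                             converged=True, residual_norm=rnorm,
                             pair_frozen=True, pair_source=pair.t.copy())
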