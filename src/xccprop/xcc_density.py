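"""Expectation-value CC one-particle density matrices (XCC, third-order form).

Instead of solving Lambda equations, the expectation value
<e^T 0| X |e^T 0>/<e^T 0|e^T 0> is expanded through the connected S-operator
of Jeziorski and Moszynski and truncated at the terms complete through
third order of perturbation theory.  With spin-free amplitudes t_i^a,
t_ij^ab and t-bar_ij^ab = 2 t_ij^ab - t_ij^ba, the density blocks are

  occ-virt:   gamma_ia = 2 (t_i^a + s_i^a) = gamma_ai,
              s_i^a = sum_jb t_j^b t-bar_ij^ab     (the S1^[2] contraction)
  occ-occ :   gamma_ik = 2 delta_ik - 2 sum_jab t_ij^ab t-bar_kj^ab
  virt-virt:  gamma_ca = +2 sum_ijb t_ij^ab t-bar_ij^cb

The occ depletion and virt accumulation have opposite sign and equal total
weight, so the trace is conserved exactly; the overall factors and the
S1^[2] index pattern are pinned by the determinant-space oracle (exact
<e^T| E_pq |e^T> expectation agrees through third order in a global
fluctuation-scaling parameter -- see the test suite).  For doubles-only
models (XpCCD, XCCD, XfpCCD, XfpLCCD) the occupied-virtual block vanishes
identically.  The quadratic single-excitation term <[S1[1]+, [X, T1]]> is
omitted from this truncation by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ccsd import ClusterAmplitudes
from .pccd import PairAmplitudes

__all__ = ["OneRDM", "s_operators", "build_xcc_1rdm", "expectation_1e"]


@dataclass
class OneRDM:
    gamma: np.ndarray
    n_elec: int
    provenance: str           # xcc | response | hf | fci
    method_tag: str = ""

    def __post_init__(self):
        g = self.gamma
        if np.max(np.abs(g - g.T)) > 1e-10:
            raise ValueError("1-RDM must be symmetric")

    @property
    def trace(self):
        return float(np.trace(self.gamma))

    def natural_occupations(self):
        return np.linalg.eigvalsh(self.gamma)[::-1]

    def save(self, path):
        """Plain-text export (header line + full matrix, loadable below)."""
        with open(path, "w") as f:
            f.write(f"# OneRDM n_elec={self.n_elec} "
                    f"provenance={self.provenance} method={self.method_tag}\n")
            np.savetxt(f, self.gamma)
        return path

    @classmethod
    def load(cls, path):
        with open(path) as f:
            header = f.readline().split()
            meta = dict(kv.split("=") for kv in header[2:])
            gamma = np.loadtxt(f)
        return cls(gamma=np.atleast_2d(gamma), n_elec=int(meta["n_elec"]),
                   provenance=meta["provenance"],
                   method_tag=meta.get("method", ""))


def _spinfree(amps):
    """(t1, t2, n_occ) from either amplitude container."""
    if isinstance(amps, PairAmplitudes):
        no, nv = amps.t.shape
        t2 = np.zeros((no, no, nv, nv))
        i = np.arange(no)
        a = np.arange(nv)
        t2[i[:, None], i[:, None], a[None, :], a[None, :]] = amps.t
        return None, t2, no
    t1 = amps.t1 if amps.has_singles else None
    return t1, amps.t2, amps.n_occ


def s_operators(amps):
    """S-operator components {S1^[1], S2^[1], S1^[2]} in spin-free form.

    S1^[1] = T1, S2^[1] = T2 and S1^[2] = P1([T1+, T2]) evaluated as
    s_i^a = sum_jb t_j^b t-bar_ij^ab; zero arrays for doubles-only input.
    """
    t1, t2, no = _spinfree(amps)
    tbar = 2.0 * t2 - t2.transpose(0, 1, 3, 2)
    if t1 is None:
        s12 = np.zeros(t2.shape[0:1] + t2.shape[2:3])
        return {"s1_1": None, "s2_1": t2, "s1_2": s12}
    s12 = np.einsum("jb,ijab->ia", t1, tbar)
    return {"s1_1": t1, "s2_1": t2, "s1_2": s12}


def build_xcc_1rdm(amps, n_orb: int, method_tag: str | None = None) -> OneRDM:
    """XCC one-particle density matrix from converged amplitudes."""
    t1, t2, no = _spinfree(amps)
    nv = n_orb - no
    if t2.shape != (no, no, nv, nv):
        raise ValueError("amplitude dimensions inconsistent with n_orb")
    if method_tag is None:
        method_tag = "xpccd" if isinstance(amps, PairAmplitudes) else \
            "x" + amps.method_tag
    tbar = 2.0 * t2 - t2.transpose(0, 1, 3, 2)

    gamma = np.zeros((n_orb, n_orb))
    gamma[:no, :no] = 2.0 * np.eye(no)
    gamma[:no, :no] -= 2.0 * np.einsum("ijab,kjab->ik", t2, tbar)
    gamma[no:, no:] += 2.0 * np.einsum("ijab,ijcb->ac", t2, tbar)
    if t1 is not None:
        ov = 2.0 * (t1 + np.einsum("jb,ijab->ia", t1, tbar))
        gamma[:no, no:] = ov
        gamma[no:, :no] = ov.T
    gamma = 0.5 * (gamma + gamma.T)
    n_elec = 2 * no
    rdm = OneRDM(gamma=gamma, n_elec=n_elec, provenance="xcc",
                 method_tag=method_tag)
    if abs(rdm.trace - n_elec) > 1e-9:
        raise AssertionError("XCC density trace violated electron count")
    return rdm


def hf_rdm(n_orb: int, n_occ: int) -> OneRDM:
    g = np.zeros((n_orb, n_orb))
    g[np.arange(n_occ), np.arange(n_occ)] = 2.0
    return OneRDM(gamma=g, n_elec=2 * n_occ, provenance="hf", method_tag="hf")


def response_rdm_pccd(sz_rdms, n_orb: int) -> OneRDM:
    """Package the diagonal pCCD response density as a OneRDM."""
    return OneRDM(gamma=sz_rdms.gamma, n_elec=2 * sz_rdms.n_occ,
                  provenance="response", method_tag="pccd")


def expectation_1e(rdm: OneRDM, X: np.ndarray) -> float:
    """Electronic expectation value sum_pq gamma_pq X_pq (shared MO basis)."""
    X = np.asarray(X)
    if X.shape != rdm.gamma.shape:
        raise ValueError("operator and density matrix dimensions differ")
    return float(np.sum(rdm.gamma * X))
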