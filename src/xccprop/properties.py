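"""Dipole and traceless quadrupole moments from a 1-RDM + operator set.

mu_alpha     = sum_i Z_i R_i,alpha - sum_pq gamma_pq <p|r_alpha|q>
Theta_ab     = (nuclear traceless part) - sum_pq gamma_pq <p|q_ab|q>
with q_ab = (3 r_a r_b - delta_ab r^2)/2; Theta is symmetric and traceless.
Moments are taken about the Cartesian origin of the supplied geometry, so
they are origin-dependent for ions (documented; neutral systems are
translation invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import PropertyOperators
from .xcc_density import OneRDM, expectation_1e

__all__ = ["DEBYE", "MultipoleResult", "dipole_moment", "quadrupole_moment",
           "orient_qzz", "multipoles"]

DEBYE = 2.5417464519  # debye per atomic unit of dipole moment


@dataclass
class MultipoleResult:
    mu: np.ndarray            # (3,) a.u.
    theta: np.ndarray         # (3, 3) a.u., traceless
    method_tag: str = ""
    orbital_tag: str = ""

    @property
    def mu_debye(self):
        return self.mu * DEBYE

    @property
    def qzz(self):
        return float(self.theta[2, 2])


def dipole_moment(rdm: OneRDM, props: PropertyOperators) -> np.ndarray:
    if props.dip[0].shape != rdm.gamma.shape:
        raise ValueError("density matrix and dipole operators live in "
                         "different bases")
    mu_el = np.array([expectation_1e(rdm, props.dip[k]) for k in range(3)])
    return props.mu_nuc - mu_el


def quadrupole_moment(rdm: OneRDM, props: PropertyOperators) -> np.ndarray:
    if props.quad[0].shape != rdm.gamma.shape:
        raise ValueError("density matrix and quadrupole operators live in "
                         "different bases")
    th = props.theta_nuc.copy()
    for k, (a, b) in enumerate(PropertyOperators.QUAD_ORDER):
        v = expectation_1e(rdm, props.quad[k])
        th[a, b] -= v
        if a != b:
            th[b, a] -= v
    return th


def orient_qzz(theta: np.ndarray, mu: np.ndarray | None = None):
    """Axis permutation putting the largest |diagonal| component on z.

    Returns (perm, theta', mu'): ``perm`` maps new axis k to old axis
    perm[k]; eigen-structure is untouched (pure relabeling of axes).
    """
    k = int(np.argmax(np.abs(np.diag(theta))))
    perm = [0, 1, 2]
    if k != 2:
        perm[2], perm[k] = perm[k], perm[2]
    perm = np.array(perm)
    th = theta[np.ix_(perm, perm)]
    mu_out = mu[perm] if mu is not None else None
    return perm, th, mu_out


def multipoles(rdm: OneRDM, props: PropertyOperators,
               orbital_tag="") -> MultipoleResult:
    return MultipoleResult(mu=dipole_moment(rdm, props),
                           theta=quadrupole_moment(rdm, props),
                           method_tag=rdm.method_tag, orbital_tag=orbital_tag)
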