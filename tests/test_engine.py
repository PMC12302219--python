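"""AO integral engine and RHF: literature anchors and exact identities."""

import numpy as np
import pytest

from xccprop import basis as B
from xccprop import mdints


def test_h2_sto3g_matches_textbook_integrals(h2):
    """S, T, V and ERI values for H2/STO-3G at 1.4 bohr are tabulated in
    standard texts; the SCF energy is -1.1167 hartree."""
    ab = B.build_basis([("H", (0, 0, 0)), ("H", (0, 0, 1.4))], "sto-3g")
    S, T, V, _, _ = B.one_electron_ao(ab)
    g = B.eri_ao(ab)
    assert S[0, 1] == pytest.approx(0.6593, abs=2e-4)
    assert T[0, 0] == pytest.approx(0.7600, abs=2e-4)
    assert V[0, 0] == pytest.approx(-1.8804, abs=2e-4)
    assert g[0, 0, 0, 0] == pytest.approx(0.7746, abs=2e-4)
    assert g[0, 0, 1, 1] == pytest.approx(0.5697, abs=2e-4)
    assert g[0, 1, 0, 1] == pytest.approx(0.2970, abs=2e-4)
    assert h2.scf.energy == pytest.approx(-1.11671, abs=2e-5)


def test_p_and_d_integrals_obey_derivative_identities():
    """Raw p = d(s)/dA/(2a); raw d_xx = (d(p_x)/dAx + s)/(2a): the MD tables
    must satisfy these translations exactly (validates all l>0 code paths)."""
    A = np.array([0.1, -0.2, 0.3])
    Bc = np.array([0.8, 0.5, -0.4])
    C = np.array([-0.3, 0.9, 0.2])
    D = np.array([0.4, -0.7, -0.1])
    a, b, c, d = 0.9, 1.3, 0.7, 1.1
    h = 2e-4

    def eri4(ls, ctrs):
        shells = [(l, ct, np.array([e]), np.array([1.0]))
                  for l, ct, e in zip(ls, ctrs, (a, b, c, d))]
        return mdints.eri_cartesian(shells)

    def ssss(Ax):
        A2 = A.copy()
        A2[0] = Ax
        return eri4((0, 0, 0, 0), (A2, Bc, C, D))[0, 1, 2, 3]

    fd = (ssss(A[0] + h) - ssss(A[0] - h)) / (2 * h) / (2 * a)
    g = eri4((1, 0, 0, 0), (A, Bc, C, D))
    assert g[0, 3, 4, 5] == pytest.approx(fd, rel=1e-6)

    def pxsss(Ax):
        A2 = A.copy()
        A2[0] = Ax
        return eri4((1, 0, 0, 0), (A2, Bc, C, D))[0, 3, 4, 5]

    fd2 = ((pxsss(A[0] + h) - pxsss(A[0] - h)) / (2 * h) + ssss(A[0])) / (2 * a)
    g2 = eri4((2, 0, 0, 0), (A, Bc, C, D))
    assert g2[0, 6, 7, 8] == pytest.approx(fd2, rel=1e-6)

    V = mdints.nuclear_attraction(1, 0, a, b, A, Bc, [(1.0, C)])
    def Vs(Ax):
        A2 = A.copy()
        A2[0] = Ax
        return mdints.nuclear_attraction(0, 0, a, b, A2, Bc, [(1.0, C)])[0, 0]
    fdV = (Vs(A[0] + h) - Vs(A[0] - h)) / (2 * h) / (2 * a)
    assert V[0, 0] == pytest.approx(fdV, rel=1e-6)


def test_rhf_energy_invariant_under_rigid_rotation():
    """Rotating H2O off its symmetry frame leaves E and |mu| unchanged
    (validates relative normalization across Cartesian components)."""
    from xccprop import scf as S
    from scipy.spatial.transform import Rotation
    atoms = [("O", (0.0, 0.0, 0.0)),
             ("H", (1.43, 0.0, 1.11)), ("H", (-1.43, 0.0, 1.11))]
    ab1 = B.build_basis(atoms, "sto-3g")
    r1 = S.rhf(ab1)
    Rm = Rotation.from_euler("xyz", [0.3, -0.8, 0.5]).as_matrix()
    atoms2 = [(el, tuple(Rm @ np.array(x))) for el, x in atoms]
    ab2 = B.build_basis(atoms2, "sto-3g")
    r2 = S.rhf(ab2)
    assert r2.energy == pytest.approx(r1.energy, abs=1e-9)
    assert np.linalg.norm(r2.dipole) == pytest.approx(
        np.linalg.norm(r1.dipole), abs=1e-8)


def test_hf_ccpvdz_scf_anchor():
    """HF molecule near equilibrium: SCF energy ~ -100.019 hartree and
    dipole ~1.95 D at cc-pVDZ (literature SCF values)."""
    from xccprop import fixtures
    s = fixtures.make_system("hf_ccpvdz")
    assert s.scf.energy == pytest.approx(-100.0198, abs=2e-3)
    assert abs(s.scf.dipole[2]) * 2.5417464519 == pytest.approx(1.956, abs=0.02)
    assert s.ints.n_orb == 19


def test_cross_geometry_overlap_limits():
    ab1 = B.build_basis([("H", (0, 0, 0)), ("H", (0, 0, 1.4))], "sto-3g")
    S_self = B.cross_overlap(ab1, ab1)
    S0, _, _, _, _ = B.one_electron_ao(ab1)
    assert np.max(np.abs(S_self - S0)) < 1e-12
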