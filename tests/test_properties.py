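"""Multipole moments: analytic anchors, invariances, SCF consistency."""

import numpy as np
import pytest

from xccprop import properties as prop
from xccprop import xcc_density as xd
from xccprop.integrals import PropertyOperators


def _shifted(props, delta):
    """Rigidly translate geometry + operator matrices by delta (exact for
    the dipole: r -> r + d shifts <p|r|q> by d*S = d*identity in MO)."""
    n = props.dip.shape[1]
    atoms = [(Z, np.asarray(R) + delta) for Z, R in props.atoms]
    dip = props.dip + np.array(delta)[:, None, None] * np.eye(n)[None, :, :]
    # traceless quadrupole does not translate so simply; dipole test only
    return PropertyOperators(atoms=atoms, dip=dip, quad=props.quad)


def test_nuclear_dipole_of_hehp(hehp):
    assert np.allclose(hehp.props.mu_nuc, [0, 0, 1.4632], atol=1e-12)


def test_hf_density_reproduces_scf_moments(h2o):
    rdm = xd.hf_rdm(7, 5)
    mu = prop.dipole_moment(rdm, h2o.props)
    assert np.allclose(mu, h2o.scf.dipole, atol=1e-6)


def test_neutral_molecule_dipole_translation_invariant(h2o):
    rdm = xd.hf_rdm(7, 5)
    mu0 = prop.dipole_moment(rdm, h2o.props)
    mu1 = prop.dipole_moment(rdm, _shifted(h2o.props, [0.3, -0.2, 0.8]))
    assert np.allclose(mu0, mu1, atol=1e-9)


def test_ion_dipole_shifts_by_charge_times_displacement(hehp):
    rdm = xd.hf_rdm(2, 1)
    d = np.array([0.0, 0.0, 0.5])
    mu0 = prop.dipole_moment(rdm, hehp.props)
    mu1 = prop.dipole_moment(rdm, _shifted(hehp.props, d))
    assert np.allclose(mu1 - mu0, 1.0 * d, atol=1e-9)  # charge +1


def test_point_charge_quadrupole_closed_form():
    """Single charge q at (0,0,d) with no electrons: Theta_zz = q d^2."""
    q, d = 2.0, 1.3
    ops = PropertyOperators(atoms=[(q, np.array([0.0, 0.0, d]))],
                            dip=np.zeros((3, 1, 1)), quad=np.zeros((6, 1, 1)))
    rdm = xd.OneRDM(gamma=np.zeros((1, 1)), n_elec=0, provenance="hf")
    th = prop.quadrupole_moment(rdm, ops)
    assert th[2, 2] == pytest.approx(q * d * d, abs=1e-12)
    assert np.trace(th) == pytest.approx(0.0, abs=1e-12)


def test_quadrupole_traceless_and_symmetric_on_fci_density(h2o, h2o_fci,
                                                           h2o_space):
    _, v = h2o_fci
    gam = h2o_space.rdm1(v)
    rdm = xd.OneRDM(gamma=gam, n_elec=10, provenance="fci")
    th = prop.quadrupole_moment(rdm, h2o.props)
    assert np.trace(th) == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(th, th.T, atol=1e-10)


def test_fci_dipole_matches_oracle_contraction(h2o, h2o_fci, h2o_space):
    _, v = h2o_fci
    gam = h2o_space.rdm1(v)
    rdm = xd.OneRDM(gamma=gam, n_elec=10, provenance="fci")
    mu = prop.dipole_moment(rdm, h2o.props)
    by_hand = h2o.props.mu_nuc - np.array(
        [np.sum(gam * h2o.props.dip[k]) for k in range(3)])
    assert np.allclose(mu, by_hand, atol=1e-12)


def test_orient_qzz_permutation_and_identity():
    th = np.diag([1.0, -3.0, 2.0])
    perm, th2, _ = prop.orient_qzz(th)
    assert th2[2, 2] == -3.0
    assert sorted(np.diag(th2)) == sorted(np.diag(th))
    th_id = np.diag([1.0, 0.5, -1.5])
    perm, th3, mu3 = prop.orient_qzz(th_id, mu=np.array([1.0, 2.0, 3.0]))
    assert np.array_equal(perm, [0, 1, 2])
    assert np.array_equal(mu3, [1.0, 2.0, 3.0])


def test_eigenvalues_invariant_under_reorientation():
    rng = np.random.default_rng(4)
    A = rng.standard_normal((3, 3))
    th = A + A.T
    th -= np.trace(th) / 3 * np.eye(3)
    _, th2, _ = prop.orient_qzz(th)
    assert np.allclose(sorted(np.linalg.eigvalsh(th)),
                       sorted(np.linalg.eigvalsh(th2)), atol=1e-12)


def test_debye_conversion():
    r = prop.MultipoleResult(mu=np.array([0, 0, 1.0]), theta=np.zeros((3, 3)))
    assert r.mu_debye[2] == pytest.approx(2.5417464519)
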