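"""pCCD amplitudes, Lambda equations and response RDMs vs the oracle."""

import numpy as np
import pytest
import scipy.sparse as sp

from xccprop import pccd
from xccprop.integrals import MolecularIntegrals, reference_energy


def test_zero_coupling_gives_zero_amplitudes():
    n = 3
    h = np.diag([-2.0, -1.0, 1.0])
    g = np.zeros((n, n, n, n))
    for p in range(n):
        g[p, p, p, p] = 0.3
    ints = MolecularIntegrals(n_orb=n, n_elec=2, e_core=0.0, h=h, g=g)
    amps = pccd.solve_pccd(ints)
    assert np.max(np.abs(amps.t)) < 1e-12
    assert amps.e_corr == pytest.approx(0.0, abs=1e-14)


def test_two_electron_pccd_equals_fci(h2, h2_space):
    e_fci, _ = h2_space.fci_solve(h2.ints)
    amps = pccd.solve_pccd(h2.ints)
    assert amps.e_total == pytest.approx(e_fci, abs=1e-9)
    # and equals the seniority-zero 2x2 CI ground state by construction
    assert amps.converged and amps.residual_norm < 1e-8


def test_converged_amplitudes_satisfy_determinant_residual(h2o, h2o_space):
    amps = pccd.solve_pccd(h2o.ints)
    T = h2o_space.cluster_operator(5, t_pair=amps.t)
    bras = [h2o_space.pair(i, 5 + a) for i in range(5) for a in range(2)]
    res = h2o_space.projective_residual(h2o.ints, T, bras)
    assert np.max(np.abs(res)) < 1e-8


def test_lambda_zero_for_zero_amplitudes():
    n = 3
    h = np.diag([-2.0, -1.0, 1.0])
    g = np.zeros((n, n, n, n))
    ints = MolecularIntegrals(n_orb=n, n_elec=2, e_core=0.0, h=h, g=g)
    amps = pccd.solve_pccd(ints)
    amps = pccd.solve_pccd_lambda(ints, amps)
    assert np.max(np.abs(amps.lam)) < 1e-12


def test_lagrangian_stationary_in_amplitudes(h2o):
    """Directional derivatives of E + lam.R vanish at the Lambda solution."""
    ints = h2o.ints
    amps = pccd.solve_pccd(ints)
    amps = pccd.solve_pccd_lambda(ints, amps)
    J, K, f = pccd.seniority_slices(ints)
    no = 5

    def lagrangian(t):
        R, _ = pccd._residual(t, J, K, f, no)
        e = reference_energy(ints) + np.sum(K[:no, no:] * t)
        return e + np.sum(amps.lam * R)

    rng = np.random.default_rng(3)
    h = 1e-6
    for _ in range(3):
        d = rng.standard_normal(amps.t.shape)
        d /= np.linalg.norm(d)
        der = (lagrangian(amps.t + h * d) - lagrangian(amps.t - h * d)) / (2 * h)
        assert abs(der) < 1e-6


def test_response_rdms_match_oracle_transition_expectations(h2o, h2o_space):
    ints = h2o.ints
    ds = h2o_space
    amps = pccd.solve_pccd(ints)
    amps = pccd.solve_pccd_lambda(ints, amps)
    rd = pccd.pccd_response_rdms(amps, 7)
    no, nv = 5, 2
    T = ds.cluster_operator(no, t_pair=amps.t)
    ref = ds.ref_vector(no)
    ket = ds.exp_apply(T, ref)
    lamvec = ref.copy()
    for i in range(no):
        for a in range(nv):
            lamvec = lamvec + amps.lam[i, a] * (ds.pair(i, no + a) @ ref)
    bra = ds.exp_apply(sp.csr_matrix(T.T), lamvec, sign=-1.0)

    gam_or = np.array([bra @ (ds.E(p, p) @ ket) for p in range(7)])
    assert np.max(np.abs(gam_or - 2 * rd.nu)) < 1e-12
    for p in range(7):
        for q in range(7):
            if p == q:
                continue
            P_or = bra @ (ds.pair(q, p) @ ket)
            N_or = bra @ (ds.pair(p, p) @ (ds.pair(q, q) @ ket))
            assert rd.pairP[p, q] == pytest.approx(P_or, abs=1e-12)
            assert rd.nunu[p, q] == pytest.approx(N_or, abs=1e-12)


def test_response_rdm_is_diagonal_and_trace_conserving(h2o):
    amps = pccd.solve_pccd(h2o.ints)
    amps = pccd.solve_pccd_lambda(h2o.ints, amps)
    rd = pccd.pccd_response_rdms(amps, 7)
    gam = rd.gamma
    assert np.allclose(gam, np.diag(np.diag(gam)), atol=1e-14)
    assert np.trace(gam) == pytest.approx(10.0, abs=1e-10)


def test_energy_from_response_rdms_matches_cc_energy(h2o):
    amps = pccd.solve_pccd(h2o.ints)
    amps = pccd.solve_pccd_lambda(h2o.ints, amps)
    rd = pccd.pccd_response_rdms(amps, 7)
    assert pccd.sz_energy(h2o.ints, rd) == pytest.approx(amps.e_total,
                                                         abs=1e-9)


def test_missing_lambda_raises(h2o):
    amps = pccd.solve_pccd(h2o.ints)
    with pytest.raises(ValueError, match="Lambda"):
        pccd.pccd_response_rdms(amps, 7)


def test_two_orbital_occupations_match_fci_naturals(h2, h2_space):
    amps = pccd.solve_pccd(h2.ints)
    amps = pccd.solve_pccd_lambda(h2.ints, amps)
    rd = pccd.pccd_response_rdms(amps, 2)
    t = amps.t[0, 0]
    assert 2 * rd.nu[0] == pytest.approx(2 / (1 + t * t), abs=1e-12)
    assert 2 * rd.nu[1] == pytest.approx(2 * t * t / (1 + t * t), abs=1e-12)
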