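"""Expectation-value density matrices: S operators, blocks, order test."""

import numpy as np
import pytest

from xccprop import ccsd, pccd, xcc_density as xd
from conftest import oracle_cluster_op, scale_fluctuation


def test_zero_amplitudes_give_reference_density(h2o):
    amps = pccd.PairAmplitudes(t=np.zeros((5, 2)), converged=True, n_occ=5)
    rdm = xd.build_xcc_1rdm(amps, 7)
    assert np.allclose(rdm.gamma, np.diag([2.0] * 5 + [0.0] * 2), atol=1e-14)


def test_single_pair_model_occupations():
    """XCC occupations 2-2t^2 / +2t^2 agree with FCI 2/(1+t^2) to O(t^4)."""
    t = 0.11
    amps = pccd.PairAmplitudes(t=np.array([[t]]), converged=True, n_occ=1)
    rdm = xd.build_xcc_1rdm(amps, 2)
    assert rdm.gamma[0, 0] == pytest.approx(2 - 2 * t * t, abs=1e-14)
    assert rdm.gamma[1, 1] == pytest.approx(2 * t * t, abs=1e-14)
    exact = 2 / (1 + t * t)
    assert rdm.gamma[0, 0] == pytest.approx(exact, abs=3 * t ** 4)


def test_s_operator_components(h2o):
    cc = ccsd.solve_cc(h2o.ints, "ccsd")
    s = xd.s_operators(cc)
    assert np.array_equal(s["s1_1"], cc.t1)
    assert np.array_equal(s["s2_1"], cc.t2)
    tbar = 2 * cc.t2 - cc.t2.transpose(0, 1, 3, 2)
    assert np.allclose(s["s1_2"], np.einsum("jb,ijab->ia", cc.t1, tbar),
                       atol=1e-14)
    # doubles-only input: singles-sector components vanish
    sp = xd.s_operators(pccd.solve_pccd(h2o.ints))
    assert sp["s1_1"] is None and np.all(sp["s1_2"] == 0.0)


def test_s1_2_is_the_second_order_singles_of_the_s_operator(h2o, h2o_space):
    """The singles content of e^S|0> = e^{T+}e^T|0>/<0|..|0> is exactly S1;
    through second order S1 = T1 + sum_jb t_j^b tbar_ij^ab, so the residual
    of that formula must vanish one order faster than S1^[2] itself."""
    import scipy.sparse as sp
    from conftest import spin_adapted_so
    ds = h2o_space
    rng = np.random.default_rng(5)
    t1_sp = rng.standard_normal((5, 2)) * 0.06
    t2_sp = rng.standard_normal((5, 5, 2, 2)) * 0.06
    t2_sp = 0.5 * (t2_sp + t2_sp.transpose(1, 0, 3, 2))
    ref = ds.ref_vector(5)
    ratios = []
    for lam in (0.4, 0.2, 0.1):
        t1so, t2so = spin_adapted_so(t1_sp * lam, t2_sp * lam)
        T = oracle_cluster_op(ds, 5, t1so, t2so)
        x = ds.exp_apply(T, ref)
        x = ds.exp_apply(sp.csr_matrix(T.T), x)
        x = x / (ref @ x)
        t1_sf = t1so[0::2, 0::2]
        t2_sf = t2so[0::2, 1::2, 0::2, 1::2]
        tbar = 2 * t2_sf - t2_sf.transpose(0, 1, 3, 2)
        s12 = np.einsum("jb,ijab->ia", t1_sf, tbar)
        S1 = np.array([[(ds.E(i, 5 + a) @ ref) @ x / 2.0
                        for a in range(2)] for i in range(5)])
        ratios.append(np.linalg.norm(S1 - t1_sf - s12) / np.linalg.norm(s12))
    assert ratios[1] < 0.6 * ratios[0]
    assert ratios[2] < 0.6 * ratios[1]


@pytest.mark.parametrize("maker", [
    lambda ints: pccd.solve_pccd(ints),
    lambda ints: ccsd.solve_cc(ints, "ccd"),
    lambda ints: ccsd.solve_cc(ints, "ccsd"),
    lambda ints: ccsd.solve_fpcc(ints, pccd.solve_pccd(ints), "d"),
    lambda ints: ccsd.solve_fpcc(ints, pccd.solve_pccd(ints), "sd"),
    lambda ints: ccsd.solve_fplcc(ints, pccd.solve_pccd(ints), "d"),
    lambda ints: ccsd.solve_fplcc(ints, pccd.solve_pccd(ints), "sd"),
], ids=["xpccd", "xccd", "xccsd", "xfpccd", "xfpccsd", "xfplccd", "xfplccsd"])
def test_trace_and_symmetry_for_every_method(h2o, maker):
    rdm = xd.build_xcc_1rdm(maker(h2o.ints), 7)
    assert np.trace(rdm.gamma) == pytest.approx(10.0, abs=1e-9)
    assert np.max(np.abs(rdm.gamma - rdm.gamma.T)) < 1e-10
    w = np.linalg.eigvalsh(rdm.gamma)
    assert w.min() > -0.05 and w.max() < 2.05


def test_doubles_only_methods_have_zero_ov_block(h2o):
    for amps in (pccd.solve_pccd(h2o.ints),
                 ccsd.solve_cc(h2o.ints, "ccd")):
        g = xd.build_xcc_1rdm(amps, 7).gamma
        assert np.max(np.abs(g[:5, 5:])) == 0.0


def test_order_consistency_against_exact_expectation(h2o, h2o_space):
    """||gamma_XCCSD - gamma_exact|| decays at least one power of lambda
    faster than ||gamma_exact - gamma_HF|| (third-order completeness)."""
    g_hf = np.diag([2.0] * 5 + [0.0] * 2)
    ratios = []
    for lam in (0.4, 0.2, 0.1):
        ints = scale_fluctuation(h2o.ints, lam)
        cc = ccsd.solve_cc(ints, "ccsd")
        gx = xd.build_xcc_1rdm(cc, 7).gamma
        T = oracle_cluster_op(h2o_space, 5, cc.t1so, cc.t2so)
        ge = h2o_space.cc_density(T, 5)
        ratios.append(np.linalg.norm(gx - ge) / np.linalg.norm(ge - g_hf))
    assert ratios[1] < 0.5 * ratios[0]
    assert ratios[2] < 0.5 * ratios[1]


def test_expectation_1e_contractions(h2o):
    rdm = xd.hf_rdm(7, 5)
    assert xd.expectation_1e(rdm, np.eye(7)) == pytest.approx(10.0)
    proj = np.diag([1.0] * 5 + [0.0] * 2)
    assert xd.expectation_1e(rdm, proj) == pytest.approx(10.0)
    with pytest.raises(ValueError, match="dimensions"):
        xd.expectation_1e(rdm, np.eye(5))


def test_asymmetric_gamma_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        xd.OneRDM(gamma=np.array([[1.0, 0.2], [0.0, 1.0]]), n_elec=2,
                  provenance="xcc")


def test_onerdm_plain_text_roundtrip(h2o, tmp_path):
    rdm = xd.build_xcc_1rdm(pccd.solve_pccd(h2o.ints), 7)
    p = tmp_path / "gamma.txt"
    rdm.save(p)
    back = xd.OneRDM.load(p)
    assert np.max(np.abs(back.gamma - rdm.gamma)) < 1e-12
    assert back.n_elec == 10 and back.provenance == "xcc"
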